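"""The EAR cut-point method.

Usual intake in a stratum is modelled as normal with the stratum's mean
supply and a fixed coefficient of variation (30% for B vitamins).  Under
the cut-point assumptions (intake independent of requirement, symmetric
requirement distribution) the prevalence of inadequate intake equals the
mass of the intake distribution below the estimated average requirement,
Phi((EAR - mean) / sd).  The normal is deliberately not truncated at
zero: with CV = 0.30 the mass below zero is Phi(-10/3) ~ 4e-4.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import CoverageError, DomainError, IntakeDistribution

log = logging.getLogger(__name__)


def prevalence_inadequate(dist: IntakeDistribution, ear: float) -> float:
    """Lower-tail normal probability below the EAR cut-point."""
    if ear <= 0:
        raise DomainError(f"ear must be > 0, got {ear}")
    return float(norm.cdf((ear - dist.mean) / dist.sd))


def prevalence_inadequate_arr(means: np.ndarray, ears: np.ndarray, cv: float) -> np.ndarray:
    """Vectorized cut-point prevalence; non-positive means give NaN."""
    means = np.asarray(means, dtype=float)
    ears = np.asarray(ears, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ears - means) / (cv * means)
        out = norm.cdf(z)
    return np.where(means > 0, out, np.nan)


def population_at_risk(prevalence: float, population: float) -> float:
    """Head-count below the cut-point; no rounding before final reporting."""
    if not 0 <= prevalence <= 1:
        raise DomainError(f"prevalence must be in [0, 1], got {prevalence}")
    if population < 0:
        raise DomainError(f"population must be >= 0, got {population}")
    return prevalence * population


def compute_adequacy(
    means: pd.DataFrame,
    ears: pd.DataFrame,
    population: pd.DataFrame,
    cv: float = 0.30,
    scenario: str = "current",
    year: int = 2010,
) -> pd.DataFrame:
    """Stratum-level adequacy table.

    ``means`` holds country, sex, age_low, nutrient, mean (total intake
    proxy); ``ears`` the matching EAR table.  Strata with zero or missing
    mean intake are excluded with a warning (a zero mean signals missing
    supply data, not universal deficiency).
    """
    df = means.merge(ears, on=["country", "sex", "age_low", "nutrient"], how="left")
    if df["ear"].isna().any():
        bad = df[df["ear"].isna()].iloc[0]
        raise CoverageError(
            f"no EAR for stratum {bad['country']}/{bad['sex']}/{bad['age_low']}/{bad['nutrient']}"
        )
    pop = population[population["year"] == year][["country", "sex", "age_low", "population"]]
    df = df.merge(pop, on=["country", "sex", "age_low"], how="left")
    df["population"] = df["population"].fillna(0.0)

    excluded = df["mean"] <= 0
    if excluded.any():
        log.warning(
            "excluding %d strata with zero/absent mean intake from adequacy", int(excluded.sum())
        )
        df = df[~excluded].copy()
    df["prevalence"] = prevalence_inadequate_arr(
        df["mean"].to_numpy(), df["ear"].to_numpy(), cv
    )
    df["population_at_risk"] = df["prevalence"] * df["population"]
    df["scenario"] = scenario
    return df[
        ["country", "sex", "age_low", "nutrient", "scenario", "prevalence", "population_at_risk"]
    ]


def aggregate(
    results: pd.DataFrame,
    regions: pd.DataFrame,
    population: pd.DataFrame,
    grouping: str = "region",
    year: int = 2010,
) -> pd.DataFrame:
    """Aggregate stratum results to regions or globally.

    Head-count columns sum; ``prevalence`` aggregates as the
    population-weighted mean.  Every country must appear in the regions
    table.
    """
    if grouping not in ("region", "global"):
        raise DomainError(f"grouping must be 'region' or 'global', got {grouping!r}")
    region_of = regions.set_index("country")["region"]
    missing = set(results["country"].unique()) - set(region_of.index)
    if missing:
        raise CoverageError(f"countries missing from regions table: {sorted(missing)}")
    pop = population[population["year"] == year].set_index(["country", "sex", "age_low"])[
        "population"
    ]
    df = results.copy()
    df["region"] = df["country"].map(region_of) if grouping == "region" else "global"
    df["pop"] = [
        float(pop.get((c, s, a), 0.0))
        for c, s, a in zip(df["country"], df["sex"], df["age_low"])
    ]
    group_cols = ["region", "nutrient"] + (["scenario"] if "scenario" in df.columns else [])

    def _agg(grp: pd.DataFrame) -> pd.Series:
        w = grp["pop"].to_numpy()
        wsum = float(w.sum())
        prev = float(np.average(grp["prevalence"], weights=w)) if wsum > 0 else float("nan")
        return pd.Series(
            {
                "prevalence": prev,
                "population_at_risk": float(grp["population_at_risk"].sum()),
                "population": wsum,
            }
        )

    out = df.groupby(group_cols, sort=True).apply(_agg, include_groups=False).reset_index()
    return out.rename(columns={"region": "scope"})
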