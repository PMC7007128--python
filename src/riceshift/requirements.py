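"""Per-stratum estimated average requirements (EARs).

Recommended nutrient intakes (RNIs) are published on irregular age
groupings and for three physiological states (none / pregnant /
lactating).  This module converts RNIs to EARs with a per-nutrient
conversion factor, harmonizes the source age bins onto the 5-year bins of
the supply data by population weighting, estimates the fraction of women
in each reproductive-age stratum who are pregnant or lactating from
age-specific fertility and national breastfeeding duration, and blends
the three state EARs into one population-weighted EAR per stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    AGE_BINS,
    NUTRIENTS,
    PREGNANCY_YEAR_FRACTION,
    REPRO_AGE_BINS,
    SEXES,
    ConfigError,
    CoverageError,
    DomainError,
)


def rni_to_ear(rni: float, ear_factor: float) -> float:
    """Convert a recommended intake to an estimated average requirement.

    The RNI is defined as the intake covering ~97.5% of a group, i.e.
    roughly EAR x (1 + 2 CV) for a symmetric requirement distribution;
    ``ear_factor`` is that multiplier (1.2 for a 10% requirement CV).
    """
    if rni <= 0 or ear_factor <= 0:
        raise DomainError(f"rni and ear_factor must be > 0, got {rni}, {ear_factor}")
    return rni / ear_factor


def harmonize_age_bins(
    source: pd.DataFrame,
    population: pd.DataFrame,
    targets: list[tuple[int, int]],
) -> pd.DataFrame:
    """Population-weighted re-binning of requirement values.

    ``source`` has columns age_low, age_high, value on arbitrary
    contiguous bins; ``population`` has columns age_low (5-year bins) and
    population.  People are assumed uniformly distributed inside each
    5-year population bin, so the weight of an overlap segment is the
    covering bin's population times the covered fraction of that bin.
    Where every overlap segment of a target has zero population the
    segments are weighted by length instead.  The terminal 80+ population
    bin is treated as 80-85 for overlap purposes.
    """
    src_lo = source["age_low"].to_numpy(dtype=float)
    src_hi = source["age_high"].to_numpy(dtype=float)
    src_val = source["value"].to_numpy(dtype=float)
    pop = dict(zip(population["age_low"].astype(int), population["population"].astype(float)))

    def density(a: float, b: float) -> float:
        """Population mass in [a, b) under uniform-within-5-year-bin density."""
        total = 0.0
        for bin_lo in AGE_BINS:
            bin_hi = bin_lo + 5
            lo, hi = max(a, bin_lo), min(b, bin_hi)
            if hi > lo:
                total += pop.get(bin_lo, 0.0) * (hi - lo) / 5.0
        return total

    rows = []
    for t_lo, t_hi in targets:
        num = den = len_num = len_den = 0.0
        covered = 0.0
        for lo, hi, val in zip(src_lo, src_hi, src_val):
            a, b = max(t_lo, lo), min(t_hi, hi)
            if b <= a:
                continue
            covered += b - a
            w = density(a, b)
            num += w * val
            den += w
            len_num += (b - a) * val
            len_den += b - a
        if covered < (t_hi - t_lo) - 1e-9:
            raise CoverageError(
                f"target bin [{t_lo}, {t_hi}) not fully covered by source bins"
            )
        value = num / den if den > 0 else len_num / len_den
        rows.append({"age_low": t_lo, "age_high": t_hi, "value": value})
    return pd.DataFrame(rows)


def pregnant_fraction(asfr: float) -> float:
    """Fraction of women pregnant at any time, from the annual birth rate.

    A pregnancy occupies 40 of 52 weeks, so the expected person-time
    fraction is asfr x 40/52, capped at 1.
    """
    if asfr < 0:
        raise DomainError(f"asfr must be >= 0, got {asfr}")
    return min(asfr * PREGNANCY_YEAR_FRACTION, 1.0)


def lactating_fraction(asfr: float, breastfeed_years: float) -> float:
    """Fraction of women lactating, rescaled jointly with pregnancy.

    The raw estimate is asfr x mean breastfeeding duration in years.  If
    the raw pregnant + lactating fractions exceed 1 the pair is rescaled
    proportionally to sum to 1 (the two states are treated as mutually
    exclusive within a year), and this returns the rescaled lactating
    part.
    """
    _, lact = reproductive_fractions(asfr, breastfeed_years)
    return lact


def reproductive_fractions(asfr: float, breastfeed_years: float) -> tuple[float, float]:
    """(pregnant, lactating) fractions after the joint cap at 1."""
    if asfr < 0 or breastfeed_years < 0:
        raise DomainError("asfr and breastfeed_years must be >= 0")
    preg = asfr * PREGNANCY_YEAR_FRACTION
    lact = asfr * breastfeed_years
    total = preg + lact
    if total > 1.0:
        preg, lact = preg / total, lact / total
    return preg, lact


def weighted_ear(
    frac_pregnant: float,
    frac_lactating: float,
    ear_none: float,
    ear_pregnant: float | None = None,
    ear_lactating: float | None = None,
) -> float:
    """Blend state-specific EARs by the fractions in each state."""
    if frac_pregnant < 0 or frac_lactating < 0 or frac_pregnant + frac_lactating > 1 + 1e-12:
        raise DomainError("invalid reproductive fractions")
    if frac_pregnant == 0 and frac_lactating == 0:
        return ear_none
    if ear_pregnant is None or ear_lactating is None:
        raise ConfigError("pregnant/lactating EAR missing for a nutrient that needs it")
    frac_neither = 1.0 - frac_pregnant - frac_lactating
    return frac_neither * ear_none + frac_pregnant * ear_pregnant + frac_lactating * ear_lactating


def _regional_breastfeed_years(
    breastfeeding: pd.DataFrame,
    regions: pd.DataFrame,
    population: pd.DataFrame,
) -> pd.Series:
    """Breastfeeding duration (years) per country with regional fallback.

    Countries absent from the table receive the population-weighted mean
    over their region's reporting countries; a region with no reporting
    country falls back to the population-weighted global mean.
    """
    pop_total = population.groupby("country")["population"].sum()
    bf = breastfeeding.set_index("country")["mean_duration_months"] / 12.0
    region_of = regions.set_index("country")["region"]
    out = {}
    have = bf.index
    weights = pop_total.reindex(have).fillna(0.0)
    global_mean = (
        float(np.average(bf.to_numpy(), weights=np.maximum(weights.to_numpy(), 1e-300)))
        if len(bf)
        else 0.0
    )
    for country in region_of.index:
        if country in bf.index:
            out[country] = float(bf[country])
            continue
        peers = [c for c in region_of.index if region_of[c] == region_of[country] and c in bf.index]
        if peers:
            w = np.maximum(pop_total.reindex(peers).fillna(0.0).to_numpy(), 1e-300)
            out[country] = float(np.average(bf[peers].to_numpy(), weights=w))
        else:
            out[country] = global_mean
    return pd.Series(out, name="breastfeed_years")


def build_ear_table(
    requirements: pd.DataFrame,
    population: pd.DataFrame,
    fertility: pd.DataFrame,
    breastfeeding: pd.DataFrame,
    regions: pd.DataFrame,
    year: int = 2010,
) -> pd.DataFrame:
    """Per-stratum EAR table: country, sex, age_low, nutrient, ear.

    Baseline (state "none") EARs are harmonized onto 5-year bins using the
    global population of the matching sex as weights.  For female strata
    aged 15-49 the EAR is the population-weighted blend over the neither /
    pregnant / lactating states with country-specific fractions.
    """
    pop_y = population[population["year"] == year]
    req = requirements.copy()
    req["ear"] = req["rni"] / req["ear_factor"]

    targets = [(a, a + 5) for a in AGE_BINS]
    base: dict[tuple[str, str], pd.DataFrame] = {}
    state_ear: dict[tuple[str, str], float] = {}
    for nutrient in NUTRIENTS:
        for sex in SEXES:
            rows = req[(req["nutrient"] == nutrient) & (req["sex"] == sex) & (req["state"] == "none")]
            if rows.empty:
                raise CoverageError(f"no baseline requirement rows for {nutrient}/{sex}")
            pop_sex = (
                pop_y[pop_y["sex"] == sex]
                .groupby("age_low", as_index=False)["population"]
                .sum()
            )
            src = rows.rename(columns={"ear": "value"})[["age_low", "age_high", "value"]]
            harm = harmonize_age_bins(src, pop_sex, targets)
            base[(nutrient, sex)] = harm.set_index("age_low")["value"]
        for state in ("pregnant", "lactating"):
            rows = req[(req["nutrient"] == nutrient) & (req["state"] == state)]
            if not rows.empty:
                state_ear[(nutrient, state)] = float(rows["ear"].iloc[0])

    bf_years = _regional_breastfeed_years(breastfeeding, regions, pop_y)
    asfr = fertility.set_index(["country", "age_low"])["asfr"]

    countries = sorted(regions["country"].unique())
    out = []
    for country in countries:
        for sex in SEXES:
            for age_low in AGE_BINS:
                for nutrient in NUTRIENTS:
                    ear_none = float(base[(nutrient, sex)][age_low])
                    ear = ear_none
                    if sex == "female" and age_low in REPRO_AGE_BINS:
                        a = float(asfr.get((country, age_low), 0.0))
                        preg, lact = reproductive_fractions(a, float(bf_years.get(country, 0.0)))
                        ear = weighted_ear(
                            preg,
                            lact,
                            ear_none,
                            state_ear.get((nutrient, "pregnant")),
                            state_ear.get((nutrient, "lactating")),
                        )
                    out.append(
                        {
                            "country": country,
                            "sex": sex,
                            "age_low": age_low,
                            "nutrient": nutrient,
                            "ear": ear,
                        }
                    )
    return pd.DataFrame(out)
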