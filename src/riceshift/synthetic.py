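"""Synthetic world generator.

Emits a complete, internally consistent set of input tables — supplies,
populations, fertility, breastfeeding, requirements, fortification
specs, CO2 loss factors, NTD burden, a dose-response table, regions and
vehicle consumption — so the whole pipeline runs and can be tested
without any external download.  Country identities and magnitudes are
deliberately fake; the statistical structure (rice-heavy diets, 5-year
age-sex strata, fertility concentrated at ages 20-34, burden scaling
with population) mirrors the real inputs.

All randomness flows from one ``numpy`` generator seeded from the
config; the draw order is fixed by the construction order of the tables
(regions, population, fertility, breastfeeding, supplies, fortification,
vehicle intake, burden), so one seed yields one byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AGE_BINS, NUTRIENTS, REPRO_AGE_BINS, SEXES, UNITS, ConfigError

#: default mean fractional change of rice nutrient density at ~580 ppm CO2
#: (negative = loss), with 95% CIs; magnitudes follow the 17-30% average
#: losses measured for B vitamins in FACE rice experiments.
DEFAULT_LOSS_MEANS: dict[str, float] = {"folate": -0.30, "thiamin": -0.17, "riboflavin": -0.17}
DEFAULT_LOSS_CIS: dict[str, tuple[float, float]] = {
    "folate": (-0.42, -0.17),
    "thiamin": (-0.28, -0.07),
    "riboflavin": (-0.26, -0.08),
}

#: adult baseline EARs used to anchor synthetic intake levels
_REFERENCE_EAR = {"folate": 320.0, "thiamin": 1.0, "riboflavin": 1.0833333333333333}

#: age-specific fertility shape (births/woman/year), scaled per country
_ASFR_SHAPE = {15: 0.03, 20: 0.10, 25: 0.14, 30: 0.12, 35: 0.07, 40: 0.03, 45: 0.01}

_FORTIFICANT = {"folate": "folic acid", "thiamin": "thiamin mononitrate", "riboflavin": "riboflavin"}
_LEVEL_RANGE = {"folate": (1.0, 2.5), "thiamin": (2.0, 8.0), "riboflavin": (1.5, 6.0)}

#: default quadratic absolute-risk curve (NTDs per 1000 births vs folate
#: ug/day), decreasing over [150, 500]; a synthetic stand-in shaped like
#: published folate dose-response data, not a reprint of it.
DEFAULT_DR_PARAMS: tuple[float, float, float] = (10.0, -0.031, 2.6e-5)
DEFAULT_DR_DOMAIN: tuple[float, float] = (150.0, 500.0)


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    n_countries: int = 10
    seed: int = 0
    rice_share_range: tuple[float, float] = (0.05, 0.70)
    mean_intake_multiplier_range: tuple[float, float] = (0.9, 2.0)
    fortified_country_fraction: float = 0.5
    loss_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOSS_MEANS))
    loss_cis: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_CIS)
    )
    #: annual NTD burden per million people: (deaths range, DALYs range)
    burden_rate_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"deaths": (1.0, 60.0), "dalys": (150.0, 6000.0)}
    )
    supply_se_frac: float = 0.10
    stratum_spread: float = 0.10
    year_current: int = 2010
    year_future: int = 2050

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        for name, (lo, hi) in (
            ("rice_share_range", self.rice_share_range),
            ("mean_intake_multiplier_range", self.mean_intake_multiplier_range),
        ):
            if lo > hi:
                raise ConfigError(f"{name} is not well-ordered: ({lo}, {hi})")
        if not 0 <= self.rice_share_range[0] <= self.rice_share_range[1] <= 1:
            raise ConfigError("rice_share_range must lie in [0, 1]")
        if self.mean_intake_multiplier_range[0] <= 0:
            raise ConfigError("mean intake multipliers must be > 0")
        if not 0 <= self.fortified_country_fraction <= 1:
            raise ConfigError("fortified_country_fraction must be in [0, 1]")


def default_requirements() -> pd.DataFrame:
    """RNI table on deliberately non-5-year source bins with EAR factors.

    RNI magnitudes follow the adult FAO/WHO recommendations for the three
    vitamins; the default EAR conversion factor of 1.2 corresponds to
    RNI = EAR x (1 + 2 x 0.10).
    """
    rows = []
    # (nutrient, sex, age_low, age_high, rni); age bins intentionally span
    # several 5-year bins (0-4, 4-9, 9-19, 19-51, 51-85) to exercise
    # harmonization.  Units: folate ug/day, others mg/day.
    base = {
        "folate": {0: 80, 4: 200, 9: 330, 19: 400, 51: 400},
        "thiamin": {0: 0.3, 4: 0.7, 9: 1.1, 19: 1.2, 51: 1.2},
        "riboflavin": {0: 0.4, 4: 0.8, 9: 1.2, 19: 1.3, 51: 1.3},
    }
    female_scale = {"folate": 1.0, "thiamin": 0.92, "riboflavin": 0.85}
    edges = [0, 4, 9, 19, 51, 85]
    for nutrient in NUTRIENTS:
        for sex in SEXES:
            scale = 1.0 if sex == "male" else female_scale[nutrient]
            for lo, hi in zip(edges[:-1], edges[1:]):
                rows.append(
                    {
                        "nutrient": nutrient,
                        "sex": sex,
                        "age_low": lo,
                        "age_high": hi,
                        "state": "none",
                        "rni": base[nutrient][lo] * scale,
                        "unit": UNITS[nutrient],
                        "ear_factor": 1.2,
                    }
                )
        preg = {"folate": 600, "thiamin": 1.4, "riboflavin": 1.4}
        lact = {"folate": 500, "thiamin": 1.5, "riboflavin": 1.6}
        for state, table in (("pregnant", preg), ("lactating", lact)):
            rows.append(
                {
                    "nutrient": nutrient,
                    "sex": "female",
                    "age_low": 15,
                    "age_high": 50,
                    "state": state,
                    "rni": table[nutrient],
                    "unit": UNITS[nutrient],
                    "ear_factor": 1.2,
                }
            )
    return pd.DataFrame(rows)


def generate_dose_response(
    points: int = 8,
    curve_params: tuple[float, ...] = DEFAULT_DR_PARAMS,
    seed: int = 0,
    noise_sd: float = 0.0,
    domain: tuple[float, float] = DEFAULT_DR_DOMAIN,
) -> pd.DataFrame:
    """Synthetic (intake, risk per 1000 births) table on a stated polynomial.

    The generating curve must be non-increasing over the emitted domain
    (NTD risk must not rise with folate); optional normal noise is added
    to the risks, floored away from zero.
    """
    if points < 3:
        raise ConfigError("need at least 3 dose-response points")
    coefs = np.asarray(curve_params, dtype=float)
    x = np.linspace(domain[0], domain[1], points)
    deriv = np.polynomial.polynomial.polyval(x, np.polynomial.polynomial.polyder(coefs))
    if np.any(deriv > 0):
        raise ConfigError("dose-response curve must be non-increasing over its domain")
    y = np.polynomial.polynomial.polyval(x, coefs)
    if np.any(y <= 0):
        raise ConfigError("dose-response risks must stay positive over the domain")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.maximum(y + rng.normal(0.0, noise_sd, size=points), 1e-6)
    return pd.DataFrame({"intake": x, "risk_per_1000": y})


def generate_world(config: WorldConfig) -> dict[str, pd.DataFrame]:
    """Build the full input bundle as {schema name: DataFrame}."""
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    countries = [f"C{i + 1:03d}" for i in range(n)]
    n_regions = min(n, 4)
    regions = pd.DataFrame(
        {"country": countries, "region": [f"R{i % n_regions + 1}" for i in range(n)]}
    )

    # population (2010 and 2050), decreasing-with-age pyramid
    age = np.array(AGE_BINS, dtype=float)
    shape = np.exp(-age / 45.0)
    shape = shape / shape.sum()
    pop_rows = []
    totals_2010 = {}
    for c in countries:
        total = 10.0 ** rng.uniform(6.0, 8.0)
        growth = rng.uniform(1.1, 1.6)
        sex_split = rng.uniform(0.49, 0.51)
        totals_2010[c] = total
        for sex, frac in (("female", sex_split), ("male", 1.0 - sex_split)):
            base = total * frac * shape
            for a, p in zip(AGE_BINS, base):
                pop_rows.append(
                    {"country": c, "year": config.year_current, "sex": sex,
                     "age_low": a, "population": round(p)}
                )
                pop_rows.append(
                    {"country": c, "year": config.year_future, "sex": sex,
                     "age_low": a, "population": round(p * growth)}
                )
    population = pd.DataFrame(pop_rows)

    fert_rows = []
    for c in countries:
        tfr_scale = rng.uniform(0.5, 1.5)
        for a in REPRO_AGE_BINS:
            fert_rows.append({"country": c, "age_low": a, "asfr": _ASFR_SHAPE[a] * tfr_scale})
    fertility = pd.DataFrame(fert_rows)

    breastfeeding = pd.DataFrame(
        {"country": countries, "mean_duration_months": rng.uniform(6.0, 24.0, size=n)}
    )

    # supplies: country-level mean anchored to the adult EAR, stratum-level
    # log-normal spread, fixed rice share, Dirichlet split of the rest
    supply_rows = []
    n_strata = len(SEXES) * len(AGE_BINS)
    for c in countries:
        for nutrient in NUTRIENTS:
            mult = rng.uniform(*config.mean_intake_multiplier_range)
            s_rice = rng.uniform(*config.rice_share_range)
            other_frac = rng.dirichlet([2.0, 2.0, 6.0])  # wheat, maize, other
            country_mean = _REFERENCE_EAR[nutrient] * mult
            spread = rng.lognormal(
                -0.5 * config.stratum_spread**2, config.stratum_spread, size=n_strata
            )
            i = 0
            for sex in SEXES:
                for a in AGE_BINS:
                    total = country_mean * spread[i]
                    i += 1
                    foods = {
                        "rice": s_rice * total,
                        "wheat flour": (1.0 - s_rice) * other_frac[0] * total,
                        "maize flour": (1.0 - s_rice) * other_frac[1] * total,
                        "other": (1.0 - s_rice) * other_frac[2] * total,
                    }
                    for food, supply in foods.items():
                        supply_rows.append(
                            {
                                "country": c,
                                "year": config.year_current,
                                "sex": sex,
                                "age_low": a,
                                "food": food,
                                "nutrient": nutrient,
                                "supply": supply,
                                "unit": UNITS[nutrient],
                                "se": config.supply_se_frac * supply,
                            }
                        )
    supplies = pd.DataFrame(supply_rows)

    n_fortified = int(round(config.fortified_country_fraction * n))
    fortified = list(rng.choice(countries, size=n_fortified, replace=False)) if n_fortified else []
    fort_rows = []
    for c in sorted(fortified):
        for vehicle in ("wheat flour", "rice", "maize flour"):
            for nutrient in NUTRIENTS:
                fort_rows.append(
                    {
                        "country": c,
                        "vehicle": vehicle,
                        "nutrient": nutrient,
                        "fortificant": _FORTIFICANT[nutrient],
                        "level_mg_per_kg": rng.uniform(*_LEVEL_RANGE[nutrient]),
                        "standardization_factor": rng.uniform(0.7, 1.0),
                        "pct_processed": rng.uniform(0.3, 0.95),
                        "pct_processed_fortified": rng.uniform(0.4, 1.0),
                    }
                )
    fortification = pd.DataFrame(
        fort_rows,
        columns=["country", "vehicle", "nutrient", "fortificant", "level_mg_per_kg",
                 "standardization_factor", "pct_processed", "pct_processed_fortified"],
    )

    veh_rows = []
    gram_range = {"rice": (30.0, 400.0), "wheat flour": (20.0, 300.0),
                  "maize flour": (0.0, 150.0), "other": (100.0, 400.0)}
    for c in countries:
        for food, (lo, hi) in gram_range.items():
            veh_rows.append({"country": c, "food": food, "grams_per_day": rng.uniform(lo, hi)})
    vehicle_intake = pd.DataFrame(veh_rows)

    burden_rows = []
    for c in countries:
        for measure in ("deaths", "dalys"):
            rate = rng.uniform(*config.burden_rate_range[measure])
            mean = rate * totals_2010[c] / 1e6
            # right-skewed interval; the upper/lower half-width ratio stays
            # below the skew-normal's attainable maximum (~1.88)
            lo = mean * rng.uniform(0.70, 0.85)
            hi = mean + (mean - lo) * rng.uniform(1.0, 1.6)
            burden_rows.append(
                {"country": c, "measure": measure, "mean": mean, "lo95": lo, "hi95": hi}
            )
    burden = pd.DataFrame(burden_rows)

    loss_rows = []
    for nutrient in NUTRIENTS:
        mean = config.loss_means.get(nutrient, DEFAULT_LOSS_MEANS[nutrient])
        lo, hi = config.loss_cis.get(nutrient, (mean - 0.1, mean + 0.1))
        if not lo <= mean <= hi:
            raise ConfigError(f"loss CI does not bracket mean for {nutrient}")
        loss_rows.append(
            {"nutrient": nutrient, "mean_frac_change": mean, "lo95": lo, "hi95": hi}
        )
    loss_factors = pd.DataFrame(loss_rows)

    return {
        "regions": regions,
        "population": population,
        "fertility": fertility,
        "breastfeeding": breastfeeding,
        "requirements": default_requirements(),
        "supplies": supplies,
        "fortification": fortification,
        "vehicle_intake": vehicle_intake,
        "burden": burden,
        "loss_factors": loss_factors,
        "dose_response": generate_dose_response(seed=config.seed),
    }
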