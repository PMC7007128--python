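"""Fortification accounting: from fortificant specs to added nutrient supply.

National fortification programs specify a fortificant compound and a dose
per kilogram of a grain vehicle (wheat flour, rice, maize flour).  The
dose is converted to pure nutrient with the compound's standardization
factor (mass fraction of pure nutrient; where several candidate
compounds are listed their factors are averaged), scaled by the fraction
of the vehicle that is industrially processed and the fraction of
processed vehicle actually fortified, and multiplied by per-capita
vehicle consumption to give an added daily nutrient supply.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .model import NUTRIENTS, VEHICLES, ConfigError, DomainError

#: conversion from mg/day to each nutrient's canonical daily unit
_MG_TO_UNIT = {"folate": 1000.0, "thiamin": 1.0, "riboflavin": 1.0}


def fortificant_to_nutrient(level: float, factors: Iterable[float] | float) -> float:
    """mg fortificant/kg vehicle -> mg pure nutrient/kg vehicle.

    ``factors`` is one or more standardization factors in (0, 1]; multiple
    candidate compounds contribute their average factor.
    """
    if np.isscalar(factors):
        factors = [float(factors)]
    factors = [float(f) for f in factors]
    if not factors:
        raise ConfigError("at least one standardization factor is required")
    if level < 0:
        raise DomainError(f"fortification level must be >= 0, got {level}")
    if any(not 0 < f <= 1 for f in factors):
        raise DomainError(f"standardization factors must be in (0, 1], got {factors}")
    return level * float(np.mean(factors))


def effective_coverage(pct_processed: float, pct_processed_fortified: float) -> float:
    """Fraction of the national vehicle supply assumed fortified."""
    for name, v in (("pct_processed", pct_processed),
                    ("pct_processed_fortified", pct_processed_fortified)):
        if not 0 <= v <= 1:
            raise DomainError(f"{name} must be in [0, 1], got {v}")
    return pct_processed * pct_processed_fortified


def added_supply(
    vehicle_supply_g_per_day: float,
    pure_level_mg_per_kg: float,
    coverage: float,
    nutrient: str = "folate",
) -> float:
    """Added nutrient per person per day, in the nutrient's canonical unit.

    300 g/day of rice at 1.5 mg/kg folic acid with full coverage adds
    0.3 kg x 1.5 mg/kg = 0.45 mg = 450 ug folate per day.
    """
    if nutrient not in NUTRIENTS:
        raise DomainError(f"unknown nutrient {nutrient!r}")
    if min(vehicle_supply_g_per_day, pure_level_mg_per_kg, coverage) < 0:
        raise DomainError("added_supply arguments must be >= 0")
    mg_per_day = (vehicle_supply_g_per_day / 1000.0) * pure_level_mg_per_kg * coverage
    return mg_per_day * _MG_TO_UNIT[nutrient]


def national_added(fortification: pd.DataFrame, vehicle_intake: pd.DataFrame) -> pd.DataFrame:
    """National per-capita added supply: country, nutrient, added.

    Rows of the fortification table for the same country/vehicle/nutrient
    are treated as alternative fortificant compounds: their
    standardization factors are averaged at the level of the first row's
    dose (doses are expected to agree; the first is used).
    """
    grams = vehicle_intake.set_index(["country", "food"])["grams_per_day"]
    rows = []
    group_cols = ["country", "vehicle", "nutrient"]
    for (country, vehicle, nutrient), grp in fortification.groupby(group_cols, sort=True):
        level = float(grp["level_mg_per_kg"].iloc[0])
        pure = fortificant_to_nutrient(level, grp["standardization_factor"].tolist())
        cov = effective_coverage(
            float(grp["pct_processed"].iloc[0]),
            float(grp["pct_processed_fortified"].iloc[0]),
        )
        g = float(grams.get((country, vehicle), 0.0))
        rows.append(
            {
                "country": country,
                "nutrient": nutrient,
                "added": added_supply(g, pure, cov, nutrient),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["country", "nutrient", "added"])
    return (
        pd.DataFrame(rows)
        .groupby(["country", "nutrient"], as_index=False)["added"]
        .sum()
    )


def stratum_added(
    fortification: pd.DataFrame,
    vehicle_intake: pd.DataFrame,
    supplies: pd.DataFrame,
    population: pd.DataFrame,
    year: int = 2010,
) -> pd.DataFrame:
    """Allocate national added supply to age-sex strata.

    Fortification reaches people in proportion to how much of the vehicle
    they eat.  Stratum-level vehicle consumption is not observed directly,
    so each stratum's share is proxied by its supply of the nutrient from
    the fortified vehicles relative to the national population-weighted
    mean of that quantity; strata with no vehicle supply anywhere share
    uniformly.  The population-weighted mean of the allocated values
    equals the national per-capita addition by construction.

    Returns country, sex, age_low, nutrient, added (per-capita/day).
    """
    nat = national_added(fortification, vehicle_intake)
    pop = population[population["year"] == year].set_index(["country", "sex", "age_low"])[
        "population"
    ]
    veh = supplies[supplies["food"].isin(VEHICLES)]
    veh_sum = veh.groupby(["country", "sex", "age_low", "nutrient"])["supply"].sum()

    strata = population[population["year"] == year][["country", "sex", "age_low"]]
    out = strata.merge(pd.DataFrame({"nutrient": list(NUTRIENTS)}), how="cross")
    out = out.merge(nat, on=["country", "nutrient"], how="left")
    out["added"] = out["added"].fillna(0.0)
    out["vehicle_supply"] = [
        float(veh_sum.get((c, s, a, n), 0.0))
        for c, s, a, n in zip(out["country"], out["sex"], out["age_low"], out["nutrient"])
    ]
    out["pop"] = [float(pop.get((c, s, a), 0.0)) for c, s, a in
                  zip(out["country"], out["sex"], out["age_low"])]

    keys = [out["country"], out["nutrient"]]
    wsum = out.groupby(keys)["pop"].transform("sum")
    wv = out["pop"] * out["vehicle_supply"]
    wvsum = wv.groupby(keys).transform("sum")
    mean_v = np.where(wsum > 0, wvsum / np.maximum(wsum, 1e-300), 0.0)
    factor = np.where(mean_v > 0, out["vehicle_supply"] / np.maximum(mean_v, 1e-300), 1.0)
    out["added"] = out["added"] * factor
    return out[["country", "sex", "age_low", "nutrient", "added"]]
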