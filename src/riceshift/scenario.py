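"""Elevated-CO2 scenario arithmetic.

Growing rice at ~580 ppm CO2 lowers its B-vitamin density by a
nutrient-specific fractional loss.  For each stratum the post-CO2 intake
is the current intake scaled by the ratio of total supply after the rice
loss to total supply before it, fortificant additions included in both
numerator and denominator (fortification is unaffected by CO2 and so
buffers the loss).  Scaling a normal intake distribution multiplicatively
preserves its CV, so the cut-point method applies unchanged to the
scaled mean.  Prevalence differences are projected onto 2050 populations
under a constant-diet assumption.
"""

from __future__ import annotations

import numpy as np

from .model import DomainError, IntakeDistribution, RiceshiftError


def eco2_ratio(
    total_prefort: float,
    rice_prefort: float,
    frac_loss: float,
    fort_added: float = 0.0,
):
    """Ratio of elevated-CO2 to current total nutrient supply.

    (total - rice x loss + fortified) / (total + fortified).  Accepts
    scalars or aligned arrays.  ``frac_loss`` may be negative (a nutrient
    gain, producing a ratio > 1) but never exceeds 1.
    """
    total = np.asarray(total_prefort, dtype=float)
    rice = np.asarray(rice_prefort, dtype=float)
    loss = np.asarray(frac_loss, dtype=float)
    fort = np.asarray(fort_added, dtype=float)
    if np.any(rice > total * (1 + 1e-12)):
        raise RiceshiftError("rice supply exceeds total supply in a stratum")
    if np.any(loss > 1):
        raise DomainError("frac_loss cannot exceed 1")
    if np.any(rice < 0) or np.any(fort < 0):
        raise DomainError("supplies must be >= 0")
    denom = total + fort
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (total - rice * loss + fort) / denom
    out = np.where(denom > 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


def apply_scenario(dist: IntakeDistribution, ratio: float) -> IntakeDistribution:
    """Scale an intake distribution by the supply ratio (CV preserved)."""
    return dist.scaled(ratio)


def newly_at_risk(prev_current: float, prev_eco2: float, population_2050: float):
    """Head-count pushed below the cut-point, on the 2050 population.

    Negative when the ratio exceeds 1 (a sampled nutrient gain); reported
    as negative, never clamped.
    """
    prev_current = np.asarray(prev_current, dtype=float)
    prev_eco2 = np.asarray(prev_eco2, dtype=float)
    if np.any((prev_current < 0) | (prev_current > 1) | (prev_eco2 < 0) | (prev_eco2 > 1)):
        raise DomainError("prevalences must be in [0, 1]")
    if np.any(np.asarray(population_2050, dtype=float) < 0):
        raise DomainError("population must be >= 0")
    out = (prev_eco2 - prev_current) * np.asarray(population_2050, dtype=float)
    return float(out) if out.ndim == 0 else out


def offset_cost(
    daily_loss_ug: float,
    fort_level_mg_per_kg: float = 1.5,
    cost_per_ton: float = 10.0,
) -> float:
    """USD per person per year to offset a folate loss by rice fortification.

    The rice mass that carries ``daily_loss_ug`` of folic acid at the
    given fortification level, accumulated over a year and priced per ton
    of fortified rice.  At the global average level of 1.5 mg/kg and
    $10/ton, an 11 ug/day loss costs about $0.027 per person-year.
    """
    if daily_loss_ug < 0:
        raise DomainError(f"daily loss must be >= 0, got {daily_loss_ug}")
    if fort_level_mg_per_kg <= 0 or cost_per_ton <= 0:
        raise DomainError("fortification level and cost must be > 0")
    kg_per_day = (daily_loss_ug / 1000.0) / fort_level_mg_per_kg
    tons_per_year = kg_per_day * 365.0 / 1000.0
    return tons_per_year * cost_per_ton
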