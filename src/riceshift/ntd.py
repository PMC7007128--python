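"""Folate -> neural-tube-defect burden via the comparative risk assessment
framework.

A polynomial is least-squares fitted through (folate intake, NTD risk)
points on the absolute risk scale; relative risk is the fitted risk
normalized to the reference intake (the highest observed intake, i.e.
best observed folate status), clamped below at 1 and evaluated with
domain clamping so the polynomial is never extrapolated beyond the data.
The exposure-weighted relative risk integrates RR over the (normal)
folate intake distribution of women of childbearing age, weighted across
age groups by births.  The potential impact fraction (PIF) is the
fractional rise of that exposure-weighted risk when intakes shift, and
multiplies the current national NTD burden to give attributable deaths
and DALYs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import (
    BurdenRecord,
    DomainError,
    FitError,
    IntakeDistribution,
    NumericError,
)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Polynomial risk curve with reference normalization and clamping."""

    coefficients: tuple[float, ...]  # ascending powers, absolute risk scale
    domain: tuple[float, float]
    reference_intake: float
    rr_floor: float = 1.0

    def risk(self, x):
        """Fitted absolute risk, with intakes clamped into the domain."""
        xc = np.clip(np.asarray(x, dtype=float), self.domain[0], self.domain[1])
        return np.polynomial.polynomial.polyval(xc, np.asarray(self.coefficients))

    def rr(self, x):
        """Relative risk vs the reference intake, floored at ``rr_floor``."""
        ref = np.polynomial.polynomial.polyval(
            self.reference_intake, np.asarray(self.coefficients)
        )
        out = np.maximum(self.risk(x) / ref, self.rr_floor)
        return float(out) if np.ndim(x) == 0 else out


def fit_rr_curve(
    intakes,
    risks,
    degree: int = 2,
    reference_intake: float | None = None,
) -> DoseResponseCurve:
    """Least-squares polynomial through the dose-response points.

    The fit happens on the absolute risk scale; the curve must come out
    positive and non-increasing over the observed intake range, otherwise
    the fit is rejected (a lower degree usually repairs a sign failure,
    and an increasing fit would mean NTD risk rising with folate).
    """
    x = np.asarray(intakes, dtype=float)
    y = np.asarray(risks, dtype=float)
    if len(x) < degree + 1:
        raise FitError(f"need at least {degree + 1} points for degree {degree}")
    if len(np.unique(x)) != len(x):
        raise FitError("dose-response intakes must be distinct")
    coefs = np.polynomial.polynomial.polyfit(x, y, degree)
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, 2001)
    vals = np.polynomial.polynomial.polyval(grid, coefs)
    if np.any(vals <= 0):
        raise FitError(
            "fitted polynomial is non-positive inside the intake domain; try a lower degree"
        )
    dvals = np.polynomial.polynomial.polyval(grid, np.polynomial.polynomial.polyder(coefs))
    slope_scale = float(np.abs(vals).max()) / max(hi - lo, 1e-300)
    if np.any(dvals > 1e-6 * slope_scale):  # flat is fine, increasing is not
        raise FitError("fitted dose-response curve increases with folate intake; rejected")
    ref = float(x.max()) if reference_intake is None else float(reference_intake)
    return DoseResponseCurve(tuple(float(c) for c in coefs), (lo, hi), ref)


_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _phi(x, means, sds):
    z = (x - means) / sds
    return np.exp(-0.5 * z * z) * _INV_SQRT_2PI / sds


def _simpson_segment(lo, hi, means, sds, curve: DoseResponseCurve, n: int):
    """Composite Simpson of RR(x) phi(x) on per-row intervals [lo, hi]."""
    t = np.linspace(0.0, 1.0, n + 1)  # n even
    x = lo[:, None] + (hi - lo)[:, None] * t[None, :]
    f = curve.rr(x) * _phi(x, means[:, None], sds[:, None])
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    h = (hi - lo) / n
    return (f * w[None, :]).sum(axis=1) * h / 3.0


def _simpson_ewr(means, sds, curve: DoseResponseCurve, n: int):
    """Integral of RR(x) phi(x) over [max(0, mean - 5 sd), mean + 5 sd].

    The integration range is split at the dose-response domain edges,
    where the clamped RR has derivative kinks, so each Simpson piece sees
    a smooth integrand.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    lo = np.maximum(0.0, means - 5 * sds)
    hi = means + 5 * sds
    d_lo = np.clip(curve.domain[0], lo, hi)
    d_hi = np.clip(curve.domain[1], lo, hi)
    total = np.zeros_like(lo)
    for a, b in ((lo, d_lo), (d_lo, d_hi), (d_hi, hi)):
        total += _simpson_segment(a, b, means, sds, curve, n)
    return total


def exposure_weighted_rr(
    dist: IntakeDistribution,
    curve: DoseResponseCurve,
    rel_tol: float = 1e-8,
) -> float:
    """Mean RR over the intake distribution.

    Composite Simpson quadrature of RR(x) phi(x) over
    [max(0, mean - 5 sd), mean + 5 sd] with grid doubling until the
    relative change falls below ``rel_tol``, normalized by the (analytic)
    normal mass of the same interval so a flat RR = 1 curve yields
    exactly 1.
    """
    return float(exposure_weighted_rr_many([dist.mean], [dist.sd], curve, rel_tol)[0])


def exposure_weighted_rr_many(means, sds, curve: DoseResponseCurve, rel_tol: float = 1e-8):
    """Vectorized grid-doubling Simpson EWR for many (mean, sd) pairs."""
    means_a = np.atleast_1d(np.asarray(means, dtype=float))
    sds_a = np.atleast_1d(np.asarray(sds, dtype=float))
    lo = np.maximum(0.0, means_a - 5 * sds_a)
    hi = means_a + 5 * sds_a
    mass = norm.cdf((hi - means_a) / sds_a) - norm.cdf((lo - means_a) / sds_a)
    prev = _simpson_ewr(means, sds, curve, 64)
    n = 128
    while n <= 2**16:
        cur = _simpson_ewr(means, sds, curve, n)
        rel = np.max(np.abs(cur - prev) / np.maximum(np.abs(cur), 1e-300))
        if rel <= rel_tol:
            return cur / mass
        prev = cur
        n *= 2
    raise NumericError("exposure-weighted RR quadrature failed to converge")


def potential_impact_fraction(
    dist_current: IntakeDistribution,
    dist_eco2: IntakeDistribution,
    curve: DoseResponseCurve,
) -> float:
    """(EWR_eco2 - EWR_current) / EWR_current for one exposure group."""
    ewr = exposure_weighted_rr_many(
        [dist_current.mean, dist_eco2.mean], [dist_current.sd, dist_eco2.sd], curve
    )
    return float((ewr[1] - ewr[0]) / ewr[0])


def discrete_pif(points_current, points_eco2, weights, curve: DoseResponseCurve) -> float:
    """PIF for a discrete exposure distribution over matched support points.

    Both exposure sets share the same weights; the PIF is the ratio of
    the weighted mean RRs minus one.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise DomainError("weights must be >= 0 with positive sum")
    w = w / w.sum()
    num = float(np.dot(w, curve.rr(np.asarray(points_eco2, dtype=float))))
    den = float(np.dot(w, curve.rr(np.asarray(points_current, dtype=float))))
    return num / den - 1.0


def mixture_pif(means_current, means_eco2, sds_current, sds_eco2, weights,
                curve: DoseResponseCurve) -> float:
    """PIF for a birth-weighted mixture of age-group exposure distributions.

    The exposure-weighted RR of a mixture is the weighted mean of the
    component EWRs, so the PIF compares the two weighted means.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise DomainError("mixture weights must be >= 0 with positive sum")
    w = w / w.sum()
    ewr_cur = exposure_weighted_rr_many(means_current, sds_current, curve)
    ewr_e = exposure_weighted_rr_many(means_eco2, sds_eco2, curve)
    num = float(np.dot(w, ewr_e))
    den = float(np.dot(w, ewr_cur))
    return (num - den) / den


def attributable_burden(pif: float, burden: BurdenRecord) -> float:
    """Additional annual burden attributable to the intake shift."""
    return pif * burden.value.mean
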