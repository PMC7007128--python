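"""Dose-response fitting, exposure-weighted RR and the PIF."""

import numpy as np
import pytest

from riceshift import (
    IntakeDistribution,
    attributable_burden,
    exposure_weighted_rr,
    fit_rr_curve,
    potential_impact_fraction,
)
from riceshift.model import BurdenRecord, FitError, UncertainQuantity
from riceshift.ntd import discrete_pif, exposure_weighted_rr_many, mixture_pif

P = np.polynomial.polynomial

QUAD = (10.0, -0.031, 2.6e-5)  # decreasing, positive on [150, 500]


def _points(n=8, coefs=QUAD, lo=150, hi=500):
    x = np.linspace(lo, hi, n)
    return x, P.polyval(x, np.asarray(coefs))


class TestFit:
    def test_exact_quadratic_recovered(self):
        x, y = _points()
        curve = fit_rr_curve(x, y, degree=2)
        assert np.allclose(curve.coefficients, QUAD, rtol=1e-9)

    def test_three_points_interpolated_exactly(self):
        x, y = _points(n=3)
        curve = fit_rr_curve(x, y, degree=2)
        assert np.allclose(curve.coefficients, QUAD, rtol=1e-9)

    def test_constant_risk_gives_unit_rr(self):
        x = np.linspace(150, 500, 6)
        curve = fit_rr_curve(x, np.full(6, 2.5), degree=2)
        probe = np.linspace(100, 600, 50)
        assert np.allclose(curve.rr(probe), 1.0, atol=1e-9)

    def test_noisy_fit_matches_normal_equations(self):
        """Residuals agree with an independent least-squares solve."""
        rng = np.random.default_rng(8)
        x, y = _points(n=12)
        y = y + rng.normal(0, 0.05, size=len(y))
        curve = fit_rr_curve(x, y, degree=2)
        design = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(curve.coefficients, beta, rtol=1e-9)

    def test_reference_is_highest_intake(self):
        x, y = _points()
        curve = fit_rr_curve(x, y, degree=2)
        assert curve.reference_intake == x.max()
        assert curve.rr(x.max()) == pytest.approx(1.0)

    def test_increasing_curve_rejected(self):
        x = np.linspace(150, 500, 6)
        with pytest.raises(FitError, match="increases"):
            fit_rr_curve(x, 1.0 + 0.01 * x, degree=1)

    def test_rr_clamped_at_domain_and_floor(self):
        x, y = _points()
        curve = fit_rr_curve(x, y, degree=2)
        assert curve.rr(50.0) == pytest.approx(curve.rr(150.0))
        assert curve.rr(10_000.0) == 1.0  # floored, never protective


class TestExposureWeightedRR:
    def test_flat_curve_gives_one(self):
        x = np.linspace(150, 500, 5)
        curve = fit_rr_curve(x, np.full(5, 3.0), degree=2)
        ewr = exposure_weighted_rr(IntakeDistribution(300.0, 0.3), curve)
        assert ewr == pytest.approx(1.0, abs=1e-9)

    def test_linear_rr_recovers_value_at_mean(self):
        """A linear RR under a symmetric density averages to RR(mean)."""
        x = np.linspace(10, 2000, 5)
        curve = fit_rr_curve(x, 5.0 - 0.002 * x, degree=1)
        dist = IntakeDistribution(600.0, 0.05)  # +-5 sd well inside the domain
        assert exposure_weighted_rr(dist, curve) == pytest.approx(curve.rr(600.0), rel=1e-7)

    def test_matches_sampling_oracle_for_random_quadratics(self):
        rng = np.random.default_rng(77)
        n = 10**6
        for _ in range(3):
            a = rng.uniform(5, 15)
            b = -rng.uniform(0.01, 0.03)
            c = rng.uniform(0, -b / 1100)  # vertex beyond the domain: decreasing
            x = np.linspace(150, 500, 9)
            y = P.polyval(x, [a, b, c])
            if (y <= 0).any():
                continue
            curve = fit_rr_curve(x, y, degree=2)
            dist = IntakeDistribution(rng.uniform(250, 450), 0.3)
            draws = rng.normal(dist.mean, dist.sd, size=n)
            keep = np.abs(draws - dist.mean) <= 5 * dist.sd
            keep &= draws >= 0
            sample = curve.rr(draws[keep])
            mc, se = float(sample.mean()), float(sample.std(ddof=1) / np.sqrt(keep.sum()))
            quad = exposure_weighted_rr(dist, curve)
            assert abs(quad - mc) <= 3 * se


class TestPif:
    def _curve(self):
        x, y = _points()
        return fit_rr_curve(x, y, degree=2)

    def test_identical_distributions_give_zero(self):
        d = IntakeDistribution(350.0, 0.3)
        assert potential_impact_fraction(d, d, self._curve()) == pytest.approx(0.0, abs=1e-12)

    def test_flat_curve_gives_zero(self):
        x = np.linspace(150, 500, 5)
        flat = fit_rr_curve(x, np.full(5, 2.0), degree=2)
        pif = potential_impact_fraction(
            IntakeDistribution(400.0, 0.3), IntakeDistribution(300.0, 0.3), flat
        )
        assert pif == pytest.approx(0.0, abs=1e-9)

    def test_two_point_discrete_exposure_brute_force(self):
        """Shifting {300: 0.5, 500: 0.5} to {280: 0.5, 470: 0.5} matches the
        weighted-RR ratio computed by hand from the raw polynomial."""
        curve = self._curve()

        def risk(x):  # independent arithmetic, no curve machinery
            return QUAD[0] + QUAD[1] * x + QUAD[2] * x * x

        hand = (0.5 * risk(280) + 0.5 * risk(470)) / (
            0.5 * risk(300) + 0.5 * risk(500)
        ) - 1.0
        pif = discrete_pif([300.0, 500.0], [280.0, 470.0], [0.5, 0.5], curve)
        assert pif == pytest.approx(hand, rel=1e-9)

    def test_narrow_mixture_components_approach_discrete_pif(self):
        """Interior point masses are the sd -> 0 limit of normal components."""
        curve = self._curve()
        hand = discrete_pif([300.0, 480.0], [280.0, 450.0], [0.5, 0.5], curve)
        pif = mixture_pif(
            [300.0, 480.0], [280.0, 450.0],
            [0.3, 0.48], [0.28, 0.45],
            [0.5, 0.5], curve,
        )
        assert pif == pytest.approx(hand, abs=1e-6)

    def test_lowering_intake_never_decreases_pif(self):
        curve = self._curve()
        base = IntakeDistribution(400.0, 0.3)
        pifs = [
            potential_impact_fraction(base, IntakeDistribution(m, 0.3), curve)
            for m in (390.0, 360.0, 330.0, 300.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(pifs, pifs[1:]))
        assert pifs[-1] > 0


class TestAttributableBurden:
    def _burden(self, mean):
        return BurdenRecord("X", "dalys", UncertainQuantity(mean, mean * 0.8, mean * 1.3))

    def test_zero_pif_zero_burden(self):
        assert attributable_burden(0.0, self._burden(1000.0)) == 0.0

    def test_product(self):
        assert attributable_burden(0.01, self._burden(1000.0)) == pytest.approx(10.0)

    def test_linear_in_both(self):
        b = self._burden(500.0)
        assert attributable_burden(0.04, b) == pytest.approx(4 * attributable_burden(0.01, b))
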