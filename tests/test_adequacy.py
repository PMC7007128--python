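"""EAR cut-point method: closed form, sampling oracle, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riceshift import IntakeDistribution, aggregate, population_at_risk, prevalence_inadequate
from riceshift.adequacy import compute_adequacy
from riceshift.model import CoverageError, DomainError


class TestPrevalence:
    def test_mean_at_cutpoint_gives_half(self):
        assert prevalence_inadequate(IntakeDistribution(350.0), 350.0) == pytest.approx(0.5)

    def test_one_sd_below_and_above(self):
        d = IntakeDistribution(400.0, cv=0.3)  # sd = 120
        assert prevalence_inadequate(d, 280.0) == pytest.approx(0.158655, abs=1e-6)
        assert prevalence_inadequate(d, 520.0) == pytest.approx(0.841345, abs=1e-6)

    def test_nonpositive_ear_rejected(self):
        with pytest.raises(DomainError):
            prevalence_inadequate(IntakeDistribution(400.0), 0.0)

    def test_matches_sampling_oracle(self):
        """Closed form vs fraction of normal draws below the EAR (3 binomial SE)."""
        rng = np.random.default_rng(2024)
        n = 100_000
        for _ in range(20):
            mean = rng.uniform(200, 600)
            ear = rng.uniform(150, 450)
            p = prevalence_inadequate(IntakeDistribution(mean, 0.3), ear)
            draws = rng.normal(mean, 0.3 * mean, size=n)
            p_hat = float(np.mean(draws < ear))
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(p - p_hat) <= 3 * se + 1e-9

    @given(
        mean=st.floats(100, 1000),
        cv=st.floats(0.2, 0.6),
        ear_frac=st.floats(0.5, 1.5),  # keep z-scores away from CDF saturation
        bump=st.floats(1, 50),
    )
    def test_monotone_in_ear_and_mean(self, mean, cv, ear_frac, bump):
        ear = ear_frac * mean
        base = prevalence_inadequate(IntakeDistribution(mean, cv), ear)
        assert prevalence_inadequate(IntakeDistribution(mean, cv), ear + bump) > base
        assert prevalence_inadequate(IntakeDistribution(mean + bump, cv), ear) < base

    @given(mean=st.floats(100, 1000), ear=st.floats(50, 900), scale=st.floats(0.1, 10))
    def test_scale_invariance(self, mean, ear, scale):
        a = prevalence_inadequate(IntakeDistribution(mean, 0.3), ear)
        b = prevalence_inadequate(IntakeDistribution(mean * scale, 0.3), ear * scale)
        assert a == pytest.approx(b, abs=1e-12)


class TestHeadCount:
    def test_examples(self):
        assert population_at_risk(0.0, 5e6) == 0.0
        assert population_at_risk(0.1587, 1_000_000) == pytest.approx(158_700)
        assert population_at_risk(1.0, 1234.0) == 1234.0

    def test_out_of_range_prevalence_rejected(self):
        with pytest.raises(DomainError):
            population_at_risk(1.5, 100)


def _mini_results():
    return pd.DataFrame(
        {
            "country": ["A", "A", "B", "B"],
            "sex": ["female"] * 4,
            "age_low": [20, 25, 20, 25],
            "nutrient": ["folate"] * 4,
            "scenario": ["current"] * 4,
            "prevalence": [0.1, 0.3, 0.2, 0.4],
            "population_at_risk": [100.0, 300.0, 400.0, 800.0],
        }
    )


def _mini_population():
    return pd.DataFrame(
        {
            "country": ["A", "A", "B", "B"],
            "year": [2010] * 4,
            "sex": ["female"] * 4,
            "age_low": [20, 25, 20, 25],
            "population": [1000.0, 1000.0, 2000.0, 2000.0],
        }
    )


class TestAggregate:
    def test_equal_population_strata_average(self):
        regions = pd.DataFrame({"country": ["A", "B"], "region": ["R1", "R2"]})
        out = aggregate(_mini_results(), regions, _mini_population(), "region")
        r1 = out[out["scope"] == "R1"].iloc[0]
        assert r1["prevalence"] == pytest.approx(0.2)
        assert r1["population_at_risk"] == pytest.approx(400.0)

    def test_single_country_region_is_identity(self):
        regions = pd.DataFrame({"country": ["A", "B"], "region": ["RA", "RB"]})
        res = _mini_results().iloc[:2]
        out = aggregate(res, regions, _mini_population(), "region")
        assert out[out["scope"] == "RA"]["population_at_risk"].iloc[0] == pytest.approx(400.0)

    def test_global_headcount_is_sum_of_regions(self):
        regions = pd.DataFrame({"country": ["A", "B"], "region": ["R1", "R2"]})
        by_region = aggregate(_mini_results(), regions, _mini_population(), "region")
        world = aggregate(_mini_results(), regions, _mini_population(), "global")
        assert world["population_at_risk"].iloc[0] == pytest.approx(
            by_region["population_at_risk"].sum()
        )

    def test_missing_country_raises(self):
        regions = pd.DataFrame({"country": ["A"], "region": ["R1"]})
        with pytest.raises(CoverageError):
            aggregate(_mini_results(), regions, _mini_population(), "region")


class TestComputeAdequacy:
    def test_zero_mean_strata_excluded_with_warning(self, caplog):
        means = pd.DataFrame(
            {
                "country": ["A", "A"], "sex": ["female"] * 2, "age_low": [20, 25],
                "nutrient": ["folate"] * 2, "mean": [400.0, 0.0],
            }
        )
        ears = means[["country", "sex", "age_low", "nutrient"]].assign(ear=320.0)
        with caplog.at_level("WARNING"):
            out = compute_adequacy(means, ears, _mini_population())
        assert len(out) == 1
        assert "excluding" in caplog.text
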