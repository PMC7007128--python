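"""EAR construction: conversion, age harmonization, reproductive weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riceshift import (
    build_ear_table,
    harmonize_age_bins,
    lactating_fraction,
    pregnant_fraction,
    rni_to_ear,
    weighted_ear,
)
from riceshift.model import CoverageError, DomainError
from riceshift.requirements import reproductive_fractions
from riceshift.synthetic import WorldConfig, generate_world


class TestRniToEar:
    def test_arithmetic(self):
        assert rni_to_ear(1.2, 1.2) == pytest.approx(1.0)
        assert rni_to_ear(400, 1.25) == pytest.approx(320)

    def test_identity_factor(self):
        assert rni_to_ear(1.3, 1.0) == 1.3

    @pytest.mark.parametrize("rni,factor", [(0, 1.2), (-1, 1.2), (1.2, 0), (1.2, -2)])
    def test_nonpositive_inputs_rejected(self, rni, factor):
        with pytest.raises(DomainError):
            rni_to_ear(rni, factor)


def _pop(pairs):
    return pd.DataFrame(pairs, columns=["age_low", "population"])


class TestHarmonize:
    def test_containment_copies_value(self):
        src = pd.DataFrame([{"age_low": 10, "age_high": 20, "value": 7.0}])
        pop = _pop([(10, 100), (15, 300)])
        out = harmonize_age_bins(src, pop, [(10, 15), (15, 20)])
        assert list(out["value"]) == [7.0, 7.0]

    def test_population_weighted_average(self):
        src = pd.DataFrame(
            [
                {"age_low": 10, "age_high": 15, "value": 1.0},
                {"age_low": 15, "age_high": 25, "value": 3.0},
            ]
        )
        pop = _pop([(10, 500), (15, 500), (20, 500)])
        out = harmonize_age_bins(src, pop, [(10, 20)])
        assert out["value"].iloc[0] == pytest.approx(2.0)

    def test_zero_population_segment_falls_back_to_populated_one(self):
        src = pd.DataFrame(
            [
                {"age_low": 10, "age_high": 15, "value": 1.0},
                {"age_low": 15, "age_high": 20, "value": 3.0},
            ]
        )
        pop = _pop([(10, 0), (15, 800)])
        out = harmonize_age_bins(src, pop, [(10, 20)])
        assert out["value"].iloc[0] == pytest.approx(3.0)

    def test_uncovered_target_bin_raises(self):
        src = pd.DataFrame([{"age_low": 10, "age_high": 15, "value": 1.0}])
        with pytest.raises(CoverageError, match=r"\[10, 20\)"):
            harmonize_age_bins(src, _pop([(10, 1)]), [(10, 20)])

    def test_exact_when_binnings_coincide(self):
        values = [2.0, 5.0, 9.0]
        src = pd.DataFrame(
            [
                {"age_low": a, "age_high": a + 5, "value": v}
                for a, v in zip([10, 15, 20], values)
            ]
        )
        pop = _pop([(10, 11), (15, 13), (20, 17)])
        out = harmonize_age_bins(src, pop, [(10, 15), (15, 20), (20, 25)])
        assert list(out["value"]) == values


class TestReproductiveFractions:
    def test_pregnant_fraction_basics(self):
        assert pregnant_fraction(0.0) == 0.0
        assert pregnant_fraction(0.1) == pytest.approx(0.1 * 40 / 52)
        assert pregnant_fraction(2.0) == 1.0  # capped

    def test_lactating_fraction_basics(self):
        assert lactating_fraction(0.1, 0.0) == 0.0
        assert lactating_fraction(0.1, 1.0) == pytest.approx(0.1)

    def test_joint_rescale_preserves_ratio(self):
        preg, lact = reproductive_fractions(1.0, 0.8)
        raw_preg, raw_lact = 1.0 * 40 / 52, 0.8
        assert preg + lact == pytest.approx(1.0)
        assert preg / lact == pytest.approx(raw_preg / raw_lact)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            pregnant_fraction(-0.1)
        with pytest.raises(DomainError):
            lactating_fraction(0.1, -1.0)


class TestWeightedEar:
    def test_no_reproduction_returns_baseline(self):
        assert weighted_ear(0.0, 0.0, 320.0) == 320.0

    def test_blend_arithmetic(self):
        assert weighted_ear(0.1, 0.1, 320, 520, 450) == pytest.approx(353.0)

    def test_equal_state_ears_invariant_to_fractions(self):
        assert weighted_ear(0.3, 0.2, 400, 400, 400) == pytest.approx(400.0)

    @given(
        preg=st.floats(0, 0.5),
        lact=st.floats(0, 0.5),
        ears=st.tuples(
            st.floats(100, 500), st.floats(100, 700), st.floats(100, 700)
        ),
    )
    def test_convexity(self, preg, lact, ears):
        """The blended EAR stays inside the hull of the state EARs."""
        value = weighted_ear(preg, lact, *ears)
        assert min(ears) - 1e-9 <= value <= max(ears) + 1e-9

    @given(
        asfr=st.floats(0, 0.4),
        bump=st.floats(0, 0.2),
        bf_years=st.floats(0, 2),
    )
    def test_monotone_in_fertility_when_reproductive_ears_higher(self, asfr, bump, bf_years):
        ear_none, ear_p, ear_l = 320.0, 520.0, 450.0
        lo = weighted_ear(*reproductive_fractions(asfr, bf_years), ear_none, ear_p, ear_l)
        hi = weighted_ear(*reproductive_fractions(asfr + bump, bf_years), ear_none, ear_p, ear_l)
        assert hi >= lo - 1e-9


@pytest.fixture(scope="module")
def ear_world():
    return generate_world(WorldConfig(n_countries=3, seed=5))


@pytest.fixture(scope="module")
def ear_table(ear_world):
    world = ear_world
    return build_ear_table(
        world["requirements"], world["population"], world["fertility"],
        world["breastfeeding"], world["regions"],
    )


class TestBuildEarTable:
    def test_covers_every_stratum_and_nutrient(self, ear_world, ear_table):
        strata = ear_world["population"].query("year == 2010")[["country", "sex", "age_low"]]
        assert len(ear_table) == len(strata.drop_duplicates()) * 3
        assert (ear_table["ear"] > 0).all()

    def test_reproductive_strata_have_elevated_folate_ear(self, ear_table):
        """Pregnancy and lactation raise the folate requirement of women 15-49
        above the same-age baseline (which here equals the male value)."""
        fol = ear_table.query("nutrient == 'folate'")
        female = fol.query("sex == 'female'").set_index(["country", "age_low"])["ear"]
        male = fol.query("sex == 'male'").set_index(["country", "age_low"])["ear"]
        repro = [idx for idx in female.index if 15 <= idx[1] <= 45]
        assert (female[repro] >= male[repro] - 1e-12).all()
        assert (female[repro] > male[repro] + 1e-9).any()

    def test_regional_fallback_for_missing_breastfeeding(self, ear_world):
        world = ear_world
        partial = world["breastfeeding"].iloc[:1]  # only the first country reports
        ears = build_ear_table(
            world["requirements"], world["population"], world["fertility"],
            partial, world["regions"],
        )
        assert (ears["ear"] > 0).all()
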