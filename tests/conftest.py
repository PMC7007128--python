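import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from riceshift import MonteCarloConfig, RunConfig, WorldConfig
from riceshift import pipeline, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """Five-country synthetic world shared by read-only tests."""
    return synthetic.generate_world(WorldConfig(n_countries=5, seed=7))


@pytest.fixture(scope="session")
def compiled_small_world(small_world):
    config = RunConfig(mc=MonteCarloConfig(n_draws=10, seed=1))
    return pipeline.compile_world(small_world, config)


def degenerate_world_config(**overrides) -> WorldConfig:
    """World with every uncertainty switched off (se 0, point CIs)."""
    means = dict(synthetic.DEFAULT_LOSS_MEANS)
    base = dict(
        n_countries=4,
        seed=11,
        supply_se_frac=0.0,
        loss_cis={k: (v, v) for k, v in means.items()},
    )
    base.update(overrides)
    return WorldConfig(**base)


def degenerate_burden(bundle) -> None:
    """Collapse the burden CIs onto the mean, in place."""
    bundle["burden"]["lo95"] = bundle["burden"]["mean"]
    bundle["burden"]["hi95"] = bundle["burden"]["mean"]
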