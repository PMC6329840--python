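import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heatrisk.config import RunConfig, SyntheticWorldConfig
from heatrisk import pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run() -> pipeline.RunResult:
    """One full pipeline run at the default study conditions (seed 0).

    Session-scoped because the hazard stage dominates runtime; every test that
    asserts a property of the default synthetic world shares this result.
    """
    return pipeline.run_all(RunConfig())


@pytest.fixture(scope="session")
def small_run() -> pipeline.RunResult:
    """A minimal run (8x8 grid, 200 years, 2 models) for structural checks."""
    cfg = RunConfig(world=SyntheticWorldConfig(years=200))
    return pipeline.run_all(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
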