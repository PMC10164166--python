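"""Shared fixtures: a small synthetic dataset reused across unit tests."""

import numpy as np
import pytest

from opdcast.io import PipelineConfig
from opdcast.synth import SynthConfig, TruthSurface, generate_stations, generate_trials


SMALL = dict(n_trials=120, n_stations=60, n_gcms=3)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(seed=42, **SMALL)


@pytest.fixture(scope="session")
def truth_surface() -> TruthSurface:
    return TruthSurface()


@pytest.fixture(scope="session")
def small_stations(small_config, truth_surface):
    return generate_stations(small_config, truth_surface)


@pytest.fixture(scope="session")
def small_trials(small_stations):
    trials, truth, weather = generate_trials(small_stations)
    return trials, truth, weather


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One complete small pipeline run shared by integration tests."""
    from opdcast.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(synth=dict(SMALL), n_trees=100, outdir=str(out))
    report, res = run_pipeline(cfg)
    return report, res, out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
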