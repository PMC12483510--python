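import numpy as np
import pytest

from pffpipe.config import PipelineConfig
from pffpipe.pipeline import run_pipeline
from pffpipe.synth import SessionConfig, make_session


def small_session_config(**overrides) -> SessionConfig:
    """A reduced synthetic session for fast unit tests (40 ROIs x 40 laps)."""
    kwargs = dict(
        n_rois=40,
        n_laps=40,
        n_btsp=4,
        n_non_btsp=3,
        n_drift=1,
        n_preexisting=8,
        n_solitary=2,
        formation_lap_range=(19, 27),
    )
    kwargs.update(overrides)
    return SessionConfig(**kwargs)


@pytest.fixture(scope="session")
def small_session():
    return make_session(small_session_config(), seed=1)


@pytest.fixture(scope="session")
def small_result(small_session):
    return run_pipeline(small_session, PipelineConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
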