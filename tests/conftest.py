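import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from t2rp.config import PipelineConfig
from t2rp.phantom import PhantomConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom() -> PhantomConfig:
    """Coarse-grid phantom for fast anatomy/dose/truth tests."""
    return PhantomConfig(
        grid_shape=(32, 32, 12),
        spacing_mm=(3.2, 3.2, 8.8),
        n_patients=6,
        seed=7,
    )


@pytest.fixture
def small_pipeline(small_phantom) -> PipelineConfig:
    return PipelineConfig(phantom=small_phantom, n_boot=100, seed=7)
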