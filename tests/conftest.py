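import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def affine_cal():
    """Affine dispersion calibration matching the simulator default λ = 500 + 2·Δpx."""
    from mimicscope import spectral as spec

    return spec.calibrate_dispersion(
        [((lam - 500.0) / 2.0, lam) for lam in (550.0, 620.0, 700.0)], order=1
    )
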