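import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from neoeit.preprocess import LungRoiMask, build_atlas_mask  # noqa: E402


@pytest.fixture(scope="session")
def atlas_mask32() -> LungRoiMask:
    return build_atlas_mask((32, 32))


@pytest.fixture
def tiny_mask() -> LungRoiMask:
    """4x4 all-lung mask: left = cols 0-1, right = cols 2-3, even row split."""
    in_lung = np.ones((4, 4), dtype=bool)
    side = np.ones((4, 4), dtype=np.int8)
    side[:, 2:] = 2
    ventral_weight = np.array([1.0, 1.0, 0.0, 0.0])
    return LungRoiMask(in_lung, side, ventral_weight, row_min=0, row_max=3)


def rel_err(measured: float, truth: float) -> float:
    if truth == 0:
        return abs(measured)
    return abs(measured - truth) / abs(truth)
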