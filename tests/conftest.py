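import numpy as np
import pytest

from texconcord.phantom import build_phantom_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_roi(rng, shape=(12, 12), ng=8, irregular=False):
    """Small random quantized-ready ROI: float image + boolean mask."""
    img = rng.integers(0, 256, size=shape).astype(float)
    mask = np.ones(shape, dtype=bool)
    if irregular:
        mask &= rng.random(shape) > 0.2
        if not mask.any():
            mask[shape[0] // 2, shape[1] // 2] = True
    return img, mask


@pytest.fixture(scope="session")
def small_series():
    """3 subjects, 3 matrix sizes, 2 slices: big enough to exercise the
    paired design, small enough for fast integration tests."""
    return build_phantom_series(
        n_subjects=3,
        matrix_sizes=(256, 384, 512),
        master_seed=42,
        n_slices=2,
    )
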