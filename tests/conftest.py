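import numpy as np
import pytest

from nufd.phantom import PhantomConfig, generate_phantom
from nufd.preprocess import discard_steady_state


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free full-size phantom (240 frames, 128x128) with ground truth."""
    cfg = PhantomConfig(noise_sigma=0.0, seed=17, anatomy_seed=42)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def phantom_clean_processed(phantom_clean):
    """Same phantom after steady-state discard (220 frames)."""
    cfg, series, truth = phantom_clean
    return cfg, discard_steady_state(series), truth


@pytest.fixture(scope="session")
def small_mask_phantom():
    """Cheap short phantom for geometry-only tests (masks, ROIs)."""
    cfg = PhantomConfig(n_frames=21, noise_sigma=0.0, seed=3, anatomy_seed=42)
    series, truth = generate_phantom(cfg)
    return series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
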