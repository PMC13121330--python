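import numpy as np
import pytest

from fapitbr.core import ImageVolume, make_affine
from fapitbr.phantom import KineticsConfig, LesionSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default-calibration phantom at 60/70/120 min."""
    cfg = PhantomConfig(noise_sd_frac=0.0, seed=11)
    return generate_phantom(cfg, KineticsConfig())


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default 10%-noise phantom."""
    cfg = PhantomConfig(seed=5)
    return generate_phantom(cfg, KineticsConfig())


@pytest.fixture()
def unit_grid():
    """Small 1 mm isotropic grid for hand-checkable geometry."""
    return ImageVolume(np.zeros((25, 25, 25)), make_affine(1.0), kind="SUV")
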