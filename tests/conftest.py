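import numpy as np
import pytest

from prostseg.cascade import CascadeSpec
from prostseg.phantom import PhantomConfig, generate_patient
from prostseg.preprocess import LocalizerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    """Small, fast phantom grid used across the suite."""
    return PhantomConfig(
        shape=(12, 64, 64),
        spacing=(4.0, 1.5, 1.5),
        gland_semiaxes_mean=(15.0, 17.0, 21.0),
        gland_semiaxes_sd=(1.0, 1.5, 1.5),
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """Minimal grid for bulk statistical tests."""
    return PhantomConfig(
        shape=(8, 32, 32),
        spacing=(4.0, 3.0, 3.0),
        gland_semiaxes_mean=(14.0, 16.0, 20.0),
        gland_semiaxes_sd=(1.0, 1.0, 1.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def phantom_case(small_config):
    return generate_patient(small_config, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def toy_cascade_spec():
    """Depth-2 cascade on 48x48 patches, sized for the small phantom grid."""
    return CascadeSpec(
        variant="bp",
        depth=2,
        base_width=8,
        patch_size=48,
        min_lesion_volume_mm3=25.0,
        localizer=LocalizerConfig(patch_size=48),
    )
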