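import numpy as np
import pytest

from octaquant import AcquisitionSetting, PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_phantom():
    """64-px phantom for fast structural tests."""
    return generate_phantom(5, PhantomParams(side=64))


@pytest.fixture(scope="session")
def retina_phantom():
    """256-px phantom at the cohort raster, for pipeline-accuracy tests."""
    return generate_phantom(3, PhantomParams(side=256))


@pytest.fixture
def clean_acq():
    """Noise-free, unattenuated spectral-domain setting."""
    return AcquisitionSetting.for_device("SD", ndf_od=0.0, seed=5,
                                         noise_floor=0.0)
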