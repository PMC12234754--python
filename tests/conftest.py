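import numpy as np
import pytest

from ramantis.core import SiteMetadata, Spectrum, WavenumberAxis
from ramantis.simulate import AcquisitionModel, TissueModel


@pytest.fixture
def axis():
    return WavenumberAxis.default()


@pytest.fixture
def coarse_axis():
    """The 500..3300 cm^-1 axis in 20 cm^-1 steps (141 channels)."""
    return WavenumberAxis(np.arange(500.0, 3301.0, 20.0))


@pytest.fixture
def tissue():
    return TissueModel()


@pytest.fixture
def acq():
    return AcquisitionModel()


@pytest.fixture
def healthy_meta():
    return SiteMetadata("P001", "oral cavity", "healthy", subgroup="tongue")


@pytest.fixture
def band_model(axis, tissue):
    """Noiseless sum of the default planted bands (healthy amplitudes)."""
    amps = np.array([b.amp_healthy for b in tissue.bands])
    return Spectrum(axis, amps @ tissue.band_profiles(axis))


def make_spectrum(values, lo=500.0, step=10.0):
    values = np.asarray(values, dtype=float)
    ax = WavenumberAxis(lo + step * np.arange(values.size))
    return Spectrum(ax, values)
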