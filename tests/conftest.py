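import numpy as np
import pytest

from sifyield import synthetic
from sifyield.spectra import Spectrum, SpectrumKind


@pytest.fixture(scope="session")
def wl_cam():
    return synthetic.camera_grid()


@pytest.fixture(scope="session")
def wl_fine():
    return synthetic.spectrometer_grid()


@pytest.fixture(scope="session")
def irradiance(wl_fine):
    return synthetic.make_irradiance(wl_fine)


@pytest.fixture(scope="session")
def materials(wl_fine):
    return synthetic.default_materials(wl_fine, phi_f=0.03)


@pytest.fixture()
def small_scene(materials, irradiance):
    """Noiseless 12 x 64 six-material scene on the camera grid."""
    layout = synthetic.default_layout(12, 64)
    return synthetic.make_scene(materials, layout, irradiance, noise_sd=0.0, seed=0)


def flat_spectrum(wl, level, kind=SpectrumKind.RADIANCE):
    return Spectrum(np.asarray(wl, float), np.full(len(wl), float(level)), kind)
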