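import numpy as np
import pytest

from meercbct import (
    ScanGeometry,
    build_insert_phantom,
    build_system_matrix,
    calibrate_from_spectra,
    generate_spectrum,
)


@pytest.fixture(scope="session")
def spectra():
    return [generate_spectrum(k) for k in (80.0, 100.0, 120.0)]


@pytest.fixture(scope="session")
def calibration(spectra):
    return calibrate_from_spectra(spectra)


@pytest.fixture(scope="session")
def small_geometry():
    """64-pixel grid covering the full 20 cm phantom (4 mm pixels)."""
    return ScanGeometry(n_views=240, image_shape=(64, 64), pixel_size=0.4)


@pytest.fixture(scope="session")
def small_phantom(small_geometry):
    return build_insert_phantom(small_geometry)


@pytest.fixture(scope="session")
def small_projector(small_geometry):
    return build_system_matrix(small_geometry)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
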