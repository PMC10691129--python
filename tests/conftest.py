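import numpy as np
import pytest

from lenszones.phantom import CohortSpec, make_eye_for_age
from lenszones.pipeline import measure_volume
from lenszones.render import ScanGeometry, render_volume

MEAN_AGE = 39.24


@pytest.fixture(scope="session")
def spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def mean_phantom(spec):
    return make_eye_for_age(MEAN_AGE, spec)


@pytest.fixture(scope="session")
def reduced_scan():
    """Reduced raster (100 x 100 A-scans, full axial depth)."""
    return ScanGeometry(n_ascans_x=100, n_ascans_y=100)


@pytest.fixture(scope="session")
def native_scan():
    return ScanGeometry()


@pytest.fixture(scope="session")
def native_rows():
    """Central B-scan rows of the native raster that cover the ROI cylinder
    and the seed context."""
    return np.arange(144, 156)


@pytest.fixture(scope="session")
def rendered_native(mean_phantom, native_scan, native_rows):
    """Noiseless central-row rendering at the study's native sampling."""
    return render_volume(mean_phantom, native_scan, y_rows=native_rows)


@pytest.fixture(scope="session")
def measured_native(rendered_native, mean_phantom):
    return measure_volume(rendered_native, media=mean_phantom.media)


@pytest.fixture(scope="session")
def rendered_reduced(mean_phantom, reduced_scan):
    return render_volume(mean_phantom, reduced_scan)


@pytest.fixture(scope="session")
def speckled_native(mean_phantom, native_scan, native_rows):
    return render_volume(mean_phantom, native_scan, y_rows=native_rows,
                         speckle=True, seed=7)
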