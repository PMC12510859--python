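import numpy as np
import pytest

from deltazone import ImageVolume, PhantomSpec, ROIMask, generate_phantom_pair
from deltazone.geometry import DoseZoneScheme, build_dose_zone_rois

SMALL_SPEC = PhantomSpec(grid_shape=(48, 48, 40), spacing_mm=(2.5, 2.5, 3.0), seed=7)


@pytest.fixture(scope="session")
def phantom_rp():
    """One affected subject's volumes on a coarse grid (session-cached)."""
    return generate_phantom_pair(SMALL_SPEC, "S000", 1)


@pytest.fixture(scope="session")
def phantom_ctrl():
    return generate_phantom_pair(SMALL_SPEC, "S000", 0)


@pytest.fixture(scope="session")
def phantom_zones(phantom_rp):
    _, _, dose, lung, _ = phantom_rp
    zones, dropped = build_dose_zone_rois(dose, lung, DoseZoneScheme())
    return zones, dropped


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0), label=None):
    return ROIMask(np.asarray(data, dtype=bool), spacing, zone_label=label)
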