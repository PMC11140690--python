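import numpy as np
import pytest

import confoxrf as cx
from confoxrf import geometry, materials, probing_volume, simulate


@pytest.fixture(scope="session")
def xsec():
    """Shared computed cross-section source (warm per-element caches)."""
    return cx.ComputedCrossSections()


@pytest.fixture(scope="session")
def water():
    return cx.Material("water", {"H": 0.111898, "O": 0.888102}, density=1.0)


@pytest.fixture(scope="session")
def filling():
    return materials.sdr_flow_plus()


@pytest.fixture(scope="session")
def dentine():
    return materials.bovine_dentine()


@pytest.fixture(scope="session")
def resin():
    return materials.dental_resin()


@pytest.fixture(scope="session")
def pv_model():
    """Foil calibration of the study: 47 um at Ca Ka, 15 um at Sr Ka."""
    return probing_volume.fit_pv_model([
        probing_volume.PVCalibrationPoint(3.7, 47.0, "Ca"),
        probing_volume.PVCalibrationPoint(14.2, 15.0, "Sr"),
    ])


@pytest.fixture(scope="session")
def geom():
    return geometry.default_geometry()


@pytest.fixture(scope="session")
def tube_30kv():
    return simulate.tube_spectrum(simulate.TubeSpec(kv=30.0))


def constant_table(mu: float, lo: float = 1.0, hi: float = 40.0):
    """Flat attenuation table for hand-computable path checks."""
    return cx.AttenuationTable(np.array([lo, hi]), np.array([mu, mu]))


@pytest.fixture(scope="session")
def slab_labels():
    """Single-material 1 x 1 x 16 column, 8 um pitch (100 um at index 12)."""
    grid = geometry.VoxelGrid.isotropic((1, 1, 16), 8.0)
    return geometry.LabelVolume(grid, np.ones(grid.shape, dtype=np.int64))
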