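import numpy as np
import pytest

from liverkbp import DoseGrid, StructureMask


@pytest.fixture
def uniform_plan():
    """10x10x10 structure at exactly 50 Gy on a 12^3 grid of 1 mm voxels."""
    dose = np.zeros((12, 12, 12))
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[1:11, 1:11, 1:11] = True
    dose[mask] = 50.0
    return DoseGrid(dose), StructureMask("ptv", mask)


@pytest.fixture
def two_level_plan():
    """100-voxel structure: 50 voxels at 10 Gy, 50 at 30 Gy (1 mm voxels)."""
    dose = np.zeros((10, 10, 1))
    mask = np.ones((10, 10, 1), dtype=bool)
    dose[:5] = 10.0
    dose[5:] = 30.0
    return DoseGrid(dose), StructureMask("s", mask)
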