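import numpy as np
import pytest

from mrtvasc.lattice import CellType, VoxelLattice, lattice_from_mask
from mrtvasc.potts import HamiltonianParams, adhesion_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_tube(n, cross=(5, 5), thick=False):
    """Straight x-axis capillary mask of length ``n``."""
    m = np.zeros((n,) + cross, dtype=bool)
    cy, cz = cross[0] // 2, cross[1] // 2
    if thick:
        m[:, cy:cy + 2, cz:cz + 2] = True
    else:
        m[:, cy, cz] = True
    return m


@pytest.fixture
def tube_lattice():
    def _make(n=50, cross=(5, 5), voxel_size=1.0, one_cell_per_voxel=False):
        m = make_tube(n, cross)
        if not one_cell_per_voxel:
            return lattice_from_mask(m, voxel_size=voxel_size)
        lat = VoxelLattice((n,) + cross, voxel_size=voxel_size)
        cy, cz = cross[0] // 2, cross[1] // 2
        for k in range(n):
            lat.add_cell_from_voxels(np.array([[k, cy, cz]]),
                                     CellType.VASCULAR)
        return lat
    return _make


@pytest.fixture
def two_cell_lattice():
    """6^3 lattice with three cells (one axis-constrained vascular)."""
    lat = VoxelLattice((6, 6, 6))
    vox = np.argwhere(np.ones((6, 6, 6), bool))
    lat.add_cell_from_voxels(vox[:30], CellType.NORMAL, target_volume=28)
    lat.add_cell_from_voxels(vox[40:70], CellType.TUMOR, target_volume=32)
    lat.add_cell_from_voxels(vox[80:100], CellType.VASCULAR,
                             target_volume=20, target_axis=5.0)
    return lat


@pytest.fixture
def generic_params():
    J = adhesion_matrix({
        (CellType.NORMAL, CellType.MEDIUM): 3.0,
        (CellType.TUMOR, CellType.MEDIUM): 2.0,
        (CellType.VASCULAR, CellType.MEDIUM): 4.0,
        (CellType.NORMAL, CellType.TUMOR): 5.0,
        (CellType.NORMAL, CellType.VASCULAR): 5.0,
        (CellType.TUMOR, CellType.VASCULAR): 5.0,
        (CellType.NORMAL, CellType.NORMAL): 1.0,
        (CellType.TUMOR, CellType.TUMOR): 1.0,
        (CellType.VASCULAR, CellType.VASCULAR): 1.0,
    })
    return HamiltonianParams(adhesion=J, lambda_volume=1.5,
                             lambda_length=0.7, temperature=2.0)
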