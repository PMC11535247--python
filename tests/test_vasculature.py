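"""Synthetic vasculature: generation, resampling, clustering, remodeling."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mrtvasc.lattice import CellType, lattice_from_mask
from mrtvasc.vasculature import (GenerationError, VEGFParams,
                                 VesselNetworkParams,
                                 cluster_to_vascular_cells,
                                 generate_capillary_network,
                                 import_and_resample, remodel_vasculature,
                                 vascular_cell_lengths, vegf_steady_state)

DIMS = (48, 48, 48)


@pytest.fixture(scope="module")
def network():
    return generate_capillary_network(
        VesselNetworkParams(rng_seed=5), DIMS)


@pytest.fixture(scope="module")
def clustered():
    lat = generate_capillary_network(VesselNetworkParams(rng_seed=5), DIMS)
    ids = cluster_to_vascular_cells(lat, 20)
    return lat, ids


def bfs_face_to_face(mask, axis):
    """Independent 6-connected reachability check between opposite faces."""
    dims = mask.shape
    seen = np.zeros(dims, bool)
    q = deque()
    face = [slice(None)] * 3
    face[axis] = 0
    for v in np.argwhere(mask[tuple(face)]):
        full = list(v)
        full.insert(axis, 0)
        q.append(tuple(full))
        seen[tuple(full)] = True
    while q:
        x, y, z = q.popleft()
        if (x, y, z)[axis] == dims[axis] - 1:
            return True
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            n = (x + dx, y + dy, z + dz)
            if all(0 <= n[i] < dims[i] for i in range(3)) and \
                    mask[n] and not seen[n]:
                seen[n] = True
                q.append(n)
    return False


class TestGenerator:
    def test_volume_fraction_near_target(self, network):
        frac = network.volume_fraction(CellType.VASCULAR)
        assert 0.138 <= frac <= 0.158

    def test_zero_fraction_gives_empty_lattice(self):
        lat = generate_capillary_network(
            VesselNetworkParams(target_volume_fraction=0.0), (32, 32, 32))
        assert not lat.type_mask(CellType.VASCULAR).any()

    def test_connectivity_spans_every_axis(self, network):
        mask = network.type_mask(CellType.VASCULAR)
        for ax in range(3):
            assert bfs_face_to_face(mask, ax)

    def test_reproducible_for_fixed_seed(self):
        a = generate_capillary_network(VesselNetworkParams(rng_seed=3),
                                       (32, 32, 32))
        b = generate_capillary_network(VesselNetworkParams(rng_seed=3),
                                       (32, 32, 32))
        assert np.array_equal(a.grid, b.grid)

    def test_insufficient_paths_raise(self):
        with pytest.raises(GenerationError, match="seed paths"):
            generate_capillary_network(
                VesselNetworkParams(n_seed_paths=3), (48, 48, 48))


class TestResample:
    def test_tube_phantom_fraction_preserved(self):
        rng = np.random.default_rng(1)
        stack = np.zeros((64, 64, 64), dtype=np.uint8)
        while stack.mean() < 0.15:
            x0, y0 = rng.integers(0, 62, 2)
            stack[:, x0:x0 + 2, y0:y0 + 2] = 1
        lat = import_and_resample(stack, factor=2)
        assert lat.dims == (32, 32, 32)
        frac = lat.volume_fraction(CellType.VASCULAR)
        assert abs(frac - stack.mean()) <= 0.01
        assert 0.14 <= frac <= 0.17

    def test_background_and_solid_stacks(self):
        empty = import_and_resample(np.zeros((8, 8, 8), np.uint8))
        assert not empty.type_mask(CellType.VASCULAR).any()
        solid = import_and_resample(np.ones((8, 8, 8), np.uint8))
        assert solid.type_mask(CellType.VASCULAR).all()

    def test_odd_dims_padded(self):
        stack = np.ones((7, 8, 9), np.uint8)
        lat = import_and_resample(stack, factor=2)
        assert lat.dims == (4, 4, 5)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            import_and_resample(np.full((4, 4, 4), 2))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.45))
    def test_fraction_preserved_for_random_blobs(self, seed, frac):
        rng = np.random.default_rng(seed)
        stack = (rng.random((16, 16, 16)) < frac).astype(np.uint8)
        out = import_and_resample(stack, factor=2)
        assert abs(out.volume_fraction(CellType.VASCULAR)
                   - stack.mean()) <= 0.01


class TestClustering:
    def test_straight_tube_exact_division(self):
        m = np.zeros((100, 5, 5), bool)
        m[:, 2, 2] = True
        lat = lattice_from_mask(m)
        ids = cluster_to_vascular_cells(lat, 20)
        assert sorted(lat.cells.volume[ids]) == [20] * 5

    def test_remainder_merges_into_neighbor(self):
        m = np.zeros((103, 5, 5), bool)
        m[:, 2, 2] = True
        lat = lattice_from_mask(m)
        ids = cluster_to_vascular_cells(lat, 20)
        assert sorted(lat.cells.volume[ids]) == [20, 20, 20, 20, 23]

    def test_partition_of_vascular_voxels(self, clustered):
        """Cells tile the capillary voxel set: disjoint, complete, exact."""
        lat, ids = clustered
        mask = lat.type_mask(CellType.VASCULAR)
        labeled = np.zeros(lat.dims, bool)
        total = 0
        for cid in ids:
            vox = lat.cell_voxels(int(cid))
            assert not labeled[vox[:, 0], vox[:, 1], vox[:, 2]].any()
            labeled[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            total += len(vox)
        assert np.array_equal(labeled, mask)
        assert total == mask.sum()

    def test_fraction_exactly_conserved(self):
        lat = generate_capillary_network(VesselNetworkParams(rng_seed=5),
                                         DIMS)
        before = lat.type_mask(CellType.VASCULAR)
        cluster_to_vascular_cells(lat, 20)
        assert np.array_equal(lat.type_mask(CellType.VASCULAR), before)

    def test_isolated_voxel_forms_single_cell(self):
        m = np.zeros((34, 34, 34), bool)
        m[4, 4, 4] = True
        m[10:30, 20, 20] = True
        lat = lattice_from_mask(m)
        ids = cluster_to_vascular_cells(lat, 20)
        vols = sorted(lat.cells.volume[ids])
        assert vols[0] == 1 and sum(vols) == 21


class TestRemodel:
    def test_zero_mcs_is_identity(self, rng):
        lat = generate_capillary_network(VesselNetworkParams(rng_seed=5),
                                         (32, 32, 32))
        cluster_to_vascular_cells(lat, 20)
        before = lat.grid.copy()
        remodel_vasculature(lat, VEGFParams(), None, 0, rng)
        assert np.array_equal(lat.grid, before)

    def test_preserves_cell_count_and_fraction(self, rng):
        lat = generate_capillary_network(VesselNetworkParams(rng_seed=5),
                                         (32, 32, 32))
        ids = cluster_to_vascular_cells(lat, 20)
        frac0 = lat.volume_fraction(CellType.VASCULAR)
        remodel_vasculature(lat, VEGFParams(), None, 150, rng)
        assert len(lat.cell_ids(CellType.VASCULAR)) == len(ids)
        frac = lat.volume_fraction(CellType.VASCULAR)
        assert abs(frac - frac0) <= 0.2 * frac0
        lat.audit()

    def test_gap_closure(self):
        """A one-voxel discontinuity in a capillary is bridged."""
        m = np.zeros((31, 12, 12), bool)
        m[:, 5:7, 5:7] = True
        m[15] = False
        lat = lattice_from_mask(m, voxel_size=6.0)
        cluster_to_vascular_cells(lat, 20)
        remodel_vasculature(lat, VEGFParams(), None, 500,
                            np.random.default_rng(3))
        mask = lat.type_mask(CellType.VASCULAR)
        lab, n = ndimage.label(
            mask, structure=ndimage.generate_binary_structure(3, 1))
        bridged = False
        for c in range(1, n + 1):
            xs = np.argwhere(lab == c)[:, 0]
            if xs.min() < 15 and xs.max() > 15:
                bridged = True
        assert bridged

    def test_vegf_steady_state_scales(self):
        """Quasi-static VEGF: doubling secretion doubles the field."""
        m = np.zeros((32, 32, 32), bool)
        m[10:22, 16, 16] = True
        lat = lattice_from_mask(m)
        f1 = vegf_steady_state(lat, VEGFParams(secretion_rate=1.0))
        f2 = vegf_steady_state(lat, VEGFParams(secretion_rate=2.0))
        assert np.allclose(f2, 2 * f1, rtol=1e-10)
        assert (f1 >= 0).all()
        # field peaks on the secreting vessel
        assert f1[16, 16, 16] == f1.max()
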