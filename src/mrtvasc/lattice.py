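"""Voxel lattice and cell registry for the Cellular-Potts (GGH) engine.

The lattice is a 3-D integer grid mapping each voxel to a cell identifier
(0 = medium).  Per-cell bookkeeping (type, volume, volume/axis targets,
first and second spatial moments) lives in flat numpy arrays indexed by
cell id, so the Monte-Carlo kernels can run inside numba without touching
Python objects.  ``CellRecord`` objects are lightweight views materialized
on demand.

Boundary (donor/acceptor) cells used by the oxygen model are registered
here but occupy *virtual* voxels outside the grid; they are excluded from
grid/registry audits and from copy attempts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np


class CellType(IntEnum):
    MEDIUM = 0
    VASCULAR = 1
    NORMAL = 2
    TUMOR = 3
    DONOR = 4
    ACCEPTOR = 5


N_TYPES = 6

#: boundary-device types excluded from Potts dynamics
FROZEN_TYPES = (CellType.DONOR, CellType.ACCEPTOR)


class OxygenState(IntEnum):
    NORMOXIC = 0
    HYPOXIC = 1
    NECROTIC = 2


# second-moment column layout shared with the numba kernels:
# sx, sy, sz, sxx, syy, szz, sxy, sxz, syz
N_MOMENTS = 9


@dataclass
class CellRecord:
    """One biological cell, materialized as a read-only view of the registry."""

    id: int
    type: CellType
    voxels: np.ndarray  # (n, 3) voxel indices, 0-based
    volume: int  # voxels
    target_volume: float  # voxels
    target_axis_length: float  # voxels; 0 = unconstrained
    oxygen_state: OxygenState
    alive: bool


class CellTable:
    """Flat per-cell arrays; ids are 1-based and never reused."""

    def __init__(self, capacity: int = 64):
        self._cap = capacity
        self.max_id = 0
        self.cell_type = np.zeros(capacity, dtype=np.int8)
        self.exists = np.zeros(capacity, dtype=np.bool_)
        self.volume = np.zeros(capacity, dtype=np.int64)
        self.target_volume = np.zeros(capacity, dtype=np.float64)
        self.target_axis = np.zeros(capacity, dtype=np.float64)
        self.oxygen_state = np.zeros(capacity, dtype=np.int8)
        self.alive = np.zeros(capacity, dtype=np.bool_)
        self.moments = np.zeros((capacity, N_MOMENTS), dtype=np.float64)

    def _grow(self, need: int) -> None:
        if need < self._cap:
            return
        new_cap = max(need + 1, self._cap * 2)
        for name in ("cell_type", "exists", "volume", "target_volume",
                     "target_axis", "oxygen_state", "alive"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: self._cap] = arr
            setattr(self, name, new)
        new_m = np.zeros((new_cap, N_MOMENTS), dtype=np.float64)
        new_m[: self._cap] = self.moments
        self.moments = new_m
        self._cap = new_cap

    def new_cell(self, cell_type: CellType, target_volume: float = 0.0,
                 target_axis: float = 0.0) -> int:
        cid = self.max_id + 1
        self._grow(cid)
        self.max_id = cid
        self.cell_type[cid] = int(cell_type)
        self.exists[cid] = True
        self.alive[cid] = True
        self.target_volume[cid] = target_volume
        self.target_axis[cid] = target_axis
        return cid

    def ids(self, cell_type: CellType | None = None,
            include_boundary: bool = False) -> np.ndarray:
        m = self.exists[: self.max_id + 1].copy()
        m[0] = False
        t = self.cell_type[: self.max_id + 1]
        if cell_type is not None:
            m &= t == int(cell_type)
        elif not include_boundary:
            m &= t < int(CellType.DONOR)
        return np.flatnonzero(m)


def _moment_axis_length(volume: np.ndarray, moments: np.ndarray) -> np.ndarray:
    """Major-axis length (voxels) from second moments, vectorized over cells.

    Uses the covariance of the cell's voxel centers plus the single-voxel
    self-variance 1/12 per axis, so a straight n-voxel rod has length exactly
    n and a single voxel has length 1.
    """
    v = np.asarray(volume, dtype=float)
    out = np.zeros_like(v)
    ok = v > 0
    if not np.any(ok):
        return out
    m = moments[ok]
    n = v[ok]
    mx, my, mz = m[:, 0] / n, m[:, 1] / n, m[:, 2] / n
    c = np.empty((m.shape[0], 3, 3))
    c[:, 0, 0] = m[:, 3] / n - mx * mx + 1.0 / 12.0
    c[:, 1, 1] = m[:, 4] / n - my * my + 1.0 / 12.0
    c[:, 2, 2] = m[:, 5] / n - mz * mz + 1.0 / 12.0
    c[:, 0, 1] = c[:, 1, 0] = m[:, 6] / n - mx * my
    c[:, 0, 2] = c[:, 2, 0] = m[:, 7] / n - mx * mz
    c[:, 1, 2] = c[:, 2, 1] = m[:, 8] / n - my * mz
    lam = np.linalg.eigvalsh(c)[:, -1]
    out[ok] = np.sqrt(12.0 * np.clip(lam, 0.0, None))
    return out


class LatticeError(ValueError):
    pass


class VoxelLattice:
    """3-D voxel-to-cell-id map with a cell registry.

    Parameters
    ----------
    dims:
        Lattice shape in voxels.
    voxel_size:
        Isotropic voxel edge in µm (default 6, as used throughout).
    periodic:
        Per-axis periodicity flags for the Potts neighborhood.  Diffusion
        fields carry their own boundary handling.
    """

    def __init__(self, dims: tuple[int, int, int], voxel_size: float = 6.0,
                 periodic: tuple[bool, bool, bool] = (False, False, False)):
        self.dims = tuple(int(d) for d in dims)
        if len(self.dims) != 3 or min(self.dims) < 1:
            raise LatticeError(f"invalid lattice dims {dims}")
        self.voxel_size = float(voxel_size)
        self.periodic = tuple(bool(p) for p in periodic)
        self.grid = np.zeros(self.dims, dtype=np.int32)
        self.cells = CellTable()
        # virtual boundary-layer cells: id -> (kind, face_axis, inside_voxel)
        self.boundary_cells: dict[int, tuple[str, int, tuple[int, int, int]]] = {}
        # per-voxel counts of virtual donor/acceptor contacts (oxygen model)
        self.donor_links: np.ndarray | None = None
        self.acceptor_links: np.ndarray | None = None

    # ---------------------------------------------------------------- basics
    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def volume_um3(self) -> float:
        return self.n_voxels * self.voxel_size ** 3

    def type_grid(self) -> np.ndarray:
        """Per-voxel cell-type map (int8)."""
        return self.cells.cell_type[self.grid]

    def type_mask(self, cell_type: CellType) -> np.ndarray:
        return self.type_grid() == int(cell_type)

    def volume_fraction(self, cell_type: CellType) -> float:
        return float(np.count_nonzero(self.type_mask(cell_type))) / self.n_voxels

    def copy(self) -> "VoxelLattice":
        import copy as _copy

        out = VoxelLattice(self.dims, self.voxel_size, self.periodic)
        out.grid = self.grid.copy()
        out.cells = _copy.deepcopy(self.cells)
        out.boundary_cells = dict(self.boundary_cells)
        out.donor_links = None if self.donor_links is None else self.donor_links.copy()
        out.acceptor_links = None if self.acceptor_links is None else self.acceptor_links.copy()
        return out

    # ----------------------------------------------------------- registration
    def rebuild_stats(self) -> None:
        """Recompute volumes and moments of all grid cells from the grid."""
        t = self.cells
        n = t.max_id + 1
        flat = self.grid.ravel()
        t.volume[:n] = np.bincount(flat, minlength=n)[:n]
        t.volume[0] = 0
        xs, ys, zs = np.unravel_index(np.arange(flat.size), self.dims)
        w = [xs, ys, zs, xs * xs, ys * ys, zs * zs, xs * ys, xs * zs, ys * zs]
        for k in range(N_MOMENTS):
            t.moments[:n, k] = np.bincount(flat, weights=w[k], minlength=n)[:n]
        t.moments[0] = 0.0
        # cells that lost all voxels are gone (boundary cells have no voxels)
        for cid in range(1, n):
            if t.exists[cid] and cid not in self.boundary_cells:
                t.exists[cid] = t.volume[cid] > 0

    def add_cell_from_voxels(self, voxels: np.ndarray, cell_type: CellType,
                             target_volume: float | None = None,
                             target_axis: float = 0.0) -> int:
        """Claim ``voxels`` ((n,3) indices) for a new cell; they must be free
        or belong to displaceable cells (their records shrink accordingly)."""
        voxels = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
        prev = self.grid[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        cid = self.cells.new_cell(
            cell_type,
            target_volume=len(voxels) if target_volume is None else target_volume,
            target_axis=target_axis,
        )
        self.grid[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = cid
        self._accumulate_moments(cid, voxels, +1)
        for old in np.unique(prev):
            if old == 0:
                continue
            taken = voxels[prev == old]
            self._accumulate_moments(int(old), taken, -1)
            if self.cells.volume[old] == 0:
                self.cells.exists[old] = False
        return cid

    def _accumulate_moments(self, cid: int, voxels: np.ndarray, sign: int) -> None:
        t = self.cells
        x, y, z = (voxels[:, 0].astype(float), voxels[:, 1].astype(float),
                   voxels[:, 2].astype(float))
        t.volume[cid] += sign * len(voxels)
        t.moments[cid] += sign * np.array(
            [x.sum(), y.sum(), z.sum(), (x * x).sum(), (y * y).sum(),
             (z * z).sum(), (x * y).sum(), (x * z).sum(), (y * z).sum()])

    def remove_cell(self, cid: int) -> None:
        """Remove a cell; its voxels become medium."""
        if cid in self.boundary_cells:
            del self.boundary_cells[cid]
        else:
            self.grid[self.grid == cid] = 0
        t = self.cells
        t.volume[cid] = 0
        t.moments[cid] = 0.0
        t.exists[cid] = False
        t.alive[cid] = False

    # ---------------------------------------------------------------- queries
    def cell_voxels(self, cid: int) -> np.ndarray:
        return np.argwhere(self.grid == cid)

    def cell_record(self, cid: int) -> CellRecord:
        t = self.cells
        if cid <= 0 or cid > t.max_id or not t.exists[cid]:
            raise LatticeError(f"no such cell {cid}")
        if cid in self.boundary_cells:
            _, _, vox = self.boundary_cells[cid]
            voxels = np.asarray([vox])
        else:
            voxels = self.cell_voxels(cid)
        return CellRecord(
            id=cid, type=CellType(t.cell_type[cid]), voxels=voxels,
            volume=int(t.volume[cid]), target_volume=float(t.target_volume[cid]),
            target_axis_length=float(t.target_axis[cid]),
            oxygen_state=OxygenState(t.oxygen_state[cid]), alive=bool(t.alive[cid]))

    def cell_ids(self, cell_type: CellType | None = None) -> np.ndarray:
        return self.cells.ids(cell_type)

    def axis_lengths(self, ids: np.ndarray | None = None) -> np.ndarray:
        """Major-axis lengths in voxels for the given cell ids."""
        if ids is None:
            ids = self.cell_ids()
        return _moment_axis_length(self.cells.volume[ids], self.cells.moments[ids])

    def centroids(self, ids: np.ndarray) -> np.ndarray:
        t = self.cells
        v = t.volume[ids].astype(float)[:, None]
        return t.moments[ids, :3] / v

    # ------------------------------------------------------------------ audit
    def audit(self) -> None:
        """Assert the registry/grid bijection and moment consistency."""
        t = self.cells
        n = t.max_id + 1
        counts = np.bincount(self.grid.ravel(), minlength=n)[:n]
        counts[0] = 0
        for cid in range(1, n):
            if cid in self.boundary_cells:
                continue
            if t.exists[cid]:
                if counts[cid] != t.volume[cid]:
                    raise LatticeError(
                        f"cell {cid}: registry volume {t.volume[cid]} != "
                        f"grid count {counts[cid]}")
                if counts[cid] == 0:
                    raise LatticeError(f"cell {cid} exists but has no voxels")
            elif counts[cid] != 0:
                raise LatticeError(f"cell {cid} removed but owns voxels")
        present = np.unique(self.grid)
        for cid in present[present > 0]:
            if not t.exists[cid]:
                raise LatticeError(f"voxel labeled with unknown cell {cid}")
        # spot-check moments against a fresh recomputation
        ref = VoxelLattice(self.dims, self.voxel_size, self.periodic)
        ref.grid = self.grid
        ref.cells = t
        saved_vol = t.volume[:n].copy()
        saved_m = t.moments[:n].copy()
        saved_ex = t.exists[:n].copy()
        ref.boundary_cells = self.boundary_cells
        ref.rebuild_stats()
        ok = (np.array_equal(saved_vol, t.volume[:n])
              and np.allclose(saved_m, t.moments[:n]))
        if not ok:
            t.volume[:n] = saved_vol
            t.moments[:n] = saved_m
            t.exists[:n] = saved_ex
            raise LatticeError("incremental moments diverged from grid")
        t.exists[:n] = saved_ex

    # --------------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        """Write a TIFF label image plus a JSON registry sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path.with_suffix(".tif"), self.grid.astype(np.int32))
        t = self.cells
        reg = {
            "voxel_size": self.voxel_size,
            "dims": list(self.dims),
            "periodic": list(self.periodic),
            "cells": [
                {
                    "id": int(cid),
                    "type": int(t.cell_type[cid]),
                    "target_volume": float(t.target_volume[cid]),
                    "target_axis": float(t.target_axis[cid]),
                    "oxygen_state": int(t.oxygen_state[cid]),
                    "alive": bool(t.alive[cid]),
                }
                for cid in range(1, t.max_id + 1)
                if t.exists[cid] and cid not in self.boundary_cells
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(reg))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelLattice":
        import tifffile

        path = Path(path)
        grid = tifffile.imread(path.with_suffix(".tif"))
        reg = json.loads(path.with_suffix(".json").read_text())
        lat = cls(tuple(reg["dims"]), reg["voxel_size"], tuple(reg["periodic"]))
        lat.grid = np.ascontiguousarray(grid.astype(np.int32))
        max_id = max((c["id"] for c in reg["cells"]), default=0)
        lat.cells._grow(max_id)
        lat.cells.max_id = max_id
        for c in reg["cells"]:
            cid = c["id"]
            lat.cells.exists[cid] = True
            lat.cells.cell_type[cid] = c["type"]
            lat.cells.target_volume[cid] = c["target_volume"]
            lat.cells.target_axis[cid] = c["target_axis"]
            lat.cells.oxygen_state[cid] = c["oxygen_state"]
            lat.cells.alive[cid] = c["alive"]
        lat.rebuild_stats()
        return lat


def lattice_from_mask(mask: np.ndarray, cell_type: CellType = CellType.VASCULAR,
                      voxel_size: float = 6.0) -> VoxelLattice:
    """Wrap a boolean mask as a lattice holding one provisional cell."""
    mask = np.asarray(mask, dtype=bool)
    lat = VoxelLattice(mask.shape, voxel_size=voxel_size)
    if mask.any():
        lat.add_cell_from_voxels(np.argwhere(mask), cell_type)
    return lat
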