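"""Dual-field oxygen perfusion model.

Two coupled scalar fields live on the lattice geometry:

* **vascular pO2** — oxygen carried inside capillaries.  It diffuses only
  across faces between two vascular voxels, is sourced by *donor* cells
  (clamped at arterial pressure, 90 mmHg) on the three minimum faces and
  drained by *acceptor* cells (clamped at 0) on the three maximum faces,
  creating a directed perfusion through every capillary that spans the
  volume.
* **cellular pO2** — tissue oxygen.  Each Monte-Carlo step it is set equal
  to the vascular pO2 inside vascular voxels, diffuses lattice-wide with
  periodic boundaries (D = 2000 µm²/s in bulk tissue), and is consumed by
  cells with Michaelis-Menten kinetics (max 0.6 mmHg/s per normal cell,
  10x for tumor cells).  The drop of cellular pO2 inside vascular voxels
  over the step (the *leak*) is subtracted from the vascular field, so
  vascular oxygen is conserved up to donor/acceptor flux and delivery to
  tissue.

Severing a capillary from its donor therefore makes it run down: drained
segments empty through the acceptor, isolated segments equilibrate with
the surrounding tissue.  ``run_capillary_demo`` reproduces the
three-scenario single-capillary proof of concept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import CellType, OxygenState, VoxelLattice

__all__ = [
    "ChemField", "OxygenParams", "place_donors_acceptors",
    "step_vascular_field", "step_cellular_field", "equilibrate_oxygen",
    "run_capillary_demo", "make_vascular_field", "make_cellular_field",
]


class FieldBoundary(Enum):
    PERIODIC = "periodic"
    CLAMPED_CELLS = "clamped_cells"


@dataclass
class ChemField:
    """One scalar concentration grid (mmHg, or a.u. in the demo)."""

    name: str
    grid: np.ndarray
    diffusion: float  # µm²/s in the reference medium
    decay: float = 0.0  # s^-1
    boundary: FieldBoundary = FieldBoundary.PERIODIC

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)

    def mass(self) -> float:
        return float(self.grid.sum())


@dataclass
class OxygenParams:
    """Transport and uptake constants.

    ``vascular_diffusion`` is under-specified by the underlying study (it
    depends on capillary caliber); the default 4000 µm²/s is a config
    value.  ``seconds_per_mcs`` maps Monte-Carlo steps to wall time for
    the diffusion solvers.
    """

    donor_pO2: float = 90.0  # mmHg, arterial
    acceptor_pO2: float = 0.0
    tissue_diffusion: float = 2000.0  # µm²/s
    vascular_diffusion: float = 4000.0  # µm²/s
    max_uptake_per_cell: float = 0.6  # mmHg/s, normal cells
    tumor_uptake_multiplier: float = 10.0
    uptake_km: float = 1.0  # mmHg
    seconds_per_mcs: float = 1.0

    def __post_init__(self):
        if min(self.donor_pO2, self.tissue_diffusion, self.vascular_diffusion,
               self.max_uptake_per_cell, self.uptake_km,
               self.seconds_per_mcs) < 0:
            raise ValueError("oxygen parameters must be non-negative")
        if self.tumor_uptake_multiplier < 1:
            raise ValueError("tumor uptake multiplier must be >= 1")

    def uptake_rates(self) -> np.ndarray:
        """Per-type maximum uptake (mmHg/s); sources and medium take none."""
        u = np.zeros(6)
        u[int(CellType.NORMAL)] = self.max_uptake_per_cell
        u[int(CellType.TUMOR)] = (self.max_uptake_per_cell
                                  * self.tumor_uptake_multiplier)
        return u


class PerfusionError(RuntimeError):
    pass


def vascular_transport_mask(lattice: VoxelLattice) -> np.ndarray:
    return lattice.type_mask(CellType.VASCULAR)


def place_donors_acceptors(lattice: VoxelLattice,
                           params: OxygenParams | None = None) -> tuple[int, int]:
    """Attach clamped donor/acceptor boundary cells to the vasculature.

    Every vascular voxel lying on a minimum face (x=0, y=0, z=0) gets one
    donor cell in the adjacent virtual layer outside the lattice (one per
    face it touches); maximum faces get acceptor cells.  Returns
    (n_donors, n_acceptors).
    """
    mask = vascular_transport_mask(lattice)
    if not mask.any():
        raise PerfusionError("no vascular voxels on the lattice")
    dlinks = np.zeros(lattice.dims, dtype=np.int8)
    alinks = np.zeros(lattice.dims, dtype=np.int8)
    n_d = n_a = 0
    for ax in range(3):
        lo = [slice(None)] * 3
        lo[ax] = 0
        hi = [slice(None)] * 3
        hi[ax] = lattice.dims[ax] - 1
        for vox in np.argwhere(mask[tuple(lo)]):
            full = list(vox)
            full.insert(ax, 0)
            cid = lattice.cells.new_cell(CellType.DONOR)
            outside = list(full)
            outside[ax] = -1
            lattice.boundary_cells[cid] = ("donor", ax, tuple(outside))
            dlinks[tuple(full)] += 1
            n_d += 1
        for vox in np.argwhere(mask[tuple(hi)]):
            full = list(vox)
            full.insert(ax, lattice.dims[ax] - 1)
            cid = lattice.cells.new_cell(CellType.ACCEPTOR)
            outside = list(full)
            outside[ax] = lattice.dims[ax]
            lattice.boundary_cells[cid] = ("acceptor", ax, tuple(outside))
            alinks[tuple(full)] += 1
            n_a += 1
    if n_d == 0:
        raise PerfusionError(
            "vascular network touches no donor face (x=0/y=0/z=0): "
            "network does not span the volume")
    lattice.donor_links = dlinks
    lattice.acceptor_links = alinks
    return n_d, n_a


def make_vascular_field(lattice: VoxelLattice, params: OxygenParams,
                        initial: float | None = None) -> ChemField:
    """Vascular pO2 field, zero outside capillary voxels."""
    grid = np.zeros(lattice.dims)
    mask = vascular_transport_mask(lattice)
    grid[mask] = params.donor_pO2 if initial is None else initial
    return ChemField("vascular_pO2", grid, params.vascular_diffusion,
                     boundary=FieldBoundary.CLAMPED_CELLS)


def make_cellular_field(lattice: VoxelLattice, params: OxygenParams,
                        initial: float = 0.0) -> ChemField:
    return ChemField("cellular_pO2", np.full(lattice.dims, float(initial)),
                     params.tissue_diffusion, boundary=FieldBoundary.PERIODIC)


def _substeps(D: float, dt: float, h: float) -> tuple[int, float]:
    """Explicit-stability sub-stepping: r = D dt_sub / h^2 <= 1/6."""
    if D <= 0 or dt <= 0:
        return 0, 0.0
    r_full = D * dt / h ** 2
    n = max(1, int(np.ceil(r_full / (1.0 / 6.0))))
    return n, r_full / n


def step_vascular_field(vasc: ChemField, cell_leak: np.ndarray | None,
                        lattice: VoxelLattice, params: OxygenParams,
                        dt: float | None = None) -> float:
    """Advance vascular pO2 by ``dt`` seconds (default one MCS) in place.

    Discrete diffusion exchanges flux only across faces between vascular
    voxels; virtual donor/acceptor links clamp the boundary.  The tissue
    leak computed by :func:`step_cellular_field` is then subtracted and
    the field clamped non-negative.  Returns the net boundary influx for
    flux audits.
    """
    if lattice.donor_links is None:
        raise PerfusionError("donors/acceptors not placed")
    dt = params.seconds_per_mcs if dt is None else dt
    mask = vascular_transport_mask(lattice)
    h = lattice.voxel_size
    n_sub, r = _substeps(vasc.diffusion, dt, h)
    flux = 0.0
    if n_sub:
        flux = _kernels.diffuse_masked(
            vasc.grid, mask, lattice.donor_links, lattice.acceptor_links,
            params.donor_pO2, params.acceptor_pO2, r, n_sub)
    if cell_leak is not None:
        vasc.grid[mask] -= cell_leak[mask]
    np.clip(vasc.grid, 0.0, None, out=vasc.grid)
    vasc.grid[~mask] = 0.0
    return float(flux)


def step_cellular_field(cell_field: ChemField, vasc: ChemField,
                        lattice: VoxelLattice, params: OxygenParams,
                        dt: float | None = None) -> np.ndarray:
    """Advance cellular pO2 by ``dt`` seconds in place; returns the leak.

    Sequence: (1) source — cellular pO2 in vascular voxels is set to the
    vascular pO2; (2) explicit diffusion with periodic wrap; (3) per-cell
    Michaelis-Menten uptake spread uniformly over each living cell's
    voxels, clamped so the field stays non-negative.  The returned leak
    grid holds the decrease of cellular pO2 in vascular voxels between
    sourcing and end of step.
    """
    dt = params.seconds_per_mcs if dt is None else dt
    mask = vascular_transport_mask(lattice)
    cell_field.grid[mask] = vasc.grid[mask]
    sourced = cell_field.grid[mask].copy()
    h = lattice.voxel_size
    n_sub, r = _substeps(cell_field.diffusion, dt, h)
    if n_sub:
        _kernels.diffuse_periodic(cell_field.grid, r, n_sub)
    # uptake
    rates = params.uptake_rates()
    tab = lattice.cells
    n = tab.max_id + 1
    flat = lattice.grid.ravel()
    vol = np.bincount(flat, minlength=n)[:n].astype(float)
    tot = np.bincount(flat, weights=cell_field.grid.ravel(), minlength=n)[:n]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_p = np.where(vol > 0, tot / np.maximum(vol, 1), 0.0)
    mean_p = np.clip(mean_p, 0.0, None)
    u_max = rates[tab.cell_type[:n]]
    u_max[~tab.alive[:n]] = 0.0
    u_max[tab.oxygen_state[:n] == int(OxygenState.NECROTIC)] = 0.0
    uptake = u_max * mean_p / (mean_p + params.uptake_km)
    uptake[0] = 0.0
    cell_field.grid -= (uptake[lattice.grid] * dt)
    np.clip(cell_field.grid, 0.0, None, out=cell_field.grid)
    if cell_field.decay > 0:
        cell_field.grid *= np.exp(-cell_field.decay * dt)
    # delivery is one-way: the drop of cellular pO2 inside vascular voxels
    # is oxygen handed to the tissue; a local cellular excess does not
    # reoxygenate the blood, so a capillary severed from its donor runs
    # down irreversibly
    leak = np.zeros(lattice.dims)
    leak[mask] = np.clip(sourced - cell_field.grid[mask], 0.0, None)
    return leak


def equilibrate_oxygen(lattice: VoxelLattice, vasc: ChemField,
                       cell_field: ChemField, params: OxygenParams,
                       max_mcs: int = 500, tol: float = 1e-4) -> int:
    """Step the coupled fields until the per-MCS relative change of both
    drops below ``tol`` (or ``max_mcs``); returns the number of MCS run."""
    for i in range(1, max_mcs + 1):
        v_prev = vasc.grid.copy()
        c_prev = cell_field.grid.copy()
        leak = step_cellular_field(cell_field, vasc, lattice, params)
        step_vascular_field(vasc, leak, lattice, params)
        dv = np.abs(vasc.grid - v_prev).max()
        dc = np.abs(cell_field.grid - c_prev).max()
        scale = max(vasc.grid.max(), cell_field.grid.max(), 1e-12)
        if max(dv, dc) / scale < tol:
            return i
    return max_mcs


# ------------------------------------------------------------------- demo


def run_capillary_demo(n_cells: int = 50, removal_step: int = 100,
                       removed: tuple[int, ...] = (10, 30),
                       n_mcs: int = 1200,
                       vascular_diffusion: float = 8.0,
                       tissue_diffusion: float = 0.002) -> pd.DataFrame:
    """Single-capillary proof of concept (arbitrary units).

    Fifty single-voxel vascular cells form a straight capillary with a
    donor (clamped at 1) at one end and an acceptor (clamped at 0) at the
    other.  All cells start at 1 a.u.  At ``removal_step`` the listed
    cells are removed, splitting the capillary into a donor-connected
    segment (holds its level), an acceptor-connected segment (drains
    fastest) and an isolated segment (runs down only by leaking oxygen to
    the surrounding tissue).  Diffusivities are in voxel²/MCS.

    Returns a DataFrame indexed by MCS with one column per cell id; removed
    cells hold NaN after removal.
    """
    lat = VoxelLattice((n_cells, 5, 5), voxel_size=1.0)
    yc, zc = 2, 2
    ids = []
    for k in range(n_cells):
        cid = lat.add_cell_from_voxels(np.array([[k, yc, zc]]),
                                       CellType.VASCULAR)
        ids.append(cid)
    params = OxygenParams(donor_pO2=1.0, acceptor_pO2=0.0,
                          tissue_diffusion=tissue_diffusion,
                          vascular_diffusion=vascular_diffusion,
                          max_uptake_per_cell=0.0, seconds_per_mcs=1.0)
    place_donors_acceptors(lat, params)
    vasc = make_vascular_field(lat, params, initial=1.0)
    cell_field = make_cellular_field(lat, params, initial=0.0)
    rows = np.full((n_mcs + 1, n_cells), np.nan)
    tube_x = {cid: k for k, cid in enumerate(ids)}
    alive = set(ids)

    def record(row):
        for cid in alive:
            rows[row, cid - 1] = vasc.grid[tube_x[cid], yc, zc]

    record(0)
    for step in range(1, n_mcs + 1):
        if step == removal_step:
            for idx in removed:
                cid = ids[idx - 1]
                lat.remove_cell(cid)
                alive.discard(cid)
                vasc.grid[tube_x[cid], yc, zc] = 0.0
        leak = step_cellular_field(cell_field, vasc, lat, params)
        step_vascular_field(vasc, leak, lat, params)
        record(step)
    return pd.DataFrame(rows, columns=[f"cell_{i}" for i in range(1, n_cells + 1)],
                        index=pd.RangeIndex(n_mcs + 1, name="mcs"))
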