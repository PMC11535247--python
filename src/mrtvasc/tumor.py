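"""Avascular tumor growth with oxygen-limited proliferation.

A single tumor cell seeded at the lattice center grows its volume target
at a Michaelis-Menten rate in its mean cellular pO2 and divides when its
volume doubles (3375 -> 6750 µm³).  No angiogenesis: the vascular cell
population is conserved, and the growing spheroid displaces vessels
toward its rim, which is what degrades the spatial uniformity of the
vasculature.  Growth stages are defined by tumor volume-fraction
milestones (geometry, not wall-clock), mirroring day-12..20 snapshots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels
from .lattice import CellType, OxygenState, VoxelLattice
from .oxygen import ChemField, OxygenParams, step_cellular_field
from .potts import HamiltonianParams, run_mcs

log = logging.getLogger(__name__)

__all__ = ["TumorGrowthParams", "seed_tumor", "growth_update", "divide_cell",
           "grow_to_stage", "seed_normal_cells"]

#: tumor volume-fraction milestones (%) defining growth stages D12..D20
STAGE_TUMOR_FRACTIONS = {"D12": 0.055, "D14": 0.135, "D16": 0.276,
                         "D18": 0.465, "D20": 0.565}


@dataclass
class TumorGrowthParams:
    initial_cell_volume: float = 3375.0  # µm³
    division_volume: float = 6750.0  # µm³
    max_growth_rate: float = 6.75  # µm³ per MCS at saturating oxygen
    growth_km: float = 5.0  # mmHg half-saturation
    stage_fractions: dict[str, float] = field(
        default_factory=lambda: dict(STAGE_TUMOR_FRACTIONS))
    mcs_per_day: int = 500
    crowding_fraction: float = 0.60  # refuse to grow past this

    def __post_init__(self):
        if not np.isclose(self.division_volume, 2 * self.initial_cell_volume):
            raise ValueError("division volume must be twice the initial")
        if min(self.max_growth_rate, self.growth_km) < 0:
            raise ValueError("rates must be non-negative")


class TumorSeedError(RuntimeError):
    pass


def seed_tumor(lattice: VoxelLattice, params: TumorGrowthParams,
               rng: np.random.Generator | None = None) -> int:
    """Place one tumor cell of the initial target volume at the center.

    If the center voxel sits inside a vascular cell the seed moves to the
    nearest non-vascular voxel.  Normal cells under the seed are
    displaced.  Refuses to seed twice.
    """
    if len(lattice.cell_ids(CellType.TUMOR)):
        raise TumorSeedError("tumor already seeded")
    n_vox = params.initial_cell_volume / lattice.voxel_size ** 3
    center = np.asarray(lattice.dims) // 2
    vasc = lattice.type_mask(CellType.VASCULAR)
    if vasc[tuple(center)]:
        free = np.argwhere(~vasc)
        center = free[np.argmin(np.abs(free - center).sum(axis=1))]
    # claim the round(n_vox) non-vascular voxels nearest the center
    dist = np.linalg.norm(np.argwhere(~vasc) - center, axis=1)
    order = np.argsort(dist, kind="stable")
    voxels = np.argwhere(~vasc)[order[: int(round(n_vox))]]
    cid = lattice.add_cell_from_voxels(
        voxels, CellType.TUMOR,
        target_volume=n_vox)
    log.info("seeded tumor cell %d (%d voxels) at %s", cid, len(voxels),
             tuple(center))
    return cid


def growth_update(lattice: VoxelLattice, cellular: ChemField,
                  params: TumorGrowthParams) -> None:
    """Grow tumor volume targets by one MCS of Michaelis-Menten growth."""
    ids = lattice.cell_ids(CellType.TUMOR)
    if len(ids) == 0:
        return
    tab = lattice.cells
    n = tab.max_id + 1
    flat = lattice.grid.ravel()
    vol = np.bincount(flat, minlength=n)[:n]
    tot = np.bincount(flat, weights=cellular.grid.ravel(), minlength=n)[:n]
    p = np.clip(tot[ids] / np.maximum(vol[ids], 1), 0.0, None)
    rate_vox = params.max_growth_rate / lattice.voxel_size ** 3
    alive = tab.alive[ids] & (tab.oxygen_state[ids] != int(OxygenState.NECROTIC))
    tab.target_volume[ids] += np.where(
        alive, rate_vox * p / (p + params.growth_km), 0.0)


def divide_cell(lattice: VoxelLattice, cid: int, params: TumorGrowthParams,
                rng: np.random.Generator) -> tuple[int, int]:
    """Split a tumor cell by a plane through its centroid orthogonal to
    its major axis; both daughters get the initial volume target.

    If a centroid split leaves a daughter disconnected or more than 20%
    unbalanced, the plane is perturbed (up to 5 retries); the final
    attempt accepts a largest-connected-component assignment.
    """
    tab = lattice.cells
    vol_vox = params.division_volume / lattice.voxel_size ** 3
    if tab.volume[cid] < vol_vox:
        raise ValueError(f"cell {cid} below division volume")
    voxels = lattice.cell_voxels(cid)
    centroid = voxels.mean(axis=0)
    centered = voxels - centroid
    cov = centered.T @ centered / len(voxels)
    w, v = np.linalg.eigh(cov)
    normal = v[:, -1]
    struct = ndimage.generate_binary_structure(3, 1)

    def try_split(nrm, offset):
        proj = centered @ nrm
        side = proj + offset >= 0
        if side.all() or (~side).all():
            return None
        a, b = voxels[side], voxels[~side]
        if min(len(a), len(b)) / max(len(a), len(b)) < 0.8:
            return None
        for part in (a, b):
            m = np.zeros(lattice.dims, dtype=bool)
            m[part[:, 0], part[:, 1], part[:, 2]] = True
            if ndimage.label(m, structure=struct)[1] != 1:
                return None
        return a, b

    split = try_split(normal, 0.0)
    tries = 0
    while split is None and tries < 5:
        jitter = rng.normal(scale=0.3, size=3)
        nrm = normal + jitter
        nrm /= np.linalg.norm(nrm)
        split = try_split(nrm, rng.normal(scale=0.5))
        tries += 1
    if split is None:
        # accept the largest-component assignment of the centroid split
        proj = centered @ normal
        med = np.median(proj)
        side = proj >= med
        if side.all() or (~side).all():
            side = np.zeros(len(voxels), dtype=bool)
            side[: len(voxels) // 2] = True
        a, b = voxels[side], voxels[~side]
        m = np.zeros(lattice.dims, dtype=bool)
        m[b[:, 0], b[:, 1], b[:, 2]] = True
        lab, nlab = ndimage.label(m, structure=struct)
        if nlab > 1:
            sizes = ndimage.sum_labels(m, lab, index=range(1, nlab + 1))
            keep = 1 + int(np.argmax(sizes))
            stray = b[lab[b[:, 0], b[:, 1], b[:, 2]] != keep]
            b = b[lab[b[:, 0], b[:, 1], b[:, 2]] == keep]
            a = np.vstack([a, stray])
        # rebalance: move interface voxels of the larger daughter to the
        # smaller one until volumes are within 20%
        a_set = {tuple(v) for v in a}
        b_set = {tuple(v) for v in b}
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                (0, 0, -1)]
        while min(len(a_set), len(b_set)) / max(len(a_set), len(b_set)) < 0.8:
            big, small = (a_set, b_set) if len(a_set) > len(b_set) \
                else (b_set, a_set)
            interface = [v for v in big
                         if any((v[0] + o[0], v[1] + o[1], v[2] + o[2])
                                in small for o in offs)]
            if not interface:
                break
            small.add(interface[0])
            big.discard(interface[0])
        a = np.asarray(sorted(a_set))
        b = np.asarray(sorted(b_set))
        split = a, b
    _, daughter_vox = split
    tab.target_volume[cid] = params.initial_cell_volume / lattice.voxel_size ** 3
    new_id = lattice.add_cell_from_voxels(
        daughter_vox, CellType.TUMOR,
        target_volume=params.initial_cell_volume / lattice.voxel_size ** 3)
    return cid, new_id


def grow_to_stage(lattice: VoxelLattice, params: TumorGrowthParams,
                  oxy_params: OxygenParams, ham: HamiltonianParams,
                  vasc: ChemField, cellular: ChemField,
                  rng: np.random.Generator,
                  stages: list[str] | None = None,
                  max_mcs: int = 20000,
                  oxygen_every: int = 5,
                  vegf_params=None,
                  vegf_refresh_every: int = 25) -> dict[str, VoxelLattice]:
    """Interleave Potts dynamics, oxygen stepping, growth and division
    until each requested stage's tumor volume fraction is reached.

    Autocrine VEGF chemotaxis stays active (as in the remodeling stage)
    so vascular cells remain cohesive while the spheroid displaces them.
    Returns deep-copied lattice snapshots keyed by stage name.  Stops
    cleanly (with a warning) if the crowding guard trips.
    """
    from .vasculature import VEGFParams, vegf_steady_state

    vegf_params = VEGFParams() if vegf_params is None else vegf_params
    stages = list(params.stage_fractions) if stages is None else stages
    targets = sorted((params.stage_fractions[s], s) for s in stages)
    vol_div = params.division_volume / lattice.voxel_size ** 3
    snapshots: dict[str, VoxelLattice] = {}
    pending = list(targets)
    n_vasc0 = len(lattice.cell_ids(CellType.VASCULAR))
    vegf_field = None
    for step in range(max_mcs):
        if step % vegf_refresh_every == 0:
            vegf_field = vegf_steady_state(lattice, vegf_params)
        run_mcs(lattice, ham, rng, 1, fields=[vegf_field])
        if step % oxygen_every == 0:
            # growth stage: vascular pO2 clamped at arterial pressure;
            # the perfusion (donor/acceptor) machinery enters only at the
            # irradiation stage
            mask = lattice.type_mask(CellType.VASCULAR)
            vasc.grid[:] = 0.0
            vasc.grid[mask] = oxy_params.donor_pO2
            step_cellular_field(cellular, vasc, lattice, oxy_params,
                                dt=oxy_params.seconds_per_mcs * oxygen_every)
        growth_update(lattice, cellular, params)
        for cid in lattice.cell_ids(CellType.TUMOR):
            if lattice.cells.volume[cid] >= vol_div:
                divide_cell(lattice, int(cid), params, rng)
        frac = lattice.volume_fraction(CellType.TUMOR)
        while pending and frac >= pending[0][0]:
            _, name = pending.pop(0)
            snapshots[name] = lattice.copy()
            log.info("stage %s reached at MCS %d (tumor fraction %.3f)",
                     name, step, frac)
        if not pending:
            break
        if frac > params.crowding_fraction:
            log.warning("crowding guard: tumor fraction %.2f > %.2f, "
                        "stopping growth", frac, params.crowding_fraction)
            break
    n_vasc = len(lattice.cell_ids(CellType.VASCULAR))
    if n_vasc != n_vasc0:
        log.warning("vascular cell count changed during growth: %d -> %d",
                    n_vasc0, n_vasc)
    return snapshots


# ---------------------------------------------------------------- seeding


def seed_normal_cells(lattice: VoxelLattice,
                      density_per_mm3: float = 127870.0,
                      cell_volume_um3: float = 1944.0,
                      rng: np.random.Generator | None = None) -> int:
    """Seed normal tissue cells at the cortical density.

    Cells are compact 9-voxel blobs (1944 µm³ at 6 µm voxels) dropped at
    uniformly random free positions; the count follows the requested
    density over the lattice volume.  Returns the number of cells placed.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_cells = int(round(density_per_mm3 * lattice.volume_um3() * 1e-9))
    n_vox_per_cell = max(1, int(round(cell_volume_um3 / lattice.voxel_size ** 3)))
    # 2x2x2 block plus extra voxels stacked along +x
    shape = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    extra = 0
    while len(shape) < n_vox_per_cell:
        shape.append((2 + extra // 4, (extra % 4) // 2, extra % 2))
        extra += 1
    shape = np.asarray(shape[:n_vox_per_cell], dtype=np.int64)
    ext = shape.max(axis=0) + 1
    occ = lattice.grid != 0
    first_id = lattice.cells.max_id + 1
    placed_total = 0
    attempts = 0
    while placed_total < n_cells and attempts < 20:
        n_left = n_cells - placed_total
        cand = np.column_stack([
            rng.integers(0, lattice.dims[ax] - ext[ax] + 1, size=n_left * 4)
            for ax in range(3)]).astype(np.int64)
        placed = _kernels.place_blocks(occ, lattice.grid, shape, cand,
                                       n_left, first_id + placed_total)
        placed_total += placed
        attempts += 1
    if placed_total < n_cells:
        raise RuntimeError(
            f"could only place {placed_total}/{n_cells} normal cells; "
            "lattice too crowded for the requested density")
    for _ in range(placed_total):
        lattice.cells.new_cell(CellType.NORMAL,
                               target_volume=float(n_vox_per_cell))
    lattice.rebuild_stats()
    return placed_total
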