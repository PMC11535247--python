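"""Cellular-Potts (Glazier-Graner-Hogeweg) dynamics.

The energy of a configuration is

    H = sum_{neighbor pairs} J(tau_i, tau_j) [sigma_i != sigma_j]
      + lambda_vol * sum_cells (v - V_t)^2
      + lambda_len * sum_{constrained cells} (L - L_t)^2

with ``L`` the major-axis length of the cell's equivalent ellipsoid
(computed from its second moments).  Voxel-copy attempts are accepted with
the Metropolis rule min(1, exp(-dH/T)).  Chemotaxis enters as a per-copy
energy bias -mu * (c(target) - c(source)) so that cells with mu > 0 climb
the field gradient.

One Monte-Carlo step (MCS) performs as many copy attempts as there are
lattice voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lattice import N_TYPES, CellType, VoxelLattice, _moment_axis_length

__all__ = [
    "HamiltonianParams", "adhesion_matrix", "delta_hamiltonian",
    "attempt_copy", "run_mcs", "hamiltonian", "neighborhood_offsets",
]


def neighborhood_offsets(kind: str) -> np.ndarray:
    """Offsets of the 3-D Moore (26) or von Neumann (6) neighborhood."""
    if kind == "von_neumann":
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                (0, 0, -1)]
    elif kind == "moore":
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    else:
        raise ValueError(f"unknown neighborhood {kind!r}")
    return np.asarray(offs, dtype=np.int64)


def adhesion_matrix(pairs: dict[tuple[CellType, CellType], float],
                    default: float = 0.0) -> np.ndarray:
    """Build a symmetric type-pair contact-energy matrix from a dict."""
    J = np.full((N_TYPES, N_TYPES), default, dtype=np.float64)
    for (a, b), v in pairs.items():
        J[int(a), int(b)] = v
        J[int(b), int(a)] = v
    J[0, 0] = 0.0
    return J


@dataclass
class HamiltonianParams:
    """GGH energy parameters.

    ``adhesion`` is a (6, 6) symmetric matrix indexed by ``CellType``;
    ``chemotaxis`` maps cell type -> mu for each field passed to the
    dynamics (a single shared mapping; fields supply their own grids).
    The source tissue-simulation scripts behind this model never publish
    their contact/volume/temperature values, so defaults here are
    calibration values documented in the methods note.
    """

    adhesion: np.ndarray = field(
        default_factory=lambda: adhesion_matrix({}, default=0.0))
    lambda_volume: float = 2.0
    lambda_length: float = 0.0
    chemotaxis: dict[CellType, float] = field(default_factory=dict)
    temperature: float = 5.0
    neighborhood: str = "moore"

    def __post_init__(self):
        self.adhesion = np.asarray(self.adhesion, dtype=np.float64)
        if self.adhesion.shape != (N_TYPES, N_TYPES):
            raise ValueError("adhesion matrix must be 6x6 (CellType-indexed)")
        if not np.allclose(self.adhesion, self.adhesion.T):
            raise ValueError("adhesion matrix must be symmetric")
        if min(self.lambda_volume, self.lambda_length, self.temperature) < 0:
            raise ValueError("lambda_volume, lambda_length, T must be >= 0")

    def mu_matrix(self, n_fields: int) -> np.ndarray:
        mu = np.zeros((n_fields, N_TYPES), dtype=np.float64)
        for t, v in self.chemotaxis.items():
            mu[:, int(t)] = v
        return mu

    def offsets(self) -> np.ndarray:
        return neighborhood_offsets(self.neighborhood)


def _field_stack(lattice: VoxelLattice,
                 fields: list[np.ndarray] | None) -> np.ndarray:
    if not fields:
        return np.zeros((0,) + lattice.dims, dtype=np.float64)
    return np.ascontiguousarray(np.stack([np.asarray(f, dtype=np.float64)
                                          for f in fields]))


def _check_voxel(lattice: VoxelLattice, vox) -> tuple[int, int, int]:
    v = tuple(int(i) for i in vox)
    for ax in range(3):
        if not (0 <= v[ax] < lattice.dims[ax]):
            raise IndexError(f"voxel {v} outside lattice {lattice.dims}")
    return v


def delta_hamiltonian(lattice: VoxelLattice, source_voxel, target_voxel,
                      params: HamiltonianParams,
                      fields: list[np.ndarray] | None = None) -> float:
    """Incremental energy change of copying source's cell id onto target.

    Source and target must be lattice-adjacent (within the configured
    neighborhood, respecting periodicity).  Copying within one cell is the
    identity and returns 0.
    """
    s = _check_voxel(lattice, source_voxel)
    t = _check_voxel(lattice, target_voxel)
    d = np.asarray(s) - np.asarray(t)
    for ax in range(3):
        if lattice.periodic[ax]:
            n = lattice.dims[ax]
            d[ax] = (d[ax] + n // 2) % n - n // 2
    if np.max(np.abs(d)) > 1 or not np.any(d):
        raise ValueError("source and target voxels are not lattice-adjacent")
    tab = lattice.cells
    stack = _field_stack(lattice, fields)
    return float(_kernels.delta_hamiltonian(
        lattice.grid, tab.cell_type, tab.volume, tab.target_volume,
        tab.target_axis, tab.moments, params.adhesion,
        params.lambda_volume, params.lambda_length,
        stack, params.mu_matrix(stack.shape[0]), params.offsets(),
        np.asarray(lattice.periodic, dtype=np.bool_),
        s[0], s[1], s[2], t[0], t[1], t[2]))


def attempt_copy(lattice: VoxelLattice, source_voxel, target_voxel,
                 params: HamiltonianParams, rng: np.random.Generator,
                 fields: list[np.ndarray] | None = None) -> bool:
    """Single Metropolis copy attempt; returns True when accepted."""
    s = _check_voxel(lattice, source_voxel)
    t = _check_voxel(lattice, target_voxel)
    tab = lattice.cells
    a = lattice.grid[s]
    b = lattice.grid[t]
    if a == b:
        return False
    if tab.cell_type[a] >= int(CellType.DONOR) or \
            tab.cell_type[b] >= int(CellType.DONOR):
        return False
    dH = delta_hamiltonian(lattice, s, t, params, fields)
    if dH > 0.0:
        T = params.temperature
        if T <= 0.0 or rng.random() >= np.exp(-dH / T):
            return False
    lattice.grid[t] = a
    vox = np.asarray([t], dtype=np.int64)
    if a != 0:
        lattice._accumulate_moments(int(a), vox, +1)
    if b != 0:
        lattice._accumulate_moments(int(b), vox, -1)
        if tab.volume[b] == 0:
            tab.exists[b] = False
            tab.alive[b] = False
    return True


def run_mcs(lattice: VoxelLattice, params: HamiltonianParams,
            rng: np.random.Generator, n_steps: int,
            fields: list[np.ndarray] | None = None) -> int:
    """Run ``n_steps`` Monte-Carlo steps in place; returns accepted copies.

    Each MCS draws ``n_voxels`` random (target, neighbor) pairs.  Donor and
    acceptor cells never move; cells shrunk to zero voxels are dropped from
    the registry.
    """
    tab = lattice.cells
    offs = params.offsets()
    stack = _field_stack(lattice, fields)
    mu = params.mu_matrix(stack.shape[0])
    periodic = np.asarray(lattice.periodic, dtype=np.bool_)
    n = lattice.n_voxels
    accepted = 0
    for _ in range(int(n_steps)):
        targ = rng.integers(0, n, size=n)
        nbr = rng.integers(0, offs.shape[0], size=n)
        u = rng.random(size=n)
        accepted += _kernels.run_attempts(
            lattice.grid, tab.cell_type, tab.volume, tab.target_volume,
            tab.target_axis, tab.moments, tab.exists, tab.alive,
            params.adhesion, params.lambda_volume, params.lambda_length,
            params.temperature, stack, mu, offs, offs, periodic,
            targ, nbr, u)
    return accepted


def hamiltonian(lattice: VoxelLattice, params: HamiltonianParams) -> float:
    """Total configuration energy by full recomputation (test oracle).

    Independent numpy implementation of the adhesion, volume and elongation
    terms; chemotaxis is a per-copy bias with no configuration energy.
    """
    grid = lattice.grid
    types = lattice.type_grid()
    J = params.adhesion
    H = 0.0
    offs = [tuple(o) for o in params.offsets().tolist()]
    xs, ys, zs = np.meshgrid(*(np.arange(d) for d in lattice.dims),
                             indexing="ij")
    coords = (xs, ys, zs)
    for off in offs:
        nbr = []
        inside = np.ones(lattice.dims, dtype=bool)
        for ax in range(3):
            c = coords[ax] + off[ax]
            if lattice.periodic[ax]:
                c = c % lattice.dims[ax]
            else:
                inside &= (c >= 0) & (c < lattice.dims[ax])
                c = np.clip(c, 0, lattice.dims[ax] - 1)
            nbr.append(c)
        nid = grid[tuple(nbr)]
        nty = types[tuple(nbr)]
        # neighbor outside the lattice counts as medium (cell id 0), and
        # each such (voxel, direction) pair appears exactly once
        e_out = np.where((grid != 0) & ~inside, J[types, 0], 0.0)
        H += float(e_out.sum())
        # interior unordered pairs: visit from the lexicographically
        # positive side only
        if off > (0, 0, 0):
            e_in = np.where((grid != nid) & inside, J[types, nty], 0.0)
            H += float(e_in.sum())
    ids = lattice.cell_ids()
    tab = lattice.cells
    if params.lambda_volume > 0:
        dv = tab.volume[ids] - tab.target_volume[ids]
        H += params.lambda_volume * float((dv * dv).sum())
    if params.lambda_length > 0:
        con = ids[tab.target_axis[ids] > 0]
        if len(con):
            L = _moment_axis_length(tab.volume[con], tab.moments[con])
            dL = L - tab.target_axis[con]
            H += params.lambda_length * float((dL * dL).sum())
    return float(H)
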