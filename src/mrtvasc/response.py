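"""Radiation damage: stochastic vascular death and beam-path ablation.

Vascular cells die with a probability read off the microvascular
endothelial apoptosis dose-response (measured between 0 and 25 Gy and
linearly extrapolated above, clamped to 1), evaluated at the mean dose
over the cell's voxels.  Non-vascular cells inside a microbeam's FWHM
band are ablated deterministically, reproducing the strip-like loss of
tissue cells at peak doses.  Oxygen enhancement of radiosensitivity is
deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import BeamSpec, beam_centers_um
from .lattice import CellType, VoxelLattice

__all__ = ["DoseResponseTable", "death_probability",
           "apply_vascular_deaths", "ablate_beam_path_cells"]

# Placeholder digitization of the cited endothelial apoptosis response;
# the source curve is not tabulated in print, so this default is
# non-authoritative and should be overridden from a measured 2-column CSV
# where available.
_DEFAULT_POINTS = ((0.0, 0.0), (5.0, 0.12), (10.0, 0.25), (15.0, 0.35),
                   (20.0, 0.42), (25.0, 0.47))


@dataclass
class DoseResponseTable:
    """(dose Gy, death probability) points with linear extrapolation
    through the two highest measured points above ``max_measured_dose``."""

    points: tuple[tuple[float, float], ...] = _DEFAULT_POINTS
    max_measured_dose: float = 25.0

    def __post_init__(self):
        d = np.asarray([p[0] for p in self.points], dtype=float)
        p = np.asarray([p[1] for p in self.points], dtype=float)
        if len(d) < 2 or d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ValueError("doses must strictly increase starting at 0")
        if np.any((p < 0) | (p > 1)) or np.any(np.diff(p) < 0):
            raise ValueError("probabilities must be non-decreasing in [0,1]")
        self._d = d
        self._p = p

    @classmethod
    def from_csv(cls, path) -> "DoseResponseTable":
        arr = np.loadtxt(path, delimiter=",", comments="#")
        return cls(points=tuple((float(a), float(b)) for a, b in arr),
                   max_measured_dose=float(arr[-1, 0]))


def death_probability(dose, table: DoseResponseTable):
    """Death probability at ``dose`` Gy (scalar or array)."""
    dose = np.asarray(dose, dtype=float)
    if (dose < 0).any():
        raise ValueError("negative dose")
    d, p = table._d, table._p
    out = np.interp(dose, d, p)
    hi = dose > table.max_measured_dose
    if np.any(hi):
        slope = (p[-1] - p[-2]) / (d[-1] - d[-2])
        out = np.where(hi, p[-1] + slope * (dose - d[-1]), out)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def apply_vascular_deaths(lattice: VoxelLattice, mean_doses: dict[int, float],
                          table: DoseResponseTable,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Kill vascular cells stochastically; dead cells' voxels turn to medium.

    Returns the death report: one row per vascular cell with its mean
    dose, death probability and outcome.
    """
    ids = lattice.cell_ids(CellType.VASCULAR)
    ids = np.asarray(sorted(ids))  # order-stable for a given seed
    doses = np.asarray([mean_doses[int(i)] for i in ids])
    probs = death_probability(doses, table)
    died = rng.random(len(ids)) < probs
    for cid in ids[died]:
        lattice.remove_cell(int(cid))
    return pd.DataFrame({
        "cell_id": ids, "type": "vascular", "mean_dose_gy": doses,
        "death_probability": probs, "dead": died,
    })


def ablate_beam_path_cells(lattice: VoxelLattice,
                           spec: BeamSpec) -> pd.DataFrame:
    """Remove non-vascular cells whose centroid falls in a beam FWHM band.

    Bands are half-open, [center - fwhm/2, center + fwhm/2), along the
    lateral axis; vascular cells are untouched (they follow the
    dose-response instead).  Returns the ablation report.
    """
    extent = lattice.dims[spec.lateral_axis] * lattice.voxel_size
    centers = beam_centers_um(spec, extent)
    rows = []
    for ct in (CellType.NORMAL, CellType.TUMOR):
        ids = lattice.cell_ids(ct)
        if len(ids) == 0:
            continue
        cent = lattice.centroids(ids)[:, spec.lateral_axis]
        pos_um = (cent + 0.5) * lattice.voxel_size
        in_band = np.zeros(len(ids), dtype=bool)
        for c in centers:
            in_band |= (pos_um >= c - spec.fwhm / 2) & \
                       (pos_um < c + spec.fwhm / 2)
        for cid, pos, hit in zip(ids, pos_um, in_band):
            rows.append((int(cid), ct.name.lower(), float(pos), bool(hit)))
        for cid in ids[in_band]:
            lattice.remove_cell(int(cid))
    return pd.DataFrame(rows, columns=["cell_id", "type",
                                       "lateral_position_um", "dead"])
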