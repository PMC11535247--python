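"""Outcome scoring: oxygenation classes, uniformity, perfusion, summaries.

Tissue cells are classified by their mean cellular pO2: below 5 mmHg they
are hypoxic (reversible), below 1 mmHg necrotic (absorbing — dead by lack
of oxygen, removed from uptake).  Vascular spatial uniformity is the
standard deviation of local vascular densities over a cubic tiling of the
lattice; tumors decrease uniformity by pushing vessels toward their rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import CellType, OxygenState, VoxelLattice
from .oxygen import ChemField, vascular_transport_mask

__all__ = ["OutcomeThresholds", "OutcomeSeries", "classify_cells",
           "uniformity_statistic", "unperfused_fraction", "summarize_run",
           "default_subregion_edge"]


@dataclass
class OutcomeThresholds:
    hypoxia_pO2: float = 5.0  # mmHg
    necrosis_pO2: float = 1.0  # mmHg
    unperfused_pO2: float = 1.0  # mmHg, "depleted" vascular pO2

    def __post_init__(self):
        if not self.necrosis_pO2 < self.hypoxia_pO2:
            raise ValueError("necrosis threshold must lie below hypoxia")


@dataclass
class OutcomeSeries:
    """Time series of oxygenation and outcome fractions for one scenario.

    Fractions are over the initial (pre-irradiation) non-vascular cell
    population, so normoxic + hypoxic + necrotic + radiation_dead = 1 at
    every time point; total_dead = necrotic + radiation_dead.
    """

    scenario: str
    rows: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.rows.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def classify_cells(lattice: VoxelLattice, cellular: ChemField,
                   thresholds: OutcomeThresholds) -> dict[str, int]:
    """Update oxygen states of living tissue cells from their mean pO2.

    Normoxic <-> hypoxic transitions are reversible; necrosis is
    absorbing.  Returns per-state counts over living + necrotic tissue
    cells.
    """
    tab = lattice.cells
    n = tab.max_id + 1
    flat = lattice.grid.ravel()
    vol = np.bincount(flat, minlength=n)[:n]
    tot = np.bincount(flat, weights=cellular.grid.ravel(), minlength=n)[:n]
    counts = {"normoxic": 0, "hypoxic": 0, "necrotic": 0}
    for ct in (CellType.NORMAL, CellType.TUMOR):
        for cid in lattice.cell_ids(ct):
            if tab.oxygen_state[cid] == int(OxygenState.NECROTIC):
                counts["necrotic"] += 1
                continue
            p = tot[cid] / vol[cid] if vol[cid] else 0.0
            if p < thresholds.necrosis_pO2:
                tab.oxygen_state[cid] = int(OxygenState.NECROTIC)
                tab.alive[cid] = False  # dead by oxygen starvation
                counts["necrotic"] += 1
            elif p < thresholds.hypoxia_pO2:
                tab.oxygen_state[cid] = int(OxygenState.HYPOXIC)
                counts["hypoxic"] += 1
            else:
                tab.oxygen_state[cid] = int(OxygenState.NORMOXIC)
                counts["normoxic"] += 1
    return counts


def default_subregion_edge(dims: tuple[int, int, int]) -> int:
    """Divisor of the lattice edge closest to edge/5 (cubic lattices)."""
    edge = dims[0]
    divisors = [d for d in range(1, edge + 1) if edge % d == 0]
    return min(divisors, key=lambda d: abs(d - edge / 5))


def uniformity_statistic(lattice: VoxelLattice, subregion_edge: int | None = None,
                         reference_sd: float | None = None):
    """SD of local vascular densities over a cubic tiling.

    Returns the SD alone, or ``(SD, decrease)`` when a reference SD is
    given, with decrease = (SD - SD_ref) / SD_ref (the relative *decrease
    in uniformity*; positive when the vasculature got less uniform).
    """
    if subregion_edge is None:
        subregion_edge = default_subregion_edge(lattice.dims)
    s = int(subregion_edge)
    if any(d % s for d in lattice.dims):
        raise ValueError(f"subregion edge {s} does not tile lattice "
                         f"{lattice.dims}")
    mask = vascular_transport_mask(lattice).astype(float)
    nb = [d // s for d in lattice.dims]
    dens = mask.reshape(nb[0], s, nb[1], s, nb[2], s).mean(axis=(1, 3, 5))
    sd = float(dens.std())
    if reference_sd is None:
        return sd
    return sd, (sd - reference_sd) / reference_sd


def unperfused_fraction(lattice: VoxelLattice, vasc: ChemField,
                        thresholds: OutcomeThresholds) -> float:
    """Fraction of surviving vascular cells whose mean vascular pO2 has
    dropped below the depletion threshold."""
    ids = lattice.cell_ids(CellType.VASCULAR)
    if len(ids) == 0:
        raise ValueError("no vascular cells")
    if thresholds.unperfused_pO2 <= 0:
        return 0.0
    tab = lattice.cells
    n = tab.max_id + 1
    flat = lattice.grid.ravel()
    vol = np.bincount(flat, minlength=n)[:n]
    tot = np.bincount(flat, weights=vasc.grid.ravel(), minlength=n)[:n]
    mean_p = tot[ids] / vol[ids]
    return float(np.mean(mean_p < thresholds.unperfused_pO2))


def summarize_run(series_list: list[OutcomeSeries]) -> pd.DataFrame:
    """Depletion-vs-uniformity summary across scenarios.

    Each series must carry ``mean_pO2`` rows flagged pre/post irradiation
    and a per-scenario ``uniformity_decrease``.  The relative pO2
    depletion (mean_pre - mean_post)/mean_pre is paired with the
    uniformity decrease; a Spearman rank correlation across scenarios is
    attached to the frame attrs.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two scenarios to summarize")
    rows = []
    for s in series_list:
        df = s.to_frame()
        pre = df[~df["post_irradiation"]]["mean_pO2"].iloc[-1]
        post = df[df["post_irradiation"]]["mean_pO2"].iloc[-1]
        depletion = (pre - post) / pre if pre > 0 else 0.0
        rows.append({
            "scenario": s.scenario,
            "mean_pO2_pre": pre,
            "mean_pO2_post": post,
            "relative_depletion": depletion,
            "uniformity_decrease": df["uniformity_decrease"].iloc[-1],
        })
    out = pd.DataFrame(rows)
    if out["relative_depletion"].nunique() > 1 and \
            out["uniformity_decrease"].nunique() > 1:
        rho, p = stats.spearmanr(out["uniformity_decrease"],
                                 out["relative_depletion"])
    else:
        rho, p = np.nan, np.nan
    out.attrs["spearman_rho"] = float(rho)
    out.attrs["spearman_p"] = float(p)
    return out
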