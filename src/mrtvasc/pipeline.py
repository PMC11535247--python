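"""Full-run orchestration: vasculature -> tumor stage -> MRT -> outcome.

``run_full`` executes the complete workflow on a synthetic
angioarchitecture: network generation, clustering into vascular cells,
VEGF/elongation remodeling, normal-tissue seeding, optional tumor growth
to a named stage, donor/acceptor placement, oxygen pre-equilibration,
MRT irradiation (parametric dose, stochastic vascular death, beam-path
ablation) and post-irradiation oxygen evolution with outcome
classification.  All randomness flows from one seed; identical configs
reproduce identical metrics files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .dose import BeamSpec, build_parametric_dose, mean_dose_per_cell
from .lattice import CellType, VoxelLattice
from .metrics import (OutcomeSeries, OutcomeThresholds, classify_cells,
                      default_subregion_edge, unperfused_fraction,
                      uniformity_statistic)
from .oxygen import (OxygenParams, equilibrate_oxygen, make_cellular_field,
                     make_vascular_field, place_donors_acceptors,
                     run_capillary_demo, step_cellular_field,
                     step_vascular_field)
from .potts import HamiltonianParams, adhesion_matrix
from .response import (DoseResponseTable, ablate_beam_path_cells,
                       apply_vascular_deaths)
from .tumor import (TumorGrowthParams, grow_to_stage, seed_normal_cells,
                    seed_tumor)
from .vasculature import (VEGFParams, VesselNetworkParams,
                          cluster_to_vascular_cells,
                          generate_capillary_network, remodel_vasculature)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_full", "run_capillary_demo_csv",
           "default_growth_hamiltonian"]

SCENARIOS = ("NORMAL", "D0", "D12", "D14", "D16", "D18", "D20")


#: lateral extent (µm) of the full-scale setup: 117 voxels of 6 µm
FULL_EXTENT_UM = 702.0


def scaled_beam_spec(dims: tuple[int, int, int],
                     voxel_size: float) -> BeamSpec:
    """Microbeam array scaled to the lattice extent.

    On the full 0.7 mm lattice this is the nominal array (3 beams, 50 µm
    FWHM, 200 µm center-to-center).  Smaller desk-scale lattices get the
    same array *topology* — three beams with the same fractional coverage
    (~21% of the lateral extent) and spacing — so that peak/valley
    perfusion effects scale down faithfully instead of degenerating to a
    single mid-lattice beam.
    """
    extent = dims[0] * voxel_size
    if extent >= FULL_EXTENT_UM - 1e-6:
        return BeamSpec()
    s = extent / FULL_EXTENT_UM
    return BeamSpec(fwhm=50.0 * s, ctc=200.0 * s, beam_length=1200.0 * s,
                    penumbra_sigma=8.0 * s)


def default_growth_hamiltonian() -> HamiltonianParams:
    """Calibrated GGH parameters for the tumor-growth stage.

    Vascular rows stay in the low-surface-tension regime of the
    remodeling stage (thin capillaries are pushed around, not eroded);
    the tumor-vascular contact is costly so the growing spheroid
    displaces vessels toward its rim rather than engulfing them; the
    elongation term keeps vascular cells cable-like while they move.
    """
    J = adhesion_matrix({
        (CellType.VASCULAR, CellType.MEDIUM): 0.2,
        (CellType.VASCULAR, CellType.VASCULAR): 0.0,
        (CellType.NORMAL, CellType.MEDIUM): 2.0,
        (CellType.NORMAL, CellType.NORMAL): 1.5,
        (CellType.NORMAL, CellType.VASCULAR): 1.0,
        (CellType.TUMOR, CellType.MEDIUM): 2.0,
        (CellType.TUMOR, CellType.TUMOR): 1.0,
        (CellType.TUMOR, CellType.NORMAL): 3.0,
        (CellType.TUMOR, CellType.VASCULAR): 6.0,
    })
    return HamiltonianParams(adhesion=J, lambda_volume=6.0,
                             lambda_length=25.0,
                             chemotaxis={CellType.VASCULAR: 3.0},
                             temperature=3.0)


@dataclass
class RunConfig:
    """One simulation run.  Defaults are the desk-scale profile (64³).

    ``scenario`` D0 aliases NORMAL (irradiation before any growth).
    """

    dims: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 6.0
    scenario: str = "NORMAL"
    irradiation_time_min: float = 30.0
    rng_seed: int = 0
    output_dir: str | None = None

    vessels: VesselNetworkParams = field(default_factory=VesselNetworkParams)
    vegf: VEGFParams = field(default_factory=VEGFParams)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    tumor: TumorGrowthParams = field(default_factory=TumorGrowthParams)
    #: None = resolve at run time: the nominal array (3 beams, 50 µm FWHM,
    #: 200 µm c-t-c) on full-scale lattices, or a coverage-preserving
    #: scaled array on smaller ones (see :func:`scaled_beam_spec`)
    beams: BeamSpec | None = None
    thresholds: OutcomeThresholds = field(default_factory=OutcomeThresholds)
    dose_response: DoseResponseTable = field(default_factory=DoseResponseTable)

    target_cell_length: int = 20  # voxels
    remodel_mcs: int = 400
    pre_equilibration_mcs: int = 200
    post_evolution_mcs: int = 300
    steady_tol: float = 1e-4
    sample_every: int = 10
    growth_max_mcs: int = 20000
    growth_oxygen_every: int = 5
    normal_cell_density_mm3: float = 127870.0
    normal_cell_volume_um3: float = 1944.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        d["dose_response"] = {
            "points": [list(p) for p in self.dose_response.points],
            "max_measured_dose": self.dose_response.max_measured_dose,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {"vessels": VesselNetworkParams, "vegf": VEGFParams,
               "oxygen": OxygenParams, "tumor": TumorGrowthParams,
               "beams": BeamSpec, "thresholds": OutcomeThresholds}
        for k, typ in sub.items():
            if k in d and isinstance(d[k], dict):
                d[k] = typ(**d[k])
        if "dose_response" in d and isinstance(d["dose_response"], dict):
            dr = d["dose_response"]
            d["dose_response"] = DoseResponseTable(
                points=tuple(tuple(p) for p in dr["points"]),
                max_measured_dose=dr.get("max_measured_dose", 25.0))
        if "dims" in d:
            d["dims"] = tuple(d["dims"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    series: OutcomeSeries
    summary: dict
    lattice: VoxelLattice
    manifest: dict


def _mean_sd(grid: np.ndarray) -> tuple[float, float]:
    return float(grid.mean()), float(grid.std())


def run_full(config: RunConfig) -> RunResult:
    """Execute the full workflow for one scenario; see the module doc."""
    t_wall = time.time()
    rng = np.random.default_rng(config.rng_seed)
    stage_times: dict[str, float] = {}

    def mark(stage):
        stage_times[stage] = round(time.time() - t_wall, 2)
        log.info("stage %-22s done at %7.2f s", stage, stage_times[stage])

    # -- vasculature --------------------------------------------------------
    vessels = replace(config.vessels, rng_seed=int(rng.integers(2 ** 31)))
    lattice = generate_capillary_network(vessels, config.dims,
                                         config.voxel_size)
    cluster_to_vascular_cells(lattice, config.target_cell_length)
    remodel_vasculature(lattice, config.vegf, None, config.remodel_mcs, rng,
                        target_axis_voxels=config.target_cell_length)
    mark("vasculature")
    edge = default_subregion_edge(config.dims)
    sd_reference = uniformity_statistic(lattice, edge)

    # -- tissue + tumor stage ----------------------------------------------
    seed_normal_cells(lattice, config.normal_cell_density_mm3,
                      config.normal_cell_volume_um3, rng)
    oxy = config.oxygen
    vasc = make_vascular_field(lattice, oxy)
    cellular = make_cellular_field(lattice, oxy)
    scenario = "NORMAL" if config.scenario == "D0" else config.scenario
    if scenario != "NORMAL":
        seed_tumor(lattice, config.tumor, rng)
        grow_to_stage(lattice, config.tumor, oxy,
                      default_growth_hamiltonian(), vasc, cellular, rng,
                      stages=[scenario], max_mcs=config.growth_max_mcs,
                      oxygen_every=config.growth_oxygen_every,
                      vegf_params=config.vegf)
    mark("tissue")
    sd_now, uniformity_decrease = uniformity_statistic(
        lattice, edge, reference_sd=sd_reference)

    # -- perfusion pre-equilibration ---------------------------------------
    place_donors_acceptors(lattice, oxy)
    vasc = make_vascular_field(lattice, oxy)
    n_eq = equilibrate_oxygen(lattice, vasc, cellular, oxy,
                              max_mcs=config.pre_equilibration_mcs,
                              tol=config.steady_tol)
    mark("pre_equilibration")

    series = OutcomeSeries(scenario=config.scenario)
    n_tissue0 = (len(lattice.cell_ids(CellType.NORMAL))
                 + len(lattice.cell_ids(CellType.TUMOR)))
    n_vasc0 = len(lattice.cell_ids(CellType.VASCULAR))

    def record(time_min, post, n_rad_dead):
        counts = classify_cells(lattice, cellular, config.thresholds)
        mean_p, sd_p = _mean_sd(cellular.grid)
        unperf = unperfused_fraction(lattice, vasc, config.thresholds)
        necro = counts["necrotic"] / n_tissue0
        rad = n_rad_dead / n_tissue0
        series.append(
            time_min=round(time_min, 3), post_irradiation=post,
            mean_pO2=round(mean_p, 6), sd_pO2=round(sd_p, 6),
            frac_normoxic=round(counts["normoxic"] / n_tissue0, 6),
            frac_hypoxic=round(counts["hypoxic"] / n_tissue0, 6),
            frac_necrotic=round(necro, 6),
            frac_radiation_dead=round(rad, 6),
            frac_total_dead=round(necro + rad, 6),
            frac_unperfused_vascular=round(unperf, 6),
            uniformity_decrease=round(uniformity_decrease, 6))

    t_irr = config.irradiation_time_min
    record(0.0, False, 0)
    record(t_irr, False, 0)
    pre_mean = float(cellular.grid.mean())

    # -- irradiation --------------------------------------------------------
    beams = config.beams if config.beams is not None else \
        scaled_beam_spec(config.dims, config.voxel_size)
    dose = build_parametric_dose(beams, config.dims, config.voxel_size)
    doses = mean_dose_per_cell(dose, lattice)
    vasc_report = apply_vascular_deaths(lattice, doses, config.dose_response,
                                        rng)
    abl_report = ablate_beam_path_cells(lattice, beams)
    n_rad_dead = int(abl_report["dead"].sum())
    # dead vessels stop carrying oxygen
    vasc.grid[~lattice.type_mask(CellType.VASCULAR)] = 0.0
    mark("irradiation")

    # -- post-irradiation evolution ----------------------------------------
    spm_min = oxy.seconds_per_mcs / 60.0
    for step in range(1, config.post_evolution_mcs + 1):
        v_prev = vasc.grid.copy()
        c_prev = cellular.grid.copy()
        leak = step_cellular_field(cellular, vasc, lattice, oxy)
        step_vascular_field(vasc, leak, lattice, oxy)
        if step % config.sample_every == 0 or step == config.post_evolution_mcs:
            record(t_irr + step * spm_min, True, n_rad_dead)
            dv = np.abs(vasc.grid - v_prev).max()
            dc = np.abs(cellular.grid - c_prev).max()
            scale = max(vasc.grid.max(), cellular.grid.max(), 1e-12)
            if max(dv, dc) / scale < config.steady_tol:
                break
    mark("post_evolution")

    post_mean = float(cellular.grid.mean())
    summary = {
        "scenario": config.scenario,
        "n_vascular_cells_initial": n_vasc0,
        "n_vascular_cells_dead": int(vasc_report["dead"].sum()),
        "vascular_death_fraction": float(vasc_report["dead"].mean()),
        "n_tissue_cells_initial": n_tissue0,
        "tissue_ablated_fraction": float(abl_report["dead"].mean()),
        "mean_pO2_pre_mmHg": pre_mean,
        "mean_pO2_post_mmHg": post_mean,
        "relative_pO2_depletion": (pre_mean - post_mean) / pre_mean
        if pre_mean > 0 else 0.0,
        "unperfused_fraction_post": series.rows[-1][
            "frac_unperfused_vascular"],
        "uniformity_sd": sd_now,
        "uniformity_decrease_vs_normal": uniformity_decrease,
        "pre_equilibration_mcs": n_eq,
    }
    manifest = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "package": "mrtvasc",
        "stage_wall_times_s": stage_times,
        "outputs": [],
    }
    result = RunResult(config, series, summary, lattice, manifest)
    if config.output_dir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: RunResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = result.series.to_frame()
    files = {"metrics_timeseries.csv": lambda p: df.to_csv(p, index=False),
             "summary.json": lambda p: p.write_text(
                 json.dumps(result.summary, indent=2)),
             "config.yaml": lambda p: p.write_text(
                 yaml.safe_dump(result.config.to_dict()))}
    for name, writer in files.items():
        writer(out / name)
        result.manifest["outputs"].append(name)
    result.lattice.save(out / "final_lattice")
    result.manifest["outputs"] += ["final_lattice.tif", "final_lattice.json"]
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def run_capillary_demo_csv(out_path: str | Path | None = None, **kwargs):
    """Single-capillary demo; optionally writes the trajectory CSV."""
    df = run_capillary_demo(**kwargs)
    if out_path is not None:
        df.to_csv(out_path)
    return df
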