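# Methods

`mrtvasc` is a multiscale model of microbeam radiation therapy (MRT)
acting on brain microvasculature: a Cellular-Potts (Glazier-Graner-
Hogeweg, GGH) tissue engine, a dual-field oxygen perfusion model, a
parametric peak/valley microbeam dose model, a stochastic endothelial
dose-response, and outcome scoring by tissue oxygenation.  This note
records the model assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Cellular-Potts engine

Cells are sets of voxels on a 3-D lattice (6 µm isotropic voxels by
default).  The configuration energy is

    H = Σ_pairs J(τ_i, τ_j)·[σ_i ≠ σ_j]
      + λ_vol Σ_cells (v − V_t)²
      + λ_len Σ_constrained (L − L_t)²,

with Metropolis voxel-copy dynamics: one Monte-Carlo step (MCS) performs
as many copy attempts as lattice voxels, each accepted with probability
min(1, exp(−ΔH/T)).  Chemotaxis enters as a per-copy bias
ΔH_chem = −μ·(c(target) − c(source)) for the moving cell (sign flipped
for retractions), so cells with μ > 0 climb the field gradient.  The
major-axis length `L` is computed from the cell's second moments — the
largest eigenvalue λ_max of the voxel-center covariance plus the 1/12
single-voxel variance, L = √(12 λ_max) — which is exact for straight
rods (an n-voxel rod has L = n) and cheap to update incrementally.
Adhesion uses the 3-D Moore neighborhood (26-connectivity; von Neumann
available in config).  Donor/acceptor boundary devices never move.
A full-recompute Hamiltonian (independent numpy implementation) serves
as the test oracle for the incremental ΔH.

Bookkeeping convention: a cell that loses its last voxel is removed from
the registry; the ΔH of that final copy still uses the (v−1−V_t)² volume
term, which strongly penalizes extinction for cells with sizeable
volume targets.

## Synthetic angioarchitecture

The generator replaces an external mouse-brain segmentation.  It grows
persistent-direction tube walks between opposite lattice faces (the
lateral drift changes direction with probability 0.05 per step, so tubes
are nearly straight over a 120 µm window, like cortical capillaries),
with Poisson branching (0.5 branches/path), until the vascular volume
fraction reaches its target, 14.8% by default.  Tube calibers are mixed
— 50% one-voxel (6 µm, the minimum capillary diameter), 35% 2×2
(12 µm), 15% plus-shaped (~18 µm) — giving a mean cell cross-section of
~2–3 voxels, comparable to the reference angioarchitecture.  Every
generated network contains at least one 6-connected capillary path
between each pair of opposite faces.  Only these emergent statistics
(fraction, caliber, connectivity, clusterability into ~120 µm elongated
cells) are treated as contracts; the topology itself is synthetic.

What the generator does *not* emulate: arterio-venous hierarchy,
diving/ascending vessel anatomy, flow-consistent branching angles, and
full connectedness — a remodeled synthetic network retains a few percent
of its vascular voxels in fragments disconnected from the boundary
supply, whereas a real segmentation is one connected bed.  Tests passing
on this geometry show the machinery behaves correctly, not that the
synthetic bed is anatomically faithful.

## Clustering into vascular cells

Capillary voxels are partitioned into contiguous, elongated vascular
cells: the mask is skeletonized, the skeleton is decomposed into chains
by greedy direction-continuity walks, chains are cut into runs of ~20
voxels of end-to-end extent (a trailing remainder shorter than half the
target merges into the previous run; whole chains shorter than half the
target are absorbed into the neighbor they touch most), and every
capillary voxel joins its nearest skeleton segment by a distance-
transform watershed.  Clustering relabels voxels only, so the vascular
volume fraction is conserved exactly.

## Vascular remodeling

Remodeling runs GGH dynamics on the clustered cells with (i) autocrine
VEGF secretion and chemotaxis and (ii) an elongation constraint with
target major axis 20 voxels (120 µm), chosen to put the mean cell length
in the experimentally measured 124 ± 7 µm range.  VEGF (D = 10 µm²/s,
decay 0.65 h⁻¹, secretion 1 unit/MCS into vascular voxels) is solved
quasi-statically — a periodic FFT solve of the discrete reaction-
diffusion steady state, refreshed every 25 MCS — because the field
equilibrates fast relative to remodeling while an explicit transient
at these constants would grow without bound on the remodeling horizon.

Calibration (no published contact/volume/temperature values exist
for this model):
J(vascular, medium) = 0.2, J(vascular, vascular) = 0, λ_vol = 6,
λ_len = 25, μ = 3, T = 2, 400 MCS at 64³.  The near-zero surface
tension matters: with J(v,m) of order 1–10, eroding a maximally exposed
voxel of a one-voxel capillary gains ~24·J(v,m) of adhesion energy, and
thin vessels crumble.  Volume targets are pinned to each cell's initial
volume, conserving the vascular fraction (a divergence guard aborts at
20% drift).  An artifact-removal pass — morphological closing of
one-voxel discontinuities, with bridging voxels assigned to the nearest
cell — runs every 50 MCS and once at the end; this is the operational
reading of the remodeling stage's stated purpose (removing small
capillary discontinuities).  At 64³ this yields mean cell length
119.5–120.1 µm (within 124 ± 7), exact cell-count conservation, and
91–95% of vascular voxels connected to the boundary supply.

## Oxygen transport

Two coupled fields, following the dual-field perfusion model:

* **Vascular pO₂** diffuses only across faces between vascular voxels.
  Donor cells (clamped at 90 mmHg, the arterial value) attach to every
  vascular voxel on the three minimum faces, acceptor cells (clamped at
  0) on the three maximum faces; they are implemented as a virtual
  clamped boundary layer with registry records rather than in-lattice
  cells.  The vascular diffusivity (default 4000 µm²/s) is a config
  value — the model it reimplements ties it to capillary caliber without
  printing a number.
* **Cellular pO₂** is set equal to the vascular pO₂ inside vascular
  voxels each MCS, diffuses lattice-wide with periodic wrap
  (D = 2000 µm²/s), and is consumed per cell at
  U = U_max·p/(p + k_m) spread uniformly over the cell's voxels
  (U_max = 0.6 mmHg/s for normal cells, 10× for tumor cells,
  k_m = 1 mmHg, config).

Both solvers are explicit 6-neighbor finite differences with automatic
sub-stepping at r = D·Δt/h² ≤ 1/6.  The drop of cellular pO₂ inside
vascular voxels over the step (the *leak*) is subtracted from the
vascular field.  The leak is clamped non-negative: delivery is one-way,
so a capillary severed from its donor runs down irreversibly and, once
empty, acts as a sink on the surrounding tissue.  (Reading the leak as a
*signed* net flux instead lets severed fragments re-equilibrate with the
tissue; post-irradiation tissue pO₂ then rises, because ablation removes
consumers — the one-way reading is what produces the depletion and
unperfused-vessel phenomenology this model exists to study.)

A consequence worth knowing: removing vascular cells does **not**
always lower tissue oxygenation in this model.  Cutting *supply*
(donor-side) vessels does; removing *drain*-side vessels blocks the
acceptor sink and can raise the upstream profile.  The monotonicity
tests cover the supply-side property.

The single-capillary demo (50 one-voxel cells, donor 1 a.u., acceptor
0, cells #10/#30 removed at step 100) uses demo-scale diffusivities
(8 and 0.002 voxel²/MCS): slow drainage keeps the donor-proximal cells
near 1 a.u. on the demo horizon, and after the removal the three
regimes separate — donor-connected cells hold their level,
acceptor-connected cells drain fastest, isolated cells run down only by
leaking to the tissue.

## Tumor growth

A single tumor cell (3375 µm³ ≈ 15.6 voxels) is seeded at the lattice
center; tumor volume targets grow at
dV/dMCS = r_max·p/(p + k_m) with the mean cellular pO₂ over the cell
(defaults r_max = 6.75 µm³/MCS, k_m = 5 mmHg — the source defers both
to its literature, so they are config-exposed), and cells divide on
reaching 6750 µm³ by a centroid plane orthogonal to the major axis
(plane perturbed up to 5 times if a daughter is disconnected or the
volumes differ by more than 20%, then a largest-component assignment
with an interface-rebalancing pass).  During growth the vascular pO₂ is
clamped at the arterial value — the donor/acceptor perfusion machinery
enters only at the irradiation stage.  No angiogenesis: the vascular
cell count is conserved, and the growing spheroid displaces vessels
toward its rim, which is what degrades the spatial uniformity of the
vasculature.  Growth stages are defined by tumor volume-fraction
milestones (5.5 / 13.5 / 27.6 / 46.5 / 56.5% for D12–D20) rather than
wall-clock days; a crowding guard stops cleanly above 60%.

## MRT dose and radiation response

The lateral dose profile is a valley floor plus one flat-top bump with
Gaussian penumbra per microbeam, with the flat-top half-width chosen so
each bump's FWHM is exactly the nominal beam width; the composite is
normalized so the maximum voxel equals the peak dose (350 Gy) with the
mid-spacing valley at 6 Gy.  The nominal array is 3 planar beams,
50 µm FWHM, 200 µm center-to-center, invariant along propagation over
the 0.7 mm depth.  On lattices smaller than the full 702 µm extent the
pipeline scales the array geometry with the lattice (same fractional
coverage and spacing), because a 384 µm box covers only one nominal
beam and that degenerate topology cuts capillary paths at mid-length
instead of near the supply.  Externally scored grids import from a CSV
scorer dialect with a binning header that must match the lattice.

Vascular cells die independently with probability read off the
endothelial apoptosis dose-response at their mean voxel dose — linear
interpolation on [0, 25] Gy, linear extrapolation through the two
highest points above, clamped at 1.  The default table is a placeholder
digitization (the measured curve is not tabulated in print) and should
be overridden from a 2-column CSV where a measured curve is available.
Non-vascular cells whose centroid falls inside a beam's FWHM band
(half-open, [center − w/2, center + w/2)) are ablated deterministically.
Oxygen enhancement of radiosensitivity is deliberately not modeled.

## Outcome scoring

Tissue cells are classified by mean cellular pO₂: hypoxic below 5 mmHg
(reversible), necrotic below 1 mmHg (absorbing — the cell is dead by
oxygen starvation and stops consuming; only hypoxia is reversible).
Fractions are reported over the initial tissue-cell population, so
normoxic + hypoxic + necrotic + radiation-dead = 1 at every time point.
Spatial uniformity of the vasculature is the SD of local vascular
densities over a cubic tiling (default subregion edge: the divisor of
the lattice edge closest to edge/5, i.e. 13 voxels at 117³, 16 at 64³);
the *decrease in uniformity* of a scenario is (SD − SD_ref)/SD_ref
against the normal-tissue reference.  A vascular cell is *unperfused*
when its mean vascular pO₂ falls below 1 mmHg ("depleted" made
operational).  Scenario summaries pair relative pO₂ depletion,
(mean_pre − mean_post)/mean_pre, with the uniformity decrease and report
a Spearman rank correlation.

## Pipeline and scaling

`run_full` executes: generate → cluster → remodel → seed normal tissue
(127,870 cells/mm³, 9-voxel ≈ 1944 µm³ cells) → optional tumor growth to
a stage milestone → donor/acceptor placement → oxygen pre-equilibration
(to relative change < 1e-4 per MCS) → irradiation at the configured
30 min mark (dose, stochastic vascular deaths, beam-path ablation) →
post-irradiation oxygen evolution with outcome classification, frozen
cell geometry (the post-MRT question is oxygen redistribution, not
tissue mechanics) → metrics.  All randomness derives from one seed;
identical configs reproduce byte-identical metrics files.

Default problem sizes: the full-scale lattice is 117³ (702 µm); library
defaults and the test suite use 64³ and 32³ with compressed Monte-Carlo
budgets (e.g. 400 remodeling MCS, 80–200 oxygen MCS, growth rate scaled
×10 in staged tests).  Desk-scale runs reproduce the structural and
qualitative contracts — fraction conservation, perfusion bookkeeping,
stage ordering of uniformity and post-MRT oxygenation — not the
full-scale headline numbers, which additionally depend on the real
angioarchitecture and a Monte-Carlo-scored dose grid.  Known desk-scale
distortions: vascular cells (120 µm) are large relative to a scaled
beam spacing, so the vascular death fraction runs high; and the
normal-tissue depletion can even change sign because surviving
donor-side stubs rise toward the arterial value when their drains are
cut.

## Numerical choices and degenerate inputs

Explicit diffusion sub-steps at r ≤ 1/6 (stability with a 1.0 safety
margin); periodic FFT Poisson/Helmholtz solve for VEGF; ties in the
Metropolis rule accept ΔH ≤ 0 even at T = 0; resampling keeps the
fullest factor³ blocks up to the foreground-preserving count
(deterministic C-order tie-break); empty stacks, zero target fractions,
zero-MCS remodeling and zero-beam arrays are all identity/empty cases
rather than errors; a network that touches no donor face, a dose grid
with mismatched binning, NaN doses, a twice-seeded tumor, and a
sub-half-target division are explicit errors.

## Known limitations

* The synthetic network is not flow-realistic and retains a few percent
  disconnected vascular fragments after remodeling; pre-irradiation
  unperfused fractions are near-nil rather than exactly nil.
* The dose-response table is a placeholder shape, not a measured curve.
* Pericyte-dependent radio-resistance, vascular repair, dose-rate
  (FLASH) chemistry, hemoglobin binding and convective transport are out
  of scope.
* Day-indexed stages are defined by tumor volume fraction, not by a
  calibrated MCS-to-day clock.
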