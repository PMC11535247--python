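"""Apply MRT damage to a seeded tissue: dose-response deaths + ablation.

Seeds tissue cells at cortical density on the full 0.7 mm lattice, builds
the nominal dose grid, and applies the two damage rules: stochastic
vascular death would use the endothelial dose-response (here we show the
deterministic beam-path ablation of tissue cells and the dose-response
curve itself).
"""

import numpy as np

from mrtvasc import (BeamSpec, DoseResponseTable, VoxelLattice,
                     ablate_beam_path_cells, death_probability,
                     seed_normal_cells)

table = DoseResponseTable()
for dose in (0, 6, 12.5, 25, 50, 350):
    print(f"vascular death probability at {dose:>5.1f} Gy: "
          f"{death_probability(dose, table):.3f}")
print("(6 Gy is the valley dose; 350 Gy the peak - peak-struck vessels "
      "die with certainty)")

lattice = VoxelLattice((117, 117, 117), voxel_size=6.0)
n = seed_normal_cells(lattice, rng=np.random.default_rng(0))
report = ablate_beam_path_cells(lattice, BeamSpec())
print(f"\nseeded {n} tissue cells at 127,870 cells/mm³; "
      f"{report['dead'].sum()} ({100 * report['dead'].mean():.1f}%) lie "
      f"inside a beam FWHM band and are ablated "
      f"(3 x 50 µm / 702 µm = {100 * 150 / 702:.1f}% of the width)")
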