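"""Full normal-tissue scenario at desk scale (32³).

Runs the complete workflow - synthetic vasculature, tissue seeding,
perfusion equilibration, MRT irradiation, post-irradiation oxygen
evolution - and prints the outcome summary.  A full-scale study uses
dims=(117, 117, 117); this desk profile compresses lattice and
Monte-Carlo budgets and therefore reproduces the structural behavior,
not the full-scale numbers.
"""

import json

from mrtvasc import RunConfig, run_full

config = RunConfig(dims=(32, 32, 32), remodel_mcs=80,
                   pre_equilibration_mcs=80, post_evolution_mcs=200,
                   rng_seed=0, output_dir="scratch/normal_run")
result = run_full(config)
print(json.dumps(result.summary, indent=2))
print("\nkey lines: 'vascular_death_fraction' is the dose-response kill; "
      "'tissue_ablated_fraction' the beam-path strips (~21% at full "
      "scale); 'frac_unperfused_vascular' in the time series shows "
      "vessels losing supply after irradiation.")
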