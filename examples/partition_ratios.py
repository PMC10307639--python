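"""Daughter-cell partition ratios under clustered vs dispersed inheritance.

The partition ratio is lower-daughter / higher-daughter summed fragment
length, the sequencing-free readout of fragment inheritance: clustered
(tethered) fragments give 0 (a 0:1 segregation), while dispersed fragments
partition binomially, centring the ratio well above 0.
"""

import numpy as np

from chromobal import SimConfig, simulate_sample

ratios = {"clustered": [], "dispersed": []}
for mode in ratios:
    for seed in range(200):
        sim = simulate_sample(SimConfig(mode=mode, n_breakpoints=10, seed=seed))
        if sim.partition_ratio is not None:
            ratios[mode].append(sim.partition_ratio)

for mode, vals in ratios.items():
    print(
        f"{mode:>9}: mean ratio {np.mean(vals):.3f}, "
        f"median {np.median(vals):.3f} over {len(vals)} simulations"
    )
# clustered mode is identically 0; dispersed mode scatters around ~0.5
# (for 4 equal fragments the exact mean over all assignments is 13/24).
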