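"""Gate flow-cytometry samples, track CNV loss, and compare loss dynamics.

Calibrates 0/1/2+ copy gates on control strains, classifies per-generation
cell samples of two evolving populations, extracts early/middle/late
CNV-loss phase times (25/50/75% loss), and runs the paired comparison
between two CNV types.
"""

import numpy as np

from cnvrevert.cytometry import (
    build_gates,
    classify_cells,
    compare_phase_times,
    phase_times,
)
from cnvrevert.synth import FlowGeneratorSpec, default_controls
from cnvrevert.wf import PopulationConfig, ReversionParams, simulate_locus
from cnvrevert.synth import gen_flow_sample

rng = np.random.default_rng(4)
gates = build_gates(default_controls(rng), containment=0.95)
b01, b12 = gates.boundaries
print(f"gate boundaries: 0|1 at {b01:.3f}, 1|2+ at {b12:.3f}")
print("achieved containment:", {k: round(v, 3) for k, v in gates.achieved_containment.items()})

# two CNV types losing their amplification at different speeds
config = PopulationConfig(N=100_000)
fast = ReversionParams(s=0.12, delta=3e-4, phi=1e-5)   # chr XIV-like
slow = ReversionParams(s=0.04, delta=3e-4, phi=1e-5)   # chr XI-like

groups = {}
for name, params in (("fast", fast), ("slow", slow)):
    group = []
    for pop in range(3):
        traj = simulate_locus(params, config, rng)
        pct = []
        for freq in traj.cnv_freq:
            spec = FlowGeneratorSpec(weights=(0.0, 1 - freq, freq))
            cells, _ = gen_flow_sample(spec, rng)
            fractions = classify_cells(cells, gates)
            pct.append(100 * fractions[2])
        pt = phase_times(traj.generations, pct)
        group.append(pt)
        print(f"{name} pop{pop}: early {pt.early:.0f}, middle {pt.middle:.0f}, "
              f"late {pt.late:.0f} generations")
    groups[name] = group

out = compare_phase_times(groups["fast"], groups["slow"])
print("\npaired t-tests (fast vs slow loser):")
print(out.to_string(index=False))
# middle-phase medians tens of generations apart with small p-values mirror
# the chromosome-dependent loss dynamics of whole-chromosome amplifications.
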