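"""Simulate CNV reversion dynamics under the Wright-Fisher model.

Compares a costly, frequently reverting amplification with an effectively
neutral one over a 220-generation serial-batch experiment, and predicts how
long fixation of the revertant allele would take if reversion were neutral.
"""

import numpy as np

from cnvrevert import (
    PopulationConfig,
    ReversionParams,
    fixation_generations,
    simulate_locus,
)

rng = np.random.default_rng(0)
config = PopulationConfig()  # N = 3e5, 220 generations, sampled every 12

costly = ReversionParams(s=0.08, delta=3e-4, phi=1e-5)
neutral = ReversionParams(s=0.001, delta=1e-5, phi=1e-5)

print("generation  %CNV (costly)  %CNV (neutral)")
t_costly = simulate_locus(costly, config, rng)
t_neutral = simulate_locus(neutral, config, rng)
for g, a, b in zip(t_costly.generations, t_costly.cnv_freq, t_neutral.cnv_freq):
    print(f"{g:>10d}  {100 * a:>13.1f}  {100 * b:>14.1f}")

# The costly CNV is swept out within ~100 generations because revertants
# carry a ~8% per-generation advantage; the effectively neutral CNV barely
# moves in 220 generations.

res = fixation_generations(neutral, N=float("inf"), fix_threshold=0.99)
print(
    f"\nWith effectively neutral reversion (s={neutral.s}, delta={neutral.delta}),"
    f"\nthe revertant allele needs ~{res.mean:,.0f} generations to reach 99%:"
    "\nneutral reversion alone cannot explain rapid CNV loss."
)
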