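"""Ploidy-normalized copy number (PNCN) from a sequencing depth track.

Simulates per-base Poisson depth with a 135 kb segment amplified 3x,
reduces it to windowed PNCN, and writes a bedGraph.
"""

from pathlib import Path

import numpy as np

from cnvrevert.cytometry import pncn_track, write_bedgraph
from cnvrevert.synth import gen_depth_track

rng = np.random.default_rng(5)
# several unamplified chromosomes keep the genome-wide mean close to the
# single-copy depth, as in a real genome
track = gen_depth_track(
    genome_spec={"chrXI": 666_000, "chrIV": 1_500_000, "chrVII": 1_100_000},
    cnv_segment=("chrXI", 100_000, 235_000),
    segment_multiplier=3.0,
    mean_depth=50.0,
    rng=rng,
)
pncn = pncn_track(track, window=10_000)
on_xi = pncn[pncn["chromosome"] == "chrXI"]
inside = on_xi[(on_xi["start"] >= 100_000) & (on_xi["end"] <= 235_000)]
outside = on_xi[(on_xi["end"] <= 100_000) | (on_xi["start"] >= 235_000)]
print(f"mean PNCN inside amplified segment : {inside['pncn'].mean():.2f}")
print(f"mean PNCN outside amplified segment: {outside['pncn'].mean():.2f}")
print(f"segment-to-flank ratio             : {inside['pncn'].mean() / outside['pncn'].mean():.2f}")
# PNCN is depth relative to the genome-wide mean, i.e. copy number per
# chromosomal copy; the amplified segment reads ~3x its flanks' level
# (amplified bases inflate the genome-wide mean slightly, so both values sit
# just below their nominal copy numbers).

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_bedgraph(out / "pncn_example.bedgraph", pncn)
print(f"wrote {out / 'pncn_example.bedgraph'}")
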