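"""Flow-cytometry gating, CNV-loss phase statistics, and PNCN depth tracks.

Cells carrying 0, 1, or 2+ copies of a fluorescent reporter are classified
by normalized fluorescence (per-cell fluorescence divided by forward
scatter). Gates are calibrated on control strains with known copy number:
each class gets the central quantile interval containing a target fraction
(95%) of its control's cells, and class boundaries are placed midway
between adjacent intervals (midpoint of their overlap, or of the gap when
they do not overlap). The three resulting intervals partition the positive
line, so every cell is assigned to exactly one class. The fraction in the
2+ gate tracks the percentage of CNV-containing cells over generations.

CNV-loss dynamics are summarized by three phase times: the generations at
which 25% (early), 50% (middle) and 75% (late) of cells have lost the CNV,
linearly interpolated between flanking observations; populations that never
reach a threshold are censored at the experiment horizon. Paired t-tests
compare phase times between CNV types, with censored populations entering
at the horizon value (flagged in the result).

Sequencing depth tracks are reduced to ploidy-normalized copy number
(PNCN): per-window mean depth divided by the genome-wide mean depth, i.e.
copy number per chromosomal copy of the strain. PNCN is invariant to
overall sequencing effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthTrack",
    "GateSet",
    "PhaseTimes",
    "build_gates",
    "classify_cells",
    "compare_phase_times",
    "phase_times",
    "pncn_track",
    "read_bedgraph",
    "write_bedgraph",
]

DEFAULT_HORIZON = 220


@dataclass(frozen=True)
class GateSet:
    """Fluorescence boundaries partitioning (0, inf) into 0/1/2+ copy classes."""

    boundaries: tuple[float, float]
    achieved_containment: dict
    target_containment: float

    def __post_init__(self) -> None:
        b01, b12 = self.boundaries
        if not 0 < b01 < b12:
            raise ValueError("boundaries must satisfy 0 < b01 < b12")

    @property
    def intervals(self) -> dict:
        b01, b12 = self.boundaries
        return {0: (0.0, b01), 1: (b01, b12), 2: (b12, np.inf)}


def build_gates(
    controls: dict | list,
    containment: float = 0.95,
) -> GateSet:
    """Construct 0/1/2+ gates from known-copy-number control samples.

    ``controls`` maps copy class (0, 1, 2) to its control sample of
    normalized fluorescence values (or is a list in that order). Each class
    interval is the central ``containment`` quantile interval of its
    control; adjacent class boundaries sit at the midpoint between one
    interval's upper edge and the next one's lower edge. The achieved
    containment of each control within its final gate is reported so any
    shortfall from the 95% target is visible.
    """
    if not 0.5 < containment < 1:
        raise ValueError("containment must be in (0.5, 1)")
    if isinstance(controls, dict):
        samples = [np.asarray(controls[k], float) for k in (0, 1, 2)]
    else:
        samples = [np.asarray(c, float) for c in controls]
    if len(samples) != 3:
        raise ValueError("need control samples for copy classes 0, 1 and 2")
    for i, smp in enumerate(samples):
        if smp.size < 100:
            raise ValueError(f"control for class {i} has < 100 cells")
    medians = [float(np.median(s)) for s in samples]
    if not medians[0] < medians[1] < medians[2]:
        raise ValueError(
            f"control medians must be ordered 0 < 1 < 2 copies, got {medians}"
        )
    ql, qh = (1 - containment) / 2, (1 + containment) / 2
    ivals = [tuple(np.quantile(s, [ql, qh])) for s in samples]
    # midpoint of the overlap when intervals overlap, of the gap otherwise —
    # the same arithmetic midpoint either way
    b01 = (ivals[0][1] + ivals[1][0]) / 2
    b12 = (ivals[1][1] + ivals[2][0]) / 2
    if not b01 < b12:
        raise ValueError("degenerate controls: class boundaries are not ordered")
    bounds = (float(b01), float(b12))
    achieved = {}
    edges = [0.0, bounds[0], bounds[1], np.inf]
    for k, smp in enumerate(samples):
        achieved[k] = float(np.mean((smp > edges[k]) & (smp <= edges[k + 1])))
    return GateSet(bounds, achieved, containment)


def classify_cells(sample, gates: GateSet) -> np.ndarray:
    """Fractions of cells in the 0/1/2+ copy classes; sums to 1 exactly."""
    values = np.asarray(sample, float)
    if values.size == 0:
        raise ValueError("empty cell sample")
    counts = np.array(
        [
            np.sum(values <= gates.boundaries[0]),
            np.sum((values > gates.boundaries[0]) & (values <= gates.boundaries[1])),
            np.sum(values > gates.boundaries[1]),
        ]
    )
    return counts / values.size


@dataclass(frozen=True)
class PhaseTimes:
    """Generations at which 25/50/75% of cells have lost the CNV.

    NaN marks a censored phase (threshold never reached within the horizon).
    """

    early: float
    middle: float
    late: float
    horizon: float

    @property
    def censored(self) -> dict:
        return {
            "early": np.isnan(self.early),
            "middle": np.isnan(self.middle),
            "late": np.isnan(self.late),
        }

    def values_at_horizon(self) -> np.ndarray:
        """Phase times with censored phases encoded at the horizon."""
        v = np.array([self.early, self.middle, self.late])
        return np.where(np.isnan(v), self.horizon, v)


def _interp_crossing(gens: np.ndarray, pct: np.ndarray, target: float) -> float:
    """First generation at which pct drops to <= target, linearly interpolated."""
    below = pct <= target
    if not below.any():
        return np.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(gens[0])
    g0, g1 = gens[i - 1], gens[i]
    p0, p1 = pct[i - 1], pct[i]
    if p0 == p1:
        return float(g1)
    return float(g0 + (p0 - target) / (p0 - p1) * (g1 - g0))


def phase_times(
    generations,
    pct_cnv,
    thresholds: tuple[float, float, float] = (25.0, 50.0, 75.0),
    horizon: float | None = None,
) -> PhaseTimes:
    """Early/middle/late CNV-loss phase times from a %CNV trajectory.

    For a loss threshold of q%, the phase time is the first generation at
    which the percentage of CNV-containing cells reaches 100 - q, linearly
    interpolated between the two flanking observations. Censoring (never
    reached) is a value, not an error.
    """
    gens = np.asarray(generations, float)
    pct = np.asarray(pct_cnv, float)
    if gens.size != pct.size or gens.size < 2:
        raise ValueError("need >= 2 (generation, %CNV) points")
    order = np.argsort(gens)
    gens, pct = gens[order], pct[order]
    hz = float(gens[-1]) if horizon is None else float(horizon)
    e, m, l = (_interp_crossing(gens, pct, 100.0 - q) for q in thresholds)
    return PhaseTimes(e, m, l, hz)


def compare_phase_times(
    group_a: list[PhaseTimes],
    group_b: list[PhaseTimes],
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Paired t-tests of phase times between two CNV types.

    Populations are paired by list position (e.g. the two loci measured in
    the same cells). Censored populations enter at the horizon value; the
    per-phase count of censored entries is reported alongside the test so
    the encoding is visible. Returns one row per phase with the t statistic,
    two-sided p-value, and per-group medians.
    """
    if len(group_a) != len(group_b):
        raise ValueError(
            f"unpaired populations: group sizes {len(group_a)} != {len(group_b)}"
        )
    if len(group_a) < 2:
        raise ValueError("need >= 2 pairs")
    a = np.array([p.values_at_horizon() for p in group_a])
    b = np.array([p.values_at_horizon() for p in group_b])
    a = np.where(np.isnan(a), horizon, a)
    b = np.where(np.isnan(b), horizon, b)
    cens_a = np.array([[p.censored[k] for k in ("early", "middle", "late")] for p in group_a])
    cens_b = np.array([[p.censored[k] for k in ("early", "middle", "late")] for p in group_b])
    rows = []
    for j, phase in enumerate(("early", "middle", "late")):
        diff = a[:, j] - b[:, j]
        if np.std(diff, ddof=1) == 0:
            t = 0.0 if diff[0] == 0 else np.inf * np.sign(diff[0])
            p = 1.0 if diff[0] == 0 else 0.0
        else:
            res = stats.ttest_rel(a[:, j], b[:, j])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "phase": phase,
                "t_statistic": t,
                "p_value": p,
                "median_a": float(np.median(a[:, j])),
                "median_b": float(np.median(b[:, j])),
                "n_pairs": len(diff),
                "n_censored_a": int(cens_a[:, j].sum()),
                "n_censored_b": int(cens_b[:, j].sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DepthTrack:
    """Per-base sequencing depth per chromosome, with strain ploidy metadata."""

    depths: dict
    ploidy: int = 1

    def genome_mean(self) -> float:
        total = sum(float(d.sum()) for d in self.depths.values())
        n = sum(d.size for d in self.depths.values())
        return total / n


def pncn_track(track: DepthTrack, window: int = 1000) -> pd.DataFrame:
    """Ploidy-normalized copy number in fixed windows.

    Each window's mean depth is divided by the genome-wide mean depth,
    giving copy number per chromosomal copy of the strain (windows are
    0-based, half-open). A window larger than a chromosome collapses to one
    whole-chromosome window with a warning.
    """
    import warnings as _warnings

    gmean = track.genome_mean()
    if gmean <= 0:
        raise ValueError("genome-wide mean depth must be > 0")
    rows = []
    for chrom, depth in track.depths.items():
        w = window
        if w > depth.size:
            _warnings.warn(
                f"window {w} exceeds chromosome {chrom} length {depth.size}; "
                "using one whole-chromosome window"
            )
            w = depth.size
        for start in range(0, depth.size, w):
            end = min(start + w, depth.size)
            rows.append(
                {
                    "chromosome": chrom,
                    "start": start,
                    "end": end,
                    "pncn": float(depth[start:end].mean() / gmean),
                }
            )
    return pd.DataFrame(rows)


def write_bedgraph(path, df: pd.DataFrame, value_col: str = "pncn") -> None:
    """Write a (chromosome, start, end, value) table as bedGraph (0-based, half-open)."""
    df[["chromosome", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file into a (chromosome, start, end, value) table."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "value"],
        comment="#",
    )
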