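"""Synthetic-data generators emulating the experimental pipeline's inputs.

Every stage of the analysis can be exercised without external downloads:
these generators produce per-cell fluorescence samples, CNV-frequency
trajectories, competition-assay count series, per-gene duplication-cost
tables and per-base depth tracks, each with the statistical structure the
analysis assumes, plus a ground-truth sidecar for recovery tests. All
generators are bit-reproducible under a fixed seed.

Defaults mirror the study conditions: 220-generation serial-batch
experiments sampled every 12 generations, 3-4 replicate populations per
strain, 10,000 cells per flow sample, Gaussian observation noise with
sigma 0.02, and overlapping one-/two-copy fluorescence distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cnvrevert import cytometry, wf
from cnvrevert.inference import fitness_transforms

__all__ = [
    "ExperimentSpec",
    "FlowGeneratorSpec",
    "GroundTruth",
    "gen_competition_series",
    "gen_depth_track",
    "gen_flow_sample",
    "gen_gene_cost_table",
    "gen_strain_trajectories",
]


@dataclass(frozen=True)
class FlowGeneratorSpec:
    """Log-normal mixture of normalized fluorescence per copy class.

    Class medians increase with copy number; a shared log-scale sigma of
    0.18 puts the optimal-threshold misclassification between the one- and
    two-copy classes near 2.7% (Phi(-ln 2 / (2 * 0.18))), matching the
    small overlap seen between one- and two-copy reporter distributions.
    The zero-copy class sits at autofluorescence level, well separated.
    """

    medians: tuple[float, float, float] = (0.05, 1.0, 2.0)
    sigma: float = 0.18
    weights: tuple[float, float, float] = (0.0, 0.0, 1.0)
    n_cells: int = 10_000

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not self.medians[0] < self.medians[1] < self.medians[2]:
            raise ValueError("class medians must increase with copy number")


def gen_flow_sample(
    spec: FlowGeneratorSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell normalized fluorescence; returns (values, true labels)."""
    labels = rng.choice(3, size=spec.n_cells, p=np.asarray(spec.weights))
    mu = np.log(np.asarray(spec.medians))[labels]
    values = np.exp(rng.normal(mu, spec.sigma))
    return values, labels


def default_controls(rng: np.random.Generator, spec: FlowGeneratorSpec | None = None):
    """Pure 0-, 1- and 2-copy control samples for gate calibration."""
    spec = spec or FlowGeneratorSpec()
    out = {}
    for k in range(3):
        w = [0.0, 0.0, 0.0]
        w[k] = 1.0
        pure = FlowGeneratorSpec(spec.medians, spec.sigma, tuple(w), spec.n_cells)
        out[k], _ = gen_flow_sample(pure, rng)
    return out


@dataclass(frozen=True)
class ExperimentSpec:
    """A full synthetic evolution experiment over several strains.

    ``strains`` maps a strain name to its per-locus true parameters: a dict
    like ``{"G": ReversionParams, "M": ReversionParams}`` (one entry for
    single-locus strains).
    """

    strains: dict
    replicates: int = 3
    config: wf.PopulationConfig = field(default_factory=wf.PopulationConfig)
    noise_sigma: float = 0.02


@dataclass(frozen=True)
class GroundTruth:
    """True parameters and derived quantities behind a generated experiment."""

    theta: dict
    fitness: dict
    phase_times: dict
    seed: int | None


def gen_strain_trajectories(
    spec: ExperimentSpec, rng: np.random.Generator, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate replicate CNV-frequency trajectories for every strain.

    Each replicate population runs an independent Wright-Fisher chain from
    the strain's true parameters, is sampled at the configured generations,
    and receives i.i.d. Gaussian observation noise. The returned table has
    both the clipped percentage (``pct_cnv``, what a gating pipeline would
    report) and the raw noisy frequency (``cnv_freq_noisy``, the unclipped
    representation used for inference).
    """
    rows = []
    theta, fit, phases = {}, {}, {}
    for strain, loci in spec.strains.items():
        theta[strain] = {loc: p for loc, p in loci.items()}
        s_by_locus = {loc: p.s for loc, p in loci.items()}
        ft = fitness_transforms(
            s_by_locus.get("G", 0.0), s_by_locus.get("M", 0.0)
        )
        fit[strain] = ft.w_strain
        phases[strain] = {}
        for loc, params in loci.items():
            det = wf.deterministic_trajectory(params, spec.config.T)
            pt = cytometry.phase_times(det.generations, 100 * det.cnv_freq)
            phases[strain][loc] = pt
        for rep in range(spec.replicates):
            for loc, params in loci.items():
                traj = wf.simulate_locus(params, spec.config, rng, locus=loc)
                noisy = traj.cnv_freq + rng.normal(
                    0.0, spec.noise_sigma, size=traj.cnv_freq.shape
                )
                pct = np.clip(noisy, 0.0, 1.0) * 100
                for g, f_noisy, p in zip(traj.generations, noisy, pct):
                    rows.append(
                        {
                            "strain": strain,
                            "population": f"{strain}_rep{rep + 1}",
                            "locus": loc,
                            "generation": int(g),
                            "pct_cnv": p,
                            "cnv_freq_noisy": f_noisy,
                        }
                    )
    df = pd.DataFrame(rows)
    truth = GroundTruth(theta=theta, fitness=fit, phase_times=phases, seed=seed)
    return df, truth


def observation_vector(df: pd.DataFrame, population: str, loci=("G", "M")) -> np.ndarray:
    """Concatenated unclipped noisy CNV frequencies for one population,
    locus blocks in the given order — the layout the inference network expects."""
    sub = df[df["population"] == population]
    blocks = []
    for loc in loci:
        grp = sub[sub["locus"] == loc].sort_values("generation")
        blocks.append(grp["cnv_freq_noisy"].to_numpy())
    return np.concatenate(blocks)


def gen_competition_series(
    true_fitness: float,
    b0: float = 0.0,
    generations=(0, 2, 4, 8, 12, 16),
    n_cells_counted: int | None = 10_000,
    replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulated pairwise competition assay against the reference strain.

    The expected ln(query/reference) ratio follows the line
    b0 + (true_fitness - 1) * g; observed counts at each time point are a
    binomial draw of ``n_cells_counted`` cells from the expected mixture
    (pass None for exact, noise-free ratios).
    """
    if true_fitness <= 0:
        raise ValueError("true_fitness must be > 0")
    if n_cells_counted is not None and n_cells_counted < 100:
        raise ValueError("n_cells_counted must be >= 100")
    gens = np.asarray(generations, float)
    rows = []
    for rep in range(replicates):
        y = b0 + (true_fitness - 1.0) * gens
        ratio = np.exp(y)
        q_frac = ratio / (1.0 + ratio)
        if n_cells_counted is None:
            for g, lr in zip(gens, y):
                rows.append(
                    {"replicate": rep + 1, "generation": g, "query_count": np.nan,
                     "reference_count": np.nan, "ln_ratio": lr}
                )
        else:
            if rng is None:
                raise ValueError("rng is required when sampling counts")
            q = rng.binomial(n_cells_counted, q_frac)
            q = np.clip(q, 1, n_cells_counted - 1)  # guard degenerate draws
            r = n_cells_counted - q
            for g, qc, rc in zip(gens, q, r):
                rows.append(
                    {"replicate": rep + 1, "generation": g, "query_count": int(qc),
                     "reference_count": int(rc), "ln_ratio": np.log(qc / rc)}
                )
    return pd.DataFrame(rows)


def gen_gene_cost_table(
    n_genes: int = 500,
    frac_significant: float = 0.2,
    chromosomes: tuple[str, ...] = ("XI", "XIV"),
    mean_target: float = -0.33,
    rng: np.random.Generator | None = None,
    sig_scale: float = 1.0,
    nonsig_scale: float = 0.05,
) -> pd.DataFrame:
    """Synthetic per-gene duplication-cost table.

    Significant genes (FDR < 0.05 in the emulated screen) draw large,
    mostly negative costs; non-significant genes draw small costs. After
    drawing, all costs are shifted by a constant so the all-gene mean
    equals ``mean_target`` exactly (default -0.33, the genome-wide mean of
    the emulated source table). Genes are laid out on the given
    chromosomes with 0-based half-open coordinates.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= frac_significant <= 1:
        raise ValueError("frac_significant must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    sig = rng.uniform(size=n_genes) < frac_significant
    cost = np.where(
        sig,
        rng.normal(-1.5, sig_scale, size=n_genes),
        rng.normal(mean_target, nonsig_scale, size=n_genes),
    )
    cost = cost + (mean_target - cost.mean())
    chrom = np.asarray(chromosomes)[np.arange(n_genes) % len(chromosomes)]
    idx_on_chrom = np.zeros(n_genes, dtype=int)
    for c in chromosomes:
        mask = chrom == c
        idx_on_chrom[mask] = np.arange(mask.sum())
    start = idx_on_chrom * 2000
    return pd.DataFrame(
        {
            "gene": [f"GENE{i:04d}" for i in range(n_genes)],
            "chromosome": chrom,
            "start": start,
            "end": start + 1500,
            "cost": cost,
            "significant": sig,
        }
    )


def gen_depth_track(
    genome_spec: dict,
    cnv_segment: tuple[str, int, int] | None = None,
    segment_multiplier: float = 3.0,
    mean_depth: float = 50.0,
    ploidy: int = 1,
    rng: np.random.Generator | None = None,
) -> cytometry.DepthTrack:
    """Per-base Poisson depth track with an optional amplified segment.

    ``genome_spec`` maps chromosome name to length (bp); within
    ``cnv_segment`` (chromosome, start, end; 0-based half-open) the Poisson
    mean is multiplied by ``segment_multiplier``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if segment_multiplier < 0:
        raise ValueError("segment_multiplier must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    depths = {}
    for chrom, length in genome_spec.items():
        lam = np.full(int(length), float(mean_depth))
        if cnv_segment is not None and cnv_segment[0] == chrom:
            _, s, e = cnv_segment
            if not (0 <= s < e <= length):
                raise ValueError(
                    f"segment [{s}, {e}) outside chromosome {chrom} of length {length}"
                )
            lam[s:e] *= segment_multiplier
        depths[chrom] = rng.poisson(lam).astype(float)
    if cnv_segment is not None and cnv_segment[0] not in genome_spec:
        raise ValueError(f"segment chromosome {cnv_segment[0]!r} not in genome")
    return cytometry.DepthTrack(depths=depths, ploidy=ploidy)
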