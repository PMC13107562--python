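"""Predicted fitness costs of CNVs and aneuploidies from per-gene cost tables.

Competitive-growth screens of systematic gene duplication assign each gene
a per-extra-copy fitness cost (a log2 fold-change in abundance). The
predicted cost of an amplified region sums the costs of its genes:
significant genes (FDR < 0.05 in the source screen) contribute their
measured cost, non-significant genes are replaced by the genome-wide mean
cost (-0.33 in the source data). The bracketed sum is multiplied by the
number of extra copies of the region (copy number minus one):

    total = extra_copies * [ sum(significant costs)
                             + n_nonsignificant * mean_all_genes ]

Aneuploidy cost is the same formula applied to every gene on the duplicated
chromosome with one extra copy; a double aneuploidy is the sum of the two
single-chromosome costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CostEstimate",
    "aneuploidy_cost",
    "genes_in_region",
    "mean_gene_cost",
    "pearson_cost_fitness",
    "total_cnv_cost",
]

DEFAULT_MEAN_GENE_COST = -0.33


def _significant(table: pd.DataFrame) -> pd.Series:
    """Significance flag: explicit ``significant`` column or FDR < 0.05.

    The flag comes from the source screen's multiple-testing correction and
    is never re-estimated here.
    """
    if "significant" in table.columns:
        return table["significant"].astype(bool)
    if "fdr" in table.columns:
        return table["fdr"] < 0.05
    raise ValueError("cost table needs a 'significant' or 'fdr' column")


@dataclass(frozen=True)
class CostEstimate:
    """Deterministic total-cost estimate for one amplified region."""

    total_cost: float
    n_significant: int
    n_nonsignificant: int
    extra_copies: int
    mean_all_genes: float


def mean_gene_cost(table: pd.DataFrame) -> float:
    """Arithmetic mean cost over all genes (significant or not).

    Rows with missing cost are excluded; the exclusion count is reported
    via a warning so silent data loss is visible.
    """
    if len(table) == 0:
        raise ValueError("cost table is empty")
    cost = pd.to_numeric(table["cost"], errors="coerce")
    n_missing = int(cost.isna().sum())
    if n_missing:
        warnings.warn(f"excluded {n_missing} gene(s) with missing cost")
    return float(cost.dropna().mean())


def total_cnv_cost(
    records: pd.DataFrame,
    extra_copies: int,
    mean_all_genes: float = DEFAULT_MEAN_GENE_COST,
) -> CostEstimate:
    """Predicted cost of amplifying a gene set by ``extra_copies`` copies."""
    if extra_copies < 0:
        raise ValueError("extra_copies must be >= 0")
    if not np.isfinite(mean_all_genes):
        raise ValueError("mean_all_genes must be finite")
    if len(records) == 0:
        if extra_copies > 0:
            warnings.warn("empty amplified region: total cost is 0")
        return CostEstimate(0.0, 0, 0, extra_copies, mean_all_genes)
    sig = _significant(records)
    cost = pd.to_numeric(records["cost"], errors="coerce")
    sig_sum = float(cost[sig].sum())
    n_nonsig = int((~sig).sum())
    total = extra_copies * (sig_sum + n_nonsig * mean_all_genes)
    return CostEstimate(total, int(sig.sum()), n_nonsig, extra_copies, mean_all_genes)


def genes_in_region(table: pd.DataFrame, chromosome: str, start: int, end: int) -> pd.DataFrame:
    """Genes wholly contained in a 0-based half-open region of one chromosome."""
    sel = (
        (table["chromosome"] == chromosome)
        & (table["start"] >= start)
        & (table["end"] <= end)
    )
    return table[sel]


def aneuploidy_cost(
    table: pd.DataFrame,
    chromosomes: str | tuple[str, ...],
    mean_all_genes: float = DEFAULT_MEAN_GENE_COST,
) -> CostEstimate:
    """Predicted cost of whole-chromosome duplication(s).

    One chromosome label gives the single-aneuploidy cost (extra_copies = 1
    over all its genes); a pair gives the double-aneuploidy cost, the exact
    sum of the two single costs.
    """
    if isinstance(chromosomes, str):
        chromosomes = (chromosomes,)
    known = set(table["chromosome"].unique())
    parts = []
    for chrom in chromosomes:
        if chrom not in known:
            raise ValueError(f"unknown chromosome label: {chrom!r}")
        records = table[table["chromosome"] == chrom]
        if len(records) == 0:
            warnings.warn(f"no genes on chromosome {chrom}: contributes 0")
        parts.append(total_cnv_cost(records, extra_copies=1, mean_all_genes=mean_all_genes))
    return CostEstimate(
        total_cost=sum(p.total_cost for p in parts),
        n_significant=sum(p.n_significant for p in parts),
        n_nonsignificant=sum(p.n_nonsignificant for p in parts),
        extra_copies=1,
        mean_all_genes=mean_all_genes,
    )


def pearson_cost_fitness(
    cost_values,
    fitness_values,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    method: str = "bootstrap",
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation between predicted cost and measured fitness.

    The 95% CI is a bias-corrected bootstrap over pairs by default (the
    interval need not be symmetric about r); ``method='fisher'`` gives the
    classical Fisher-z interval instead.
    """
    x = np.asarray(cost_values, dtype=float)
    y = np.asarray(fitness_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(stats.pearsonr(x, y).statistic)
    if method == "fisher":
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(x.size - 3)
        return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'fisher'")
    rng = np.random.default_rng() if rng is None else rng
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = (xc * yc).sum(axis=1) / denom
    boots = boots[np.isfinite(boots)]
    # bias correction: shift percentiles by the bootstrap's median bias
    z0 = stats.norm.ppf(np.clip(np.mean(boots < r), 1e-6, 1 - 1e-6))
    lo_q = stats.norm.cdf(2 * z0 - 1.959963984540054)
    hi_q = stats.norm.cdf(2 * z0 + 1.959963984540054)
    lo, hi = np.percentile(boots, [100 * lo_q, 100 * hi_q])
    return r, (float(lo), float(hi))
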