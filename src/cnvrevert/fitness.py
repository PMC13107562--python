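"""Relative fitness from pairwise competition assays.

A query strain is co-cultured with a reference at a known starting ratio
and their relative abundance measured every few generations. The natural
log of the query/reference ratio grows linearly with generations at a rate
equal to the per-generation growth-rate difference. Because the starting
ratio is fixed by the assay design, the intercept is known (b0 = ln of the
starting ratio at generation 0) and only the slope is fitted:

    slope = sum_j g_j (y_j - b0) / sum_j g_j^2

pooled over all replicate time points. Relative fitness is slope + 1, so
the reference competed against itself has fitness exactly 1. The standard
error uses residual variance with n - 1 degrees of freedom (one fitted
parameter); the 95% CI and the two-sided p-value for slope = 0 come from
the t distribution.

Because the intercept is anchored at generation 0, shifting all generation
values by a constant changes the estimate: generations must be counted
from the start of the assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FitnessEstimate", "fit_relative_fitness", "fit_strain_table", "ln_ratios"]


def ln_ratios(query_counts, reference_counts) -> np.ndarray:
    """Elementwise ln(query/reference); zero counts are an error."""
    q = np.asarray(query_counts, dtype=float)
    r = np.asarray(reference_counts, dtype=float)
    if q.shape != r.shape:
        raise ValueError("query and reference count series differ in length")
    for name, arr in (("query", q), ("reference", r)):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(f"non-positive {name} count at time point(s) {bad.tolist()}")
    return np.log(q / r)


@dataclass(frozen=True)
class FitnessEstimate:
    """One-parameter regression result; fitness = slope + 1."""

    slope: float
    se: float
    fitness: float
    ci95: tuple[float, float]
    p_value: float
    n_points: int


def fit_relative_fitness(
    generations, ln_ratio, b0: float = 0.0, alpha: float = 0.05
) -> FitnessEstimate:
    """Fixed-intercept least squares of pooled replicate points.

    Parameters
    ----------
    generations, ln_ratio : pooled arrays over all replicates and time points.
    b0 : the common starting ln-ratio (theoretical by default: ln of the
        configured starting mix, 0 for a 1:1 mix).
    alpha : significance level for the confidence interval.
    """
    g = np.asarray(generations, dtype=float)
    y = np.asarray(ln_ratio, dtype=float)
    if g.shape != y.shape:
        raise ValueError("generations and ln_ratio differ in length")
    if g.size < 2:
        raise ValueError("need at least 2 pooled points")
    ss_g = float(np.sum(g**2))
    if ss_g == 0:
        raise ValueError("slope unidentifiable: all generation values are zero")
    slope = float(np.sum(g * (y - b0)) / ss_g)
    resid = y - b0 - slope * g
    df = g.size - 1
    sigma2 = float(np.sum(resid**2)) / df
    se = float(np.sqrt(sigma2 / ss_g))
    if se > 0:
        tstat = slope / se
        p = float(2 * stats.t.sf(abs(tstat), df))
    else:
        p = 0.0 if slope != 0 else 1.0
    half = stats.t.ppf(1 - alpha / 2, df) * se
    fitness = slope + 1.0
    return FitnessEstimate(
        slope=slope,
        se=se,
        fitness=fitness,
        ci95=(fitness - half, fitness + half),
        p_value=p,
        n_points=int(g.size),
    )


def fit_strain_table(df: pd.DataFrame, b0: float = 0.0, alpha: float = 0.05) -> pd.DataFrame:
    """Per-strain fitness from a tidy competition table.

    Expects columns ``strain``, ``generation`` and either ``ln_ratio`` or the
    pair ``query_count``/``reference_count``. Replicates are pooled into one
    regression per strain. Returns a table of fitness, CI bounds and p-value.
    """
    rows = []
    for strain, grp in df.groupby("strain", sort=False):
        if "ln_ratio" in grp.columns and grp["ln_ratio"].notna().all():
            y = grp["ln_ratio"].to_numpy()
        else:
            y = ln_ratios(grp["query_count"].to_numpy(), grp["reference_count"].to_numpy())
        est = fit_relative_fitness(grp["generation"].to_numpy(), y, b0=b0, alpha=alpha)
        rows.append(
            {
                "strain": strain,
                "fitness": est.fitness,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
                "p_value": est.p_value,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(rows)
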