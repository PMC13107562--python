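"""Wright-Fisher model of CNV reversion with selection, mutation and drift.

A population of cells carries a copy-number amplification (CNV) at one or two
loci. Each generation, a CNV-carrying cell reverts to the single-copy state
with probability ``delta`` (mutation); revertants have relative fitness
``1 + s`` with ``s >= 0`` (selection, reversion is beneficial or effectively
neutral); reproduction is a binomial/multinomial draw at fixed population
size ``N`` (drift). Reversion is unidirectional: re-amplification of a lost
copy is not modelled.

The per-generation update for the revertant frequency ``x`` at one locus is

    p_mut = x + (1 - x) * delta
    p_sel = p_mut (1 + s) / (p_mut (1 + s) + (1 - p_mut))
    x'    = Binomial(N, p_sel) / N

applied in the order reversion -> selection -> drift. Passing ``N = inf``
switches off drift and gives the deterministic recursion, which serves as
the infinite-population oracle for the stochastic simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_N",
    "EpistasisSpec",
    "FixationResult",
    "PopulationConfig",
    "ReversionParams",
    "Trajectory",
    "deterministic_trajectory",
    "fixation_generations",
    "generations_per_cycle",
    "read_trajectories",
    "simulate_locus",
    "simulate_strain_two_locus",
    "wf_step_locus",
    "write_trajectories",
]

#: Default effective population size: a 200 uL culture at ~1e8 cells/mL
#: diluted 1:64 passes through a bottleneck of roughly 3e5 cells.
DEFAULT_N = 300_000

#: Generations elapsed per serial-transfer cycle at the default 1:64
#: back-dilution (log2 of the dilution factor).
DEFAULT_CYCLE_LENGTH = 6


def generations_per_cycle(dilution_factor: float) -> float:
    """Generations of regrowth per serial-transfer cycle.

    A culture diluted 1:``dilution_factor`` must double ``log2(dilution_factor)``
    times to return to saturation, so a 1:64 back-dilution corresponds to six
    generations per cycle.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    return math.log2(dilution_factor)


@dataclass(frozen=True)
class ReversionParams:
    """Per-locus reversion parameters (s, delta, phi).

    Attributes
    ----------
    s : float
        Selection coefficient of the single-copy revertant relative to the
        CNV carrier. Revertant fitness is ``1 + s``; must be >= 0.
    delta : float
        Reversion rate per cell per generation, in [0, 1).
    phi : float
        Initial revertant frequency, in [0, 1).
    """

    s: float
    delta: float
    phi: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if not 0 <= self.phi < 1:
            raise ValueError(f"phi must be in [0, 1), got {self.phi}")


def _default_sample_gens() -> tuple[int, ...]:
    return tuple(range(0, 220, 12))


@dataclass(frozen=True)
class PopulationConfig:
    """Population size, duration and observation schedule of an experiment.

    Defaults mirror a 220-generation serial-batch experiment sampled every
    12 generations (within the 12-18 generation measurement cadence; a
    multiple of the 6-generation transfer cycle).
    """

    N: float = DEFAULT_N
    T: int = 220
    sample_gens: tuple[int, ...] = field(default_factory=_default_sample_gens)
    cycle_length: int = DEFAULT_CYCLE_LENGTH

    def __post_init__(self) -> None:
        if not (self.N == math.inf or (self.N >= 1 and float(self.N).is_integer())):
            raise ValueError("N must be an integer >= 1 or inf")
        gens = tuple(int(g) for g in self.sample_gens)
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("sample_gens must be strictly increasing")
        if gens and (gens[0] < 0 or gens[-1] > self.T):
            raise ValueError("sample_gens must lie within [0, T]")
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be >= 1")
        object.__setattr__(self, "sample_gens", gens)


@dataclass(frozen=True)
class EpistasisSpec:
    """Multiplicative fitness interaction between two reverted loci.

    The double revertant has fitness ``(1+sG)(1+sM)(1+e)``; ``e = 0`` is the
    no-epistasis (multiplicative) model.
    """

    e: float = 0.0

    def __post_init__(self) -> None:
        if 1 + self.e <= 0:
            raise ValueError(f"1 + e must be > 0, got e={self.e}")


@dataclass(frozen=True)
class Trajectory:
    """CNV-carrier frequency over generations for one locus in one population."""

    generations: np.ndarray
    cnv_freq: np.ndarray
    locus: str = ""

    def __post_init__(self) -> None:
        gens = np.asarray(self.generations)
        freq = np.asarray(self.cnv_freq, dtype=float)
        if gens.shape != freq.shape:
            raise ValueError("generations and cnv_freq must have the same length")
        if freq.size and (np.nanmin(freq) < -1e-12 or np.nanmax(freq) > 1 + 1e-12):
            raise ValueError("cnv_freq must lie in [0, 1]")
        object.__setattr__(self, "generations", gens)
        object.__setattr__(self, "cnv_freq", freq)

    @property
    def revertant_freq(self) -> np.ndarray:
        return 1.0 - self.cnv_freq

    def to_frame(self, strain: str = "", population: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": strain,
                "population": population,
                "locus": self.locus,
                "generation": self.generations,
                "cnv_freq": self.cnv_freq,
            }
        )


def _check_freq(x: np.ndarray | float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("revertant frequency must lie in [0, 1]")
    return x


def _step(
    x: np.ndarray,
    s: np.ndarray | float,
    delta: np.ndarray | float,
    N: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Vectorized one-generation update; x may be an array of populations."""
    p_mut = x + (1.0 - x) * delta
    fit = p_mut * (1.0 + s)
    p_sel = fit / (fit + (1.0 - p_mut))
    if N == math.inf:
        return p_sel
    if rng is None:
        raise ValueError("rng is required for finite N")
    n = int(N)
    return rng.binomial(n, p_sel) / n


def wf_step_locus(
    x: float,
    params: ReversionParams,
    N: float,
    rng: np.random.Generator | None = None,
) -> float:
    """Advance the revertant frequency at one locus by one generation.

    Update order is reversion, then selection, then binomial drift. With
    ``N = inf`` the deterministic (drift-free) update is returned exactly.
    """
    if not (N == math.inf or N >= 1):
        raise ValueError("N must be >= 1 or inf")
    xv = _check_freq(x)
    return float(_step(xv, params.s, params.delta, N, rng))


def _simulate_batch(
    s: np.ndarray,
    delta: np.ndarray,
    phi: np.ndarray,
    T: int,
    N: float,
    rng: np.random.Generator | None,
    record_gens: tuple[int, ...],
) -> np.ndarray:
    """Simulate many independent single-locus populations in parallel.

    Returns revertant frequencies, shape ``(n_pop, len(record_gens))``.
    """
    s, delta, phi = np.broadcast_arrays(
        np.atleast_1d(np.asarray(s, float)),
        np.atleast_1d(np.asarray(delta, float)),
        np.atleast_1d(np.asarray(phi, float)),
    )
    record = {g: i for i, g in enumerate(record_gens)}
    out = np.empty((s.shape[0], len(record_gens)))
    x = phi.copy()
    if 0 in record:
        out[:, record[0]] = x
    for t in range(1, T + 1):
        x = _step(x, s, delta, N, rng)
        if t in record:
            out[:, record[t]] = x
    return out


def simulate_locus(
    params: ReversionParams,
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
    locus: str = "",
) -> Trajectory:
    """Simulate one locus and return the CNV-carrier frequency trajectory.

    Starts from revertant frequency ``phi`` and iterates the Wright-Fisher
    update for ``config.T`` generations; the CNV frequency ``1 - x`` is
    recorded at each generation in ``config.sample_gens``. Identical seeds
    give bit-identical output.
    """
    rev = _simulate_batch(
        params.s, params.delta, params.phi, config.T, config.N, rng, config.sample_gens
    )[0]
    return Trajectory(np.asarray(config.sample_gens), 1.0 - rev, locus=locus)


def deterministic_trajectory(params: ReversionParams, T: int) -> Trajectory:
    """Exact infinite-population recursion, recorded at every generation.

    Serves as the brute-force oracle for the stochastic simulator: the mean
    of many finite-N replicates converges to this recursion as N grows.
    """
    gens = tuple(range(T + 1))
    rev = _simulate_batch(params.s, params.delta, params.phi, T, math.inf, None, gens)[0]
    return Trajectory(np.arange(T + 1), 1.0 - rev)


# Genotype order for the joint two-locus model. Labels name a locus
# (G or M) and its copy number: G2M2 carries both CNVs, G1M1 is the
# double revertant.
GENOTYPES = ("G2M2", "G2M1", "G1M2", "G1M1")


def _two_locus_joint(
    pG: ReversionParams,
    pM: ReversionParams,
    config: PopulationConfig,
    e: float,
    rng: np.random.Generator | None,
    record_genotypes: bool = False,
):
    """Joint 4-genotype chain; returns (sampled marginal revertant freqs G, M)
    and, if requested, the full genotype frequencies at the sampled generations."""
    dG, dM = pG.delta, pM.delta
    w = np.array(
        [1.0, 1.0 + pM.s, 1.0 + pG.s, (1.0 + pG.s) * (1.0 + pM.s) * (1.0 + e)]
    )
    # independent initial frequencies per locus
    f = np.array(
        [
            (1 - pG.phi) * (1 - pM.phi),
            (1 - pG.phi) * pM.phi,
            pG.phi * (1 - pM.phi),
            pG.phi * pM.phi,
        ]
    )
    # reversion transition matrix T[i, j] = P(i -> j)
    trans = np.array(
        [
            [(1 - dG) * (1 - dM), (1 - dG) * dM, dG * (1 - dM), dG * dM],
            [0.0, 1 - dG, 0.0, dG],
            [0.0, 0.0, 1 - dM, dM],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    record = {g: i for i, g in enumerate(config.sample_gens)}
    outG = np.empty(len(config.sample_gens))
    outM = np.empty(len(config.sample_gens))
    geno = np.empty((len(config.sample_gens), 4)) if record_genotypes else None

    def _record(t: int, f: np.ndarray) -> None:
        if t in record:
            outG[record[t]] = f[2] + f[3]
            outM[record[t]] = f[1] + f[3]
            if geno is not None:
                geno[record[t]] = f

    _record(0, f)
    for t in range(1, config.T + 1):
        f = f @ trans
        f = f * w
        f = f / f.sum()
        if config.N != math.inf:
            if rng is None:
                raise ValueError("rng is required for finite N")
            f = rng.multinomial(int(config.N), f) / config.N
        _record(t, f)
    if record_genotypes:
        return outG, outM, geno
    return outG, outM


def simulate_strain_two_locus(
    paramsG: ReversionParams,
    paramsM: ReversionParams,
    config: PopulationConfig,
    epistasis: EpistasisSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Simulate a strain carrying CNVs at two loci (G and M).

    Without epistasis the loci are independent alleles and are simulated as
    two independent single-locus chains. With epistasis the four genotypes
    are tracked jointly: fitnesses are w(G2M2)=1, w(G1M2)=1+sG,
    w(G2M1)=1+sM, w(G1M1)=(1+sG)(1+sM)(1+e), and drift is one multinomial
    draw of size N per generation. Returned trajectories are the marginal
    CNV-carrier frequencies per locus.
    """
    if epistasis is None:
        tG = simulate_locus(paramsG, config, rng, locus="G")
        tM = simulate_locus(paramsM, config, rng, locus="M")
        return tG, tM
    revG, revM = _two_locus_joint(paramsG, paramsM, config, epistasis.e, rng)
    gens = np.asarray(config.sample_gens)
    return (
        Trajectory(gens, 1.0 - revG, locus="G"),
        Trajectory(gens, 1.0 - revM, locus="M"),
    )


@dataclass(frozen=True)
class FixationResult:
    """Generations until the revertant allele reaches a frequency threshold."""

    mean: float
    ci_low: float
    ci_high: float
    n_censored: int
    times: np.ndarray


def fixation_generations(
    params: ReversionParams,
    N: float,
    fix_threshold: float = 0.99,
    rng: np.random.Generator | None = None,
    reps: int = 100,
    max_generations: int = 100_000,
) -> FixationResult:
    """Generations until the revertant frequency first reaches ``fix_threshold``.

    Simulates ``reps`` replicate populations (one if ``N = inf``); replicates
    that never cross within ``max_generations`` are censored at the cap and
    counted in ``n_censored`` (censored replicates enter the mean and
    percentiles at the cap value).
    """
    if not 0 < fix_threshold <= 1:
        raise ValueError("fix_threshold must be in (0, 1]")
    if params.delta == 0 and params.phi == 0:
        raise ValueError("fixation unreachable: delta = 0 and phi = 0")
    n_rep = 1 if N == math.inf else int(reps)
    x = np.full(n_rep, params.phi, dtype=float)
    times = np.full(n_rep, max_generations, dtype=float)
    done = x >= fix_threshold
    times[done] = 0
    t = 0
    while not done.all() and t < max_generations:
        t += 1
        x[~done] = _step(x[~done], params.s, params.delta, N, rng)
        newly = (~done) & (x >= fix_threshold)
        times[newly] = t
        done |= newly
    return FixationResult(
        mean=float(times.mean()),
        ci_low=float(np.percentile(times, 2.5)),
        ci_high=float(np.percentile(times, 97.5)),
        n_censored=int((~done).sum()),
        times=times,
    )


def write_trajectories(path, trajectories: list[tuple[str, str, Trajectory]]) -> None:
    """Write (strain, population, Trajectory) records to CSV."""
    frames = [t.to_frame(strain, pop) for strain, pop, t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[tuple[str, str, Trajectory]]:
    """Read trajectories from CSV with columns strain, population, locus, generation, cnv_freq."""
    df = pd.read_csv(path)
    out = []
    for (strain, pop, locus), grp in df.groupby(
        ["strain", "population", "locus"], sort=False, dropna=False
    ):
        grp = grp.sort_values("generation")
        out.append(
            (
                str(strain),
                str(pop),
                Trajectory(
                    grp["generation"].to_numpy(), grp["cnv_freq"].to_numpy(), str(locus)
                ),
            )
        )
    return out
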