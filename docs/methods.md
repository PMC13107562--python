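# Methods

## Evolutionary model

CNV reversion at one locus is a discrete-generation Wright-Fisher chain on
the revertant frequency x with three forces applied in a fixed order each
generation:

1. **Reversion (mutation).** Each CNV-carrying cell produces a single-copy
   revertant with probability δ per generation: p_mut = x + (1 − x)δ.
   Reversion is unidirectional; re-amplification is not modelled, because
   the process under study is loss of existing amplifications and the
   re-amplification rate is far below the reversion rates of interest.
2. **Selection.** Revertants have relative fitness 1 + s with s ≥ 0
   (reversion is beneficial or effectively neutral once the selecting
   nutrient limitation is removed):
   p_sel = p_mut(1+s) / (p_mut(1+s) + 1 − p_mut).
3. **Drift.** x′ = Binomial(N, p_sel)/N at constant population size N.

The update order is a modelling choice; reordering changes results at
O(sδ) per generation, negligible at the parameter scales involved
(s ≤ 0.3, δ ≤ 10⁻²). A third parameter φ, the revertant frequency at
generation 0, captures standing revertants present when the experiment
starts.

**Population size.** Serial 1:64 back-dilution of a 200 µL culture at
~10⁸ cells/mL passes a bottleneck of roughly 3×10⁵ cells; N = 3×10⁵ is the
default, configurable. The boom-bust cycle (6 generations per transfer,
log₂ 64) is approximated by a constant-N chain; drift in a serial-transfer
regime is dominated by the bottleneck, and a constant N equal to the
bottleneck size is the standard conservative reduction. N = ∞ selects the
exact deterministic recursion, which doubles as the oracle against which
the stochastic simulator is tested (1000 replicates at N = 10⁶ agree with
it within 3 standard errors at every sampled generation).

**Two loci.** Without epistasis the G and M loci are independent alleles:
fitness is multiplicative, 1 + s_GM = (1 + s_G)(1 + s_M), and the joint
4-genotype chain factorizes exactly into two independent single-locus
chains (verified to 10⁻⁹ in tests). With epistasis the four genotypes
(G2M2, G2M1, G1M2, G1M1) are tracked jointly with the double-revertant
fitness multiplied by (1 + e) and a single multinomial drift draw per
generation. The multiplicative (1+e) interaction form is this package's
choice for the interaction term.

**Observation schedule.** Default: 220 generations sampled every 12
(within a 12–18-generation measurement cadence; a multiple of the
6-generation transfer cycle), 3–4 replicate populations per strain.

## Simulation-based inference

The likelihood of a noisy trajectory under this model is intractable, so
parameters are inferred by neural posterior estimation (NPE): draw
θ = (s_G, δ_G, φ_G, s_M, δ_M, φ_M) from the prior, simulate the two-locus
model, add observation noise ε ~ N(0, σ²) i.i.d. per data point
(σ = 0.02, matching the fluctuation level of fluorescence-derived CNV
frequencies; noisy values are not clipped to [0,1], so the network trains
on the same representation it will see at inference), and fit a
conditional masked autoregressive flow q(θ|x) to the (θ, x_noisy) pairs by
maximum likelihood. One network serves both loci and all observations with
the same layout (amortization); single-locus strains use a separately
trained 3-parameter network with k = |sample_gens|.

**Priors.** Independent log-uniform: s ∈ [10⁻³, 0.3], δ ∈ [10⁻⁷, 10⁻²],
φ ∈ [10⁻⁷, 10⁻¹], all configurable. The bounds bracket the regimes of
interest: reversion rates between 10⁻⁵ and 10⁻³ per cell per generation
and selection coefficients up to ~0.085 (CNV fitness 1/(1+s) down to
~0.92).

**Flow.** 5 MADE transforms with alternating autoregressive orders, 50
tanh hidden units, trained with Adam (batch 200, lr 10⁻³) and early
stopping (patience 15) on a held-out validation set. Three details matter
at desk-scale training budgets (the tests train on 2,000 simulations;
10,000 is the intended production scale):

- *Logit parameterization with a logistic base.* θ is mapped to
  z = (ln θ − ln lo)/(ln hi − ln lo) — uniform under the prior — and then
  through the logit. A flow with hard density edges at prior bounds
  systematically underweights the boundary region; in logit space the
  prior is a smooth standard-logistic bell. The flow's base distribution
  is logistic rather than Gaussian for the same reason: an unidentified
  parameter's posterior (≈ the prior) is then exactly representable, where
  Gaussian tails would thin it and overdisperse calibration ranks.
- *Model-structure augmentation.* The clean simulated trajectories are
  re-noised 8 times (the noise model is part of the generative process, so
  fresh draws are free training signal) and each two-locus simulation is
  duplicated with its locus blocks swapped (the loci are exchangeable
  given their parameters).
- *Candidate selection on held-out likelihood.* Three flows are trained
  from independent initializations and the one with the best validation
  NLL is kept. Validation is held out at the level of base simulations,
  not augmented rows — augmented copies share their θ, and a row-level
  split leaks targets into the early-stopping criterion (measurably
  miscalibrating the posterior). Pooling all candidates as a mixture is
  available but widens the posterior and humps the calibration ranks.

**Posterior use.** Point estimates are per-marginal posterior medians.
Draws are restricted to the prior support (the logit map enforces this up
to numerical clipping). Calibration is monitored by simulation-based
calibration (SBC): ranks of true parameters within posterior samples over
fresh prior draws, tested for uniformity by chi-square per marginal with
Bonferroni correction across the six marginals.

**Collective posterior.** Replicate populations of a strain share one θ,
so a posterior conditioned on all replicates is proportional to
p(θ)^(1−n) Π_i q(θ|x_i). It is sampled by sampling-importance-resampling
with an equal mixture of the individual posteriors as proposal, truncated
importance weights (cap at mean × √N) and the effective sample size
reported (warning below ESS 50). The operator is verified against the
closed-form product posterior of a conjugate-normal toy model. A caution
documented as a limitation: multiplying several copies of the *same*
approximate posterior raises its approximation errors to the n-th power,
so at desk-scale training budgets the collective posterior can drift into
regions no individual posterior supports; the ESS diagnostic flags this.

**Identifiability.** A reverting trajectory constrains s strongly (the
slope of the sweep) but only the combination φ + δ/s′ (s′ = s/(1+s)) of
the two supply parameters: standing revertants (φ) and recurrent reversion
(δ) seed the same exponential takeoff. Posterior medians of δ are
therefore expected to be order-of-magnitude, not point, estimates — the
recovery tests assert exactly that — and φ inherits the complementary
uncertainty.

**Posterior predictive checks.** Trajectories are simulated for (default)
100 posterior draws; reported are the pointwise predictive median, the
central 95% envelope, the fraction of observed points inside the envelope,
and the RMSE between observation and predictive median.

## Competition-assay regression

The assay fixes the starting query:reference mix, so the intercept
b0 = ln(starting ratio) is known and only the slope is fitted:
slope = Σ g(y − b0)/Σ g² over all replicate time points pooled (default
generations 0–16 sampled every 2–4, three replicates). Relative fitness is
slope + 1. The standard error uses residual variance with n − 1 degrees of
freedom (one fitted parameter); the CI and the two-sided p-value of
slope = 0 come from the t distribution, significance at α = 0.05. b0
defaults to the theoretical value of the configured mix (measured b0 can
be passed instead). Because the intercept is anchored at generation 0, the
estimator is *not* invariant to shifting the generation axis — generations
must be counted from assay start; this is tested. Replicates are pooled
into one regression rather than averaging per-replicate slopes, making the
p-value a pooled-error test.

## CNV cost scoring

Per-gene duplication costs (log₂ fold-change units) from a systematic
screen are summed over the amplified region: significant genes
(FDR < 0.05 in the source screen — the flag is taken from the table, never
re-estimated) contribute their measured cost, non-significant genes the
genome-wide mean cost (−0.33), and the bracketed sum is multiplied by the
number of extra copies (copy number − 1). Aneuploidy cost applies the same
formula to all genes of the duplicated chromosome; a double aneuploidy is
the exact sum of the two singles. Gene membership in a segmental region is
whole containment within the breakpoints (boundary-straddling genes are
excluded; an arbitrary but documented convention). The cost-fitness
Pearson correlation ships with a bias-corrected bootstrap CI by default
(10,000 seeded resamples; the printed intervals of such correlations are
asymmetric, which Fisher-z intervals cannot produce; Fisher-z is available
by flag).

## Gating and loss dynamics

Copy-number classification uses normalized fluorescence (per-cell
fluorescence / forward scatter). For each control strain of known copy
number (0, 1, 2) the central 95% quantile interval is computed; adjacent
class boundaries sit at the midpoint between one interval's upper edge and
the next's lower edge (the same arithmetic for overlapping and disjoint
intervals). This quantile construction stands in for manual gate drawing;
the achieved containment per control is reported so any shortfall from the
95% target is visible. The three intervals partition (0, ∞), so class
fractions sum to 1 exactly. With the default synthetic fluorescence model
(log-normal per class, shared log-scale σ = 0.18, medians 0.05/1/2) the
1-vs-2-copy Bayes error at the optimal threshold is ~2.7%, inside the
1–5% band of a small-but-real overlap.

Phase times: for a loss threshold of q% (25/50/75 = early/middle/late),
the first generation at which %CNV ≤ 100 − q, linearly interpolated
between flanking observations (reported phase times fall between sampling
points, implying interpolation; the exact rule is this package's choice).
Populations that never reach a threshold are censored; in paired t-tests
between CNV types they enter at the experiment horizon (220 generations),
with censoring counts reported alongside the test — the alternative
encodings (exclusion, last-observation) are not used because dropping
censored populations would bias toward fast losers. Pairing is by list
position (the two loci of a double aneuploid are measured in the same
cells; across strains, pairing by within-strain index is arbitrary and
documented as such).

PNCN: per-window mean sequencing depth divided by the genome-wide mean
depth — copy number per chromosomal copy, invariant to sequencing effort;
windows are 0-based half-open.

## Synthetic data

The generators mirror the study design: 220 generations sampled every 12,
3–4 replicates, 10⁴ cells per flow sample, observation noise N(0, 0.02),
cost tables recentred so the all-gene mean is exactly −0.33, per-base
Poisson depth at mean 50×. They reproduce the statistical structure the
analysis assumes — not features of real data such as batch drift of the
cytometer, autofluorescence tails, mapping artifacts in depth tracks, or
clonal interference between simultaneously segregating mutations. Passing
recovery tests on these inputs therefore demonstrates correctness of the
estimators under the stated model, not robustness to violations of it.
Every generator is bit-reproducible given a seed and emits its ground
truth.

## Problem sizes and numerical choices

The test suite trains the flow on 2,000 simulations (a scaled-down
training budget; inference quality statements in the tests are calibrated
to it), uses 1000 replicates at N = 10⁶ for the drift-oracle check, 200
SBC draws with 99 posterior samples each, and 10³–10⁴ Monte-Carlo
repetitions for estimator-calibration checks. Frequencies are kept in
[0, 1] by construction, genotype frequencies renormalized each generation
(deviations ≤ 10⁻¹²). Flow log-scales are soft-bounded at |α| ≤ 5 by a
tanh squash for conditioning; the logit map clips z at 10⁻⁶ from the
bounds. Degenerate inputs raise informative errors (δ = φ = 0 fixation,
zero competition counts, unordered control medians, zero-variance
correlations).

## Known limitations

- Constant-N Wright-Fisher ignores the within-cycle demography of batch
  growth (lag/exponential/stationary phases) and chemostat dynamics.
- The epistasis interaction form is a single multiplicative coefficient.
- NPE quality at 2,000 training simulations leaves δ/φ order-of-magnitude
  estimates only; the collective posterior amplifies shared flow bias (see
  above) and should be read together with its ESS.
- Gate construction assumes unimodal control distributions with ordered
  medians; compensation/spillover and debris/doublet pre-filtering are out
  of scope.
- The paired-t encoding of censored phase times at the horizon compresses
  differences between very slow losers.
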