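# Methods and design notes

This note records the statistical conventions, simulator assumptions and
open design choices behind `polysel`.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Fitness components and the exact product identity

All quantities are daughter-based: in the motivating design only
daughters carry the paternity marker, so *T* (reproductive success), *N*
(mate productivity) and *P* (paternity share) count daughters only.

*P* is defined as the **pooled** share — total daughters sired divided by
total daughters produced by the male's mates — rather than the mean of
per-female proportions.  With the pooled definition and *N* the
arithmetic mean of mates' outputs, `T = M · N · P` holds exactly for
every male with at least one mate, which in turn makes the variance
decomposition ledger exact.  The per-female proportions are still
computed (`MaleSummary.per_female_share`) for descriptive use.

The re-mating rate is total copulations divided by unique mates, so 1.0
means no re-mating.  Males with `M = 0` get `T = 0` and undefined
(`NaN`) *P*, *N* and re-mating rate; downstream statistics exclude them
with a logged count.

## Opportunity indices and the bootstrap

Opportunity indices are squared coefficients of variation with the
sample (n−1) variance throughout; the package never uses the population
variance, so indices computed here are directly comparable with the
common tooling in the field.  Confidence intervals use the percentile
bootstrap (default 10,000 resamples) resampling focal males with
replacement; group-level resampling is available (`unit="group"`) for
designs with more than one focal per group.  Resamples where the index
is undefined (zero mean) are dropped and counted.  Two estimates are
declared different only when their 95% intervals are disjoint — a
deliberately conservative rule.

Indices and gradients are standardised *within treatment* (each arm's
males divided by that arm's means), since paternity is only assignable
for one focal per group and cross-group standardisation keeps the
pre- and post-copulatory indices comparable.

## Gradients

The Bateman gradient is `β = cov(t, x)/var(x)` with `t` relative
(mean-1) reproductive success, fitted by OLS.  Mean-standardisation
divides the predictor by its mean; variance-standardisation z-scores it.
The identity `β^σ = β^μ · CV(x)` (and hence `= β^μ·√I_S`, the Jones'
index) is implemented as two genuinely independent code paths — a direct
fit on the z-scored predictor and the product `β^μ·CV` — and is asserted
to 1e-10 in the tests.

Multivariate gradients fit relative *T* on *M*, *P* and *N* jointly.
Default covariates are vial fecundity (continuous: total daughters in
the group) and experimental replicate (categorical, dummy-coded).
Zero-variance components carry no selection information and are dropped
with a warning; genuine collinearity among non-constant columns is an
error naming the offending columns.  One systematic collinearity is
worth knowing about: when every focal male mates every female, vial
fecundity equals `M·N` exactly and the mean-standardised design is
singular.  The pipeline then refits with the replicate covariate only
and records that choice in its summary.

Significance of gradient terms can additionally be read from a refit on
square-root-transformed raw *T* (the Box–Cox λ = 1/2 case, which tames
the right skew of count fitness data); reported gradient estimates
always come from the standardised fits.  Cross-treatment gradient
differences are tested as the treatment × predictor interaction in a
pooled model with within-treatment standardisation — the pooled-model
convention is this package's choice.

## Adjusted paternity share

`P_adj = P(n−1)/(P(n−2)+1)` maps a share observed against *n* maters of
the same female onto the two-male standard: a fair-raffle share of 1/n
maps to 1/2 for every *n*, `n = 2` is the identity, and 0/1 are fixed
points.  *n* is the total number of males observed to mate the female,
focal included; that is the only reading under which the n = 2 identity,
the fair-raffle mapping and the exclusion of single-mater females are
simultaneously coherent.  Excluded per male (and counted): females mated
by only one male, females the focal never mated, and females with no
scored daughters.

## Variance decomposition

Relative fitness factorises as `t = m·p·n`; the ledger reports the three
component variances and the three pairwise covariances **entering
once**, with the residual *D* defined as whatever closes
`var(t) = Σ terms + D` exactly.  Published component tables in this
literature are ambiguous about whether covariances absorb the
conventional factor of two; defining *D* as the closing residual makes
the output well-defined under either convention, and the package's
residual reproduces the printed residuals of the motivating study's
component table from its printed components.  Percent contributions are
descriptive, computed against var(t) by default (configurable to the
component sum), and need not total 100 because *D* is excluded.

## SCI, SCIC and the randomization null

Polyandry counts `k_j` are unique male partners, not copulation counts,
and the randomization operates on the unique-pair binary incidence
matrix; copulation multiplicities are not shuffled.  SCI is the harmonic
mean of a male's mates' `k_j`; SCIC pools **all** males (focal and
rival) within a treatment, divides SCI and *M* by their means, and takes
the OLS slope.  A constant-SCI group gives an exact zero slope; constant
*M* (e.g. a saturated matrix) makes the slope undefined and is flagged.

The null holds each vial's row and column sums fixed and samples
uniformly from the family of admissible binary matrices: by exhaustive
enumeration whenever the family has ≤ 10,000 members (always true for
4 × 4 groups), otherwise by a checkerboard-swap Markov chain (symmetric
proposals, hence uniform stationary distribution) with a thinning
interval of 100 × (number of 1-entries) between samples and a burn-in of
ten intervals.  Uniformity of the chain is verified against enumeration
by chi-square in the tests.  Vials whose margins admit a single matrix
pass through unchanged and are flagged.  Three tails are reported;
`p_lower` (proportion of null ≤ observed) is the headline because the
biological hypothesis is directional (negative SCIC under saturation).
This tail convention is an interpretation: published analyses of this
kind report a single randomization p without naming the tail.

The quasi-likelihood regressions of *T* (overdispersed Poisson) and *P*
(overdispersed binomial) on SCI use Pearson-χ² dispersion and
t-distributed Wald tests, matching the output of R's `glm` with
`quasipoisson`/`quasibinomial` families; the test suite pins both models
to coefficients from such a reference fit.

## The simulator

The simulator emulates the experimental design, not fly behaviour in
detail.  Per group: 1 focal + `n_rivals` (3) rival males and
`n_females` (4) females, observed `n_days` (4) days of `window_slots`
(8) discrete mating opportunities.  Each slot, one receptive female (if
any) is chosen uniformly and paired with a male drawn proportionally to
mating propensity; the focal's propensity (1.5 vs. 1 per rival) makes
his expected share of matings 1/3, the calibration reported for the
motivating experiment.  After mating, the female draws a geometric
refractory duration (memoryless — the simplest one-parameter receptivity
model); its mean is the treatment knob: 24 slots for the control-like
arm, 3 for the high-polyandry arm, values chosen to bracket the
experiment's duration so control females re-mate rarely within the
observation window while manipulated females re-mate within the same
morning.  Clocks tick only during observation slots.

Mated females draw daughters from
`Poisson(fecundity_mean × multiplier × n_days)` with
`fecundity_mean = 12`/day (so ≈ 48 daughters per female over the
experiment, the order of magnitude implied by the motivating study's
≈ 11,000 daughters over 58 × 4 females); the high-polyandry arm uses a
0.85 multiplier to mirror the mildly reduced fecundity of
receptor-lacking females.  Sires are drawn multinomially with tickets
proportional to copulation counts; `last_male_weight` (default 1 — a
fair raffle) multiplies the final mate's tickets to model last-male
sperm precedence.  Unmated females produce nothing.

A single seeded generator drives each arm, with draws in a fixed
documented order, so identical configs are bit-reproducible; the paired
arms use `seed` and `seed + 1`.

**What the simulator does not emulate** — courtship and male–male
interference, sperm-storage organ dynamics and passive sperm loss,
egg-to-adult survival variation, female choice of specific males, and
per-slot mating kinetics calibrated to real observation data
(`window_slots` is a free abstraction).  Consequently, passing
directional tests shows the statistical machinery recovers the
qualitative regime the design creates (lower `I_S`, unchanged `I_P`,
variance shifting from *M* to *P*, re-mating rewarded under sperm
precedence); it does not certify effect sizes in real data.  At small
numbers of groups, some contrasts (notably the var(*P*) percent share)
are noisy; the directional checks are therefore run at 100 groups per
arm, a size at which they are stable across seeds, while unit tests use
25 groups for speed.

## The trio resampler

"One male per trio, no replacement" is read as: within one iteration
each twice-mated female contributes exactly one of her two males;
iterations are independent.  I_P is computed from the sampled shares
pooled across re-mating intervals.  Iterations whose sampled shares are
all zero (I_P undefined) are dropped and counted.

## Numerical conventions and degenerate inputs

* Sample (n−1) moments everywhere; means of exactly zero raise errors
  rather than returning infinities.
* OLS designs are rank-checked; saturated designs (parameters ≥ males)
  are rejected rather than silently fitted with zero residual df.
* Randomization and bootstrap p-values are plain proportions (no +1
  smoothing); equality is tested with a 1e-12 tolerance so enumerated
  point-mass nulls behave correctly.
* All stochastic stages accept explicit seeds; the pipeline fans a
  single seed into named per-stage substreams via `SeedSequence`.

## Problem sizes used in the checks

The acceptance script simulates 100 groups per arm (10,000 bootstrap
resamples, 1000 SCIC randomizations), verifies the fixed-margin sampler
with 50,000 draws against an enumerated 3 × 3 family, and the trio
resampler with 20,000 iterations against a 4-outcome enumeration; these
sizes give Monte-Carlo error comfortably below the effects being
checked.
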