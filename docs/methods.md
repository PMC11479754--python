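# Methods

## The problem

A cohort study observes every individual daily from birth to death and asks
whether two groups — here offspring of young versus old parents, indexed by
birth order ("first" vs. "fifth") as a proxy for parental age — differ in
their mortality trajectories, and if so, *where*: in the level of mortality
at the start of life, in the rate at which mortality rises with age, or in
the late-life plateau. A difference concentrated in the initial level
(greater frailty from birth) and one concentrated in the rate of ageing
carry very different biological interpretations for parental-age effects
such as the Lansing Effect.

## Mortality models

Four hazard families, all per day, with survivorship l(t) and hazard h(t):

| family      | l(t)                                   | h(t)                              | k |
|-------------|----------------------------------------|-----------------------------------|---|
| exponential | exp(−a t)                              | a                                 | 1 |
| Gompertz    | exp(−(a/b)(e^{bt} − 1))                | a e^{bt}                          | 2 |
| Weibull     | exp(−(a t)^b)                          | a b (a t)^{b−1}                   | 2 |
| logistic    | (1 + (a c/b)(e^{bt} − 1))^{−1/c}       | a e^{bt} / (1 + (a c/b)(e^{bt}−1)) | 3 |

`a` (> 0, per day) is the initial mortality: the hazard at age zero for the
exponential, Gompertz, and logistic families. `b` (> 0, per day) is the
mortality-rate parameter. `c` (> 0, dimensionless) is the logistic
heterogeneity/deceleration parameter: a gamma-frailty mixture of Gompertz
individuals produces exactly this population hazard, which plateaus at b/c
late in life, and c → 0 recovers Gompertz (implemented through the series
limit below). The Weibull form here keeps `a` level-like and `b` shape-like;
other conventions exist, and this one is a documented package choice, not a
claim about any particular prior analysis.

## Likelihood for daily census data

Observed lifespans are interval censored: a recorded lifespan L means death
during [L, L+1) days (death is detected on the day the last offspring
detaches, so L is a lower bound on continuous age at death). The default
log-likelihood is therefore Σ ln[l(L) − l(L+1)]. A continuous-density mode
Σ ln[h(L) l(L)] is provided for sensitivity analysis, because published
analyses of such data do not always state which was used. AICc uses the
number of individuals as n (one lifespan datum per individual).

## Optimization

Derivative-free Nelder–Mead on log-parameters (positivity by construction),
objective tolerance 1e-8, restarted from a log-spaced grid
(a ∈ [1e-4, 0.5], b ∈ [1e-3, 1], c ∈ [1e-2, 1e2]) plus nested warm starts:
the exponential interval MLE has the closed form ln((1 + L̄)/L̄) and seeds
the Gompertz fit; the fitted Gompertz seeds the logistic fit with c near
zero. The warm-start chain makes the fitted log-likelihoods respect
exponential ≤ Gompertz ≤ logistic up to optimizer tolerance, which the test
suite asserts. Ties between converged starts are broken by the smaller
parameter-vector norm. Non-convergence is flagged in results, never
silently dropped.

The joint two-group logistic candidates ("abc" … "ABC": capital = distinct
between groups, k = 3 + #capitals) are optimized directly in the reduced
space, so common parameters are single coordinates shared bit-identically by
both groups. Each candidate starts from (i) the two separate single-group
logistic fits (log-means on common coordinates), (ii) the pooled fit, and
(iii) a small grid. With these starts the fully distinct candidate "ABC"
reproduces the sum of the separate fits and "abc" the pooled fit to ~1e-10.

## Numerical notes

* Survival is computed in log space; ln l for the logistic family uses
  log1p, and for c < 1e-6 the Gompertz series limit −u(1 − cu/2) with
  u = (a/b)(e^{bt} − 1), avoiding cancellation in the (·)^{−1/c} exponent.
* Daily death probabilities use l(L)·(−expm1(ln l(L+1) − ln l(L))), which
  stays accurate deep in the tail; ages where l has underflowed to 0 return
  probability 0 (they telescope exactly to l(1) over any horizon).
* Likelihood terms that underflow are clamped at 1e-300 (warned in the
  public API, silent inside optimizer loops).

## Resampling inference

Life-history traits (lifespan, age at first reproduction, total offspring,
intrinsic rate of increase r) are skewed, so group comparisons use a
two-sided randomization test on |difference in group means| — exhaustively
enumerated when the number of label assignments is below 2e5, otherwise
sampled with the add-one correction p = (count + 1)/(n_perm + 1), so p is
never reported as exactly 0 (default 10,000 permutations). Confidence
intervals for mean differences are stratified percentile bootstrap
(resampling within group, default 10,000 replicates, level 0.95). Model
parameters get percentile CIs by refitting to within-group bootstrap
replicates; each replicate is refit from the original optimum only (a full
multi-start per replicate would be prohibitively slow and the replicates
are near the base optimum), with non-converged replicates counted and a
hard warning above 10%. Survival confidence bands are pointwise percentile
envelopes of l(t) over the parameter draws — pointwise, not simultaneous,
as stated in the output metadata.

## Individual-level demography

For an individual with daily offspring counts m(1..L): age at first
reproduction is the first day with m > 0; total offspring is Σ m; r is the
natural log of the dominant eigenvalue of the individual's L×L Leslie
matrix with fecundity row m and unit survival subdiagonal — the individual
demonstrably survived each day it was observed, so its realized survival is
1. That eigenvalue equals the positive root of the Euler–Lotka equation
Σ m(x) λ^{−x} = 1, which is strictly decreasing in λ and bracketed in
[0.5, Σm + 1]; the implementation solves the root to near machine precision
and cross-checks it against a dense eigen-decomposition on every call
(tolerance 1e-9). Individuals with no offspring (impossible under the death
definition, possible in unvalidated data) get r = NaN, are flagged, and are
excluded from r aggregates with a logged count.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: two
groups of 191 and 192 individuals; integer lifespans by inverse-CDF
sampling of a logistic model, with continuous death time T mapped to the
census day L = ⌊T⌋ and draws below day 1 resampled (the resampled fraction
is reported; < 5% is expected and ~0.1–1% realized at defaults); age at
first reproduction 1 + Poisson (group means 2.7 and 2.2 days, the
high-mortality group earlier by 0.5 day); one guaranteed birth at the
sampled first-reproduction age, Bernoulli(0.35) births on subsequent days,
and a forced birth on the final day so the operational death definition
m(L) ≥ 1 holds by construction.

Default mortality is logistic with a = 0.001 vs. 0.01 (10-fold initial-
mortality difference), common b = 0.25 and c = 1.0. These values were
chosen for identifiability: because observed lifespans are truncated at
day 1 while the likelihood is unconditioned, the fitted model converges to
a pseudo-true optimum that drifts away from the generating parameters as
the truncated mass grows; at ~2% truncation the drift is large enough that
the joint model selection systematically prefers fully distinct parameters,
whereas at the default ~0.1–1% truncation the drift is negligible relative
to sampling error at the n used here. The resulting mean lifespans
(~22 vs ~13 days) are realistic for duckweed reproductive lifespans; the
between-group gap is larger than in the motivating system, and the
generator is a stylized rehearsal of the analysis, not an estimate of any
real cohort. The fecundity process in particular ignores senescent decline
in daily fecundity and inter-birth correlation. Passing pipeline tests
therefore demonstrate that the machinery identifies the structure it
assumes, at the effect sizes configured — not that real data meet those
assumptions.

All randomness flows from a single integer seed; every stochastic result
object records its seed and replicate counts, and rerunning with the same
config is bit-identical.

## Problem sizes used in the test suite

Recovery and calibration checks run at the sizes that make their tolerances
meaningful while keeping the suite fast: exponential-MLE oracle equivalence
on 100 random datasets; Euler–Lotka/eigenvalue agreement on 1,000 random
schedules; logistic parameter recovery on 50 cohorts of n = 2000 (median
relative error thresholds 25% for a, 15% for b — a and c are partially
confounded at this n); joint structure recovery on 100 two-group datasets
of n = 400/group; permutation type-I error over 1,000 null simulations at
n = 50/group with 999 permutations; bootstrap coverage over 200 replicates
at n = 200/group with 1,000 resamples; the full-pipeline rehearsal at the
default cohort size with 2,000 permutations/bootstrap replicates and 150
model-bootstrap replicates.

## Known limitations

* No right censoring: every individual is assumed observed to death, as in
  the emulated design; censoring-heavy designs need a different likelihood.
* No covariates, Makeham background mortality, or more than two groups.
* The day-1 truncation bias described above is a real feature of
  unconditioned fits to lifespans that are ≥ 1 by construction; it is
  negligible only when early mortality is small relative to one census
  interval.
* Percentile bootstrap and pointwise bands only (no BCa, no simultaneous
  bands).
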