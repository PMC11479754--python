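# lansing

Two-group demographic survival analysis for daily-census cohort studies,
motivated by the Lansing Effect — the propensity for offspring of older
parents to live shorter lives than offspring of younger parents. Given two
cohorts observed daily from birth to death (e.g. first-born vs. fifth-born
offspring, with birth order a proxy for parental age), the package asks not
just *whether* their survival differs but *where* on the mortality
trajectory the difference lies: in the initial mortality level, the rate of
demographic ageing, or the late-life plateau.

It is written for biodemographers and evolutionary ecologists analysing
small-organism cohort data (duckweed ramets, rotifers, flies, ...) where
every individual is followed to death and lifespans are recorded in whole
days.

## The analysis

**Stage 1 — which mortality family?** Four hazard models, fitted per group
to interval-censored daily lifespans (a recorded lifespan *L* means death
during [*L*, *L*+1)) by maximum likelihood and ranked by AICc:
exponential *l*(*t*) = e^(−*at*); Gompertz *l*(*t*) = exp(−(*a*/*b*)(e^(*bt*)−1));
Weibull *l*(*t*) = exp(−(*at*)^*b*); and the logistic (Gompertz–logistic)
model

> *l*(*t*) = (1 + (*ac*/*b*)(e^(*bt*) − 1))^(−1/*c*)

with initial mortality *a*, mortality-rate parameter *b*, and heterogeneity
(deceleration) parameter *c* (c → 0 recovers Gompertz).

**Stage 2 — where do the groups differ?** The two groups are fitted jointly
under all 2³ = 8 logistic candidates in which each of (*a*, *b*, *c*) is
independently common or distinct between groups ("Abc" = distinct *a*,
common *b*, *c*; k = 3 + #distinct), ranked by AICc with Akaike weights
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2).

**Traits and inference.** Per-individual life-history traits — reproductive
lifespan, age at first reproduction, total offspring, and the intrinsic
rate of increase *r* = ln λ from an individual-level Leslie matrix (checked
against the Euler–Lotka root Σ_x m(x) λ^(−x) = 1) — are compared by
two-sided randomization tests and stratified percentile-bootstrap CIs, and
fitted survival curves get bootstrap confidence bands.

A synthetic-cohort generator reproduces the statistical structure this
design assumes (10-fold distinct initial mortality, common *b* and *c*,
group-shifted age at first reproduction), so the whole pipeline can be
rehearsed end-to-end without any real data. See `docs/methods.md` for
modelling details and caveats.

## Worked example

```python
import lansing as L

result = L.run_full_pipeline(L.CohortConfig(seed=0),
                             n_permutations=2000, n_boot_mean=2000,
                             n_boot_model=150)
print(result.stage2_table.head(4).round(4).to_string(index=False))
print(result.traits.round(4).to_string(index=False))
```

prints (stage-2 joint selection, top candidates):

```
model a_status b_status c_status  k      AICc  delta_AICc  weight  converged
  Abc distinct   common   common  4 2570.2397      0.0000  0.3996       True
  ABc distinct distinct   common  5 2571.0706      0.8309  0.2637       True
  AbC distinct   common distinct  5 2571.9481      1.7084  0.1701       True
  ABC distinct distinct distinct  6 2572.3186      2.0789  0.1413       True
```

The generating truth (distinct *a*, common *b*, *c*) is the AICc-best
candidate, and the four distinct-*a* candidates jointly carry ~97% of the
Akaike weight: the survival difference is localized to initial mortality.
The trait table shows every expected contrast:

```
                 trait  mean_first  mean_fifth    diff  pct_diff  n_first  n_fifth  p_value  ci_lower  ci_upper
              lifespan     20.8010     13.2969  7.5042   36.0759      191      192   0.0005    6.0132    8.8443
age_first_reproduction      2.7801      2.2604  0.5197   18.6931      191      192   0.0005    0.2523    0.7968
       total_offspring      8.0524      5.5365  2.5159   31.2442      191      192   0.0005    1.8912    3.1001
                     r      0.2974      0.3096 -0.0122   -4.0972      191      192   0.3618   -0.0359    0.0125
```

The high-initial-mortality ("fifth") group lives shorter, starts
reproducing ~0.5 day earlier, and produces fewer offspring — yet its
earlier reproduction gives it the *higher* intrinsic rate of increase
(diff is first − fifth throughout; permutation p-values are add-one
corrected, so the floor at 2000 permutations is 1/2001 ≈ 0.0005).

The same analysis runs from the shell on any long-format cohort CSV
(`individual_id,group,day,offspring_count`):

```sh
lansing simulate --output cohort.csv --seed 0
lansing full --input cohort.csv --output-dir results/ --seed 0
```

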