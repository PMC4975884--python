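# Methods

## Setting and model

`spinedecline` estimates how fast degenerative imaging features of the
lumbar spine progress with age in asymptomatic adults, using only
age-aggregated summaries of the kind published in cross-sectional imaging
studies and meta-analyses. Two data structures are supported:

* **Prevalence tables** — per endpoint, an ordered set of age groups, each
  with a sample size `n_j` and a prevalence percentage `p_j` of a binary
  finding.
* **Continuous tables** — per endpoint, age groups with sample size `n_j`,
  mean `μ_j` and standard deviation `σ_j` of muscle fatty infiltration (FI,
  % of the muscle cross-section).

Every subject of a group is assigned the group's single *representative
age*; within-group age variation is deliberately not modelled, because the
aggregates contain no information about it. Decline rates are therefore
identified purely from the between-group trend.

### Binary path (deterministic reconstruction + logistic AME)

Each group is expanded into `k_j = round(n_j p_j / 100)` ones and
`n_j − k_j` zeros, rounding half away from zero. The expansion is
deterministic, not Bernoulli sampling: the aggregate prevalences are treated
as exact proportions, so a single fit (not a simulation) is appropriate, and
the reconstruction conserves each group's prevalence to within the rounding
bound `0.5/n_j` (property-tested).

A logistic regression on age is fitted by maximum likelihood (IRLS via
statsmodels GLM/Binomial; deviance tolerance 1e-12, max 50 iterations, and a
post-fit score check — the fit is rejected if the score norm exceeds 1e-8
relative to the sample size). The reported decline rate is the average
marginal effect of age over the reconstructed sample,
`AME = (100/n) Σ β p̂ᵢ(1−p̂ᵢ)` in percentage points per year — the sample-AME
flavour (not the effect at the mean covariate), which is what standard
`margins` machinery reports by default. Its standard error comes from the
delta method with the analytic gradient

```
∂AME/∂α = (100/n) Σ β wᵢ (1−2p̂ᵢ),      wᵢ = p̂ᵢ(1−p̂ᵢ)
∂AME/∂β = (100/n) Σ [wᵢ + β xᵢ wᵢ (1−2p̂ᵢ)]
```

and the full estimated parameter covariance. Tests cross-check the SE
against a finite-difference Jacobian (1e-6), against statsmodels'
`get_margeff`, and against a 100,000-draw parametric bootstrap of the
parameter covariance (2%). CIs use ±1.96·SE (normal quantile, not t).

Grouped-binomial and expanded-Bernoulli representations give identical
fits; log-likelihoods are always evaluated on the per-subject Bernoulli
scale (dropping the binomial coefficient) so the two representations are
exactly comparable. Perfect separation is a hard error, never a silent
penalised fit: the bundled tables never separate, so separation signals
malformed input. Separation is detected when any fitted linear predictor
exceeds ±30 (probabilities saturated at 0/1 to beyond double precision).

### Continuous path (Monte Carlo linear regression)

Per iteration, `n_j` draws from `N(μ_j, σ_j)` per group are regressed on the
representative ages by OLS; the slope `b` (FI %-points per year) and its
standard OLS standard error `se` are recorded. Draws are *not* truncated to
[0, 100] FI%: the group summaries describe plain normal variation and
truncation would bias the reconstructed means. Default 10,000 iterations;
the cross-iteration mean/SD/min/max of `b` and `se` are reported, with the
95% CI `mean(b) ± 1.96·mean(se)`. An empirical percentile CI
(2.5th/97.5th of the `b` draws) is available behind a flag; the normal rule
is the default because it is the construction the summary statistics
support directly. The exact expectation of `b` — the size-weighted OLS slope
through the group means — is exposed as `expected_slope` and used as the
convergence oracle in tests (the observed bias is bounded by
`4·SD(b)/√iterations`).

The per-iteration regression is computed by a closed-form simple-regression
path vectorised across iterations; a test pins it to the per-iteration
`draw_continuous` + `fit_gaussian` route at 1e-10 and to bit-identical
draws.

### Linearity check

Each linear-age fit is compared with the saturated model (one parameter per
age group) by likelihood ratio: `LR = 2(ℓ_sat − ℓ_lin)` on `#groups − 2`
degrees of freedom. With two groups the linear model is itself saturated
(df 0, p ≡ 1). For Gaussian fits the stored log-likelihood uses the ML
variance estimate so nested fits are comparable. Zero-residual (noise-free)
data makes the Gaussian log-likelihood unbounded and the test ill-defined;
tests use noisy draws for this check. All bundled endpoints pass the
linearity check at the 0.05 level (asserted in the suite).

## Age coding

Representative ages are a modelling choice with direct leverage on the
slope denominators:

* decade tables (prevalence endpoints and the four-decade muscle study) use
  the equally spaced grid 25/35/45/55 (`age_low + 5`), including the last
  group printed as 50–60 — any equally spaced coding gives identical slopes,
  and this grid also matches the published combined-muscle estimate exactly;
* the two-group muscle study (18–25 vs 45–60) uses true midpoints
  21.5/52.5, giving a 31-year span.

Both defaults are per-source settings; an explicit age list can override
them. Slopes, their SEs and AMEs are invariant to translating all ages by a
constant (tested at 1e-10).

## Randomness and reproducibility

All stochastic draws flow through `RngSpec(seed, stream)`: the stream name
is hashed (SHA-256, two 31-bit words) into a `SeedSequence` spawn key, so
every (endpoint × iteration) has an independent, individually reproducible
PCG64 stream. Identical specs reproduce results bit-for-bit (JSON outputs
byte-identical); distinct stream names are statistically independent.

## Synthetic-data generator and its limits

`recovery_generator` fabricates continuous aggregates whose group means lie
exactly on a known line with a chosen noise SD; pushing them through the
Monte Carlo pipeline must recover the true slope within
`4·SD(b)/√iterations` (tested for slopes −0.3, 0 and +0.3 %-points/year,
with the four-decade, 20-per-group design and noise SD 5 FI% — values in
the range of the real muscle tables).

What the generators emulate is exactly the aggregate structure the real
inputs have: fixed group sizes, exact group prevalences, normal within-group
outcome variation, and a single representative age per group. They do not
emulate within-group age heterogeneity, non-normal or skewed FI
distributions, measurement error in the published summaries, or any
covariance between endpoints measured on the same subjects. Passing tests
therefore demonstrate fidelity of the estimation pipeline to this aggregate
model, not robustness to those real-data features.

## Known limitations

* Decline rates compare a prevalence derivative (%-points of *subjects
  affected* per year) with a mean-FI derivative (%-points of *fat content*
  per year); the common unit makes them comparable as rates of change, not
  as the same biological quantity.
* Two prevalence endpoints carry imputed sample sizes (n = 100) for their
  two youngest groups; these are flagged in the data model
  (`n_assumed`) and narrow the CIs relative to typical reported group sizes.
* The published per-endpoint simulation summaries this pipeline is checked
  against contain internal inconsistencies of a few thousandths of a
  %-point/year for the two-group muscle study (the printed means imply
  mutually inconsistent age spans across endpoints sharing the same
  groups), and one CI-separation statement in the source prose contradicts
  the corresponding printed CI bounds (1.472 vs 1.477). The acceptance
  tests assert the printed claims as stated and leave the irreconcilable
  cases failing rather than widening tolerances; see the test docstrings.
* Cross-sectional age trends are not longitudinal ageing: cohort effects
  cannot be excluded, and the asymptomatic samples span 18–60 only.

## Problem sizes

Default analyses run the full published designs: 8 prevalence endpoints
(n = 284–1603) fitted once each, and 7 muscle endpoints (n = 24 or 80) at
10,000 Monte Carlo iterations. The whole default pipeline completes in a
few seconds on one CPU; the test suite uses reduced iteration counts
(100–2,500) for properties whose tolerances scale with √iterations, and the
full 10,000 for comparisons against the published summaries.
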