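# spinedecline

Yearly decline rates of lumbar spinal-column degeneration and paravertebral
muscle quality, estimated from **published age-aggregated imaging summaries**
of asymptomatic adults (18–60 years).

## The problem

Prevalences of degenerative imaging findings (disk degeneration, disk signal
loss, disk bulge, …) are published per age decade, and paravertebral muscle
fatty infiltration (FI %, for multifidus MF, erector spinae ES and psoas) is
published as per-age-group means and SDs — but never as individual-level
data. To put all of these on a single comparable scale (percentage points of
decline per year of age), `spinedecline` reconstructs synthetic
individual-level samples from the aggregate tables and fits age regressions:

* **Binary findings** — each age group of size `n_j` with prevalence `p_j` is
  expanded deterministically into `round(n_j p_j)` positive and the remaining
  negative subjects, all carrying the group's representative age `x_j`. A
  logistic regression `logit P(y=1) = α + β·age` is fitted and the decline
  rate reported as the **average marginal effect** (AME) of age,

  `AME = (100/n) Σᵢ β p̂ᵢ(1−p̂ᵢ)`  [%-points/year],

  with a delta-method standard error propagated from the full parameter
  covariance and a 95% CI of ±1.96·SE.

* **Continuous FI endpoints** — a Monte Carlo simulation draws, per
  iteration, `n_j` normal variates `N(μ_j, σ_j)` per age group and fits an
  ordinary least-squares line on age; the slope `b(age)` and its SE are
  summarised (mean/SD/min/max) over 10,000 iterations, and the decline rate
  is reported as `mean(b) ± 1.96·mean(se)`.

A likelihood-ratio test compares each linear-age fit against the saturated
age-group-factor model to verify that the linear age coding is adequate, and
a combined report orders all endpoints by decline rate with pairwise
CI-separation flags. The published tables for all 15 endpoints are bundled as
CSV fixtures; arbitrary grouped tables in the same schema are accepted.

## Worked example

```bash
spinedecline fit-prevalence --endpoint "disk degeneration"
```

```json
{
  "endpoint": "disk degeneration",
  "n": 1603,
  "fit": {"model_kind": "logistic", "slope": 0.06463723795394774,
          "se_slope": 0.00570251492708566, "n": 1603, "...": "..."},
  "marginal_effect": {"estimate": 1.4290665399414202,
                      "se": 0.10591632099509363,
                      "ci_low": 1.2214705507910366,
                      "ci_high": 1.6366625290918038}
}
```

Reading: across the 1603 reconstructed subjects, the prevalence of disk
degeneration rises by ≈1.43 percentage points per year of age
(95% CI 1.22–1.64). The logit slope itself is 0.0646 log-odds/year.

```bash
spinedecline mc-continuous --endpoint "MF (C)" --seed 1 --iterations 10000
```

```json
{
  "endpoint": "MF (C)", "iterations": 10000, "n": 80,
  "b":  {"mean": 0.24151973038470487, "sd": 0.07094248302028255,
         "min": -0.006181119968601831, "max": 0.4934307912705166},
  "se": {"mean": 0.06761178468771069, "sd": 0.005953235690773264,
         "min": 0.04693027632991374, "max": 0.09221382713979047},
  "ci": {"point": 0.24151973038470487, "ci_low": 0.10900063239679192,
         "ci_high": 0.3740388283726178, "method": "normal"}
}
```

Reading: multifidus FI (four decade groups of 20 subjects each) increases by
≈0.24 %-points per year (95% CI 0.11–0.37) — an order of magnitude slower
than disk signal loss. The combined comparison across all 15 endpoints:

```bash
spinedecline report --seed 1 --format plot-data   # Fig-2-style whisker data
spinedecline recover --slope 0.2 --seed 7         # parameter-recovery check
```

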