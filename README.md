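# beetox

Acute contact toxicity analysis for bee pesticide risk assessment: from
per-cage mortality counts to species LD50s, a species sensitivity
distribution (SSD) with hazardous dose HD5, a surrogate-species
safety-factor check, and an allometric body-weight model that extrapolates
LD50s for species too small or too rare to test.

## The problem

Lower-tier pesticide risk assessment for bees rests on acute tests with a
single surrogate species, the honey bee *Apis mellifera*, with a safety
factor (EFSA recommends 10) meant to cover the sensitivity range of the
hundreds of wild bee species actually foraging on treated crops. Whether
that factor suffices can be checked by testing multiple species against a
reference compound (here the organophosphate dimethoate), building an SSD
from the resulting LD50s, and comparing its protective percentile with the
surrogate-based threshold. Because most wild bees are hard to collect in
numbers, a second question is whether body weight alone predicts
sensitivity well enough to extrapolate endpoints for untested species.

## Models

**Dose–response.** Deaths per cage are binomial with expected mortality
`p(d) = c + (1 − c)·F(s·(log₁₀ d − log₁₀ LD50))`, where `c` is background
control mortality (Abbott's correction folded into the likelihood) and `F`
a two-parameter sigmoid on log₁₀ dose — log-logistic, probit, or Weibull,
each parametrised by its median so the location parameter *is* the LD50.
Families are compared by AIC; LD50 confidence limits use the delta method
on log₁₀(LD50) via the inverse observed information. Species are compared
by the Bonferroni-adjusted confidence-interval-overlap rule, and replicate
runs are pooled by geometric mean.

**SSD / HD5.** Interspecific sensitivity is modelled as
log₁₀(LD50) ~ Normal(μ, σ) fitted by maximum likelihood. The 5% hazardous
dose is `HD5 = 10^(μ + σ·z₀.₀₅)`; its confidence limits come from a
parametric bootstrap (resample n log-endpoints, refit, recompute HD5;
default 5000 iterations, percentile limits). The **lower-limit HD5** is
compared with the surrogate LD50 divided by the safety factor.

**Allometry.** `log₁₀(LD50) = a·log₁₀(weight) + b` by OLS (equivalently
`LD50 = 10^b · weight^a`), fitted on fresh or dry weight with or without
literature endpoints, with a parametric bootstrap band over the
coefficient sampling distribution. Predictions outside the fitted weight
range are flagged as extrapolations.

A synthetic-data module generates assays, log-normal communities and
power-law allometric endpoints from exactly these models, so every
estimator has a seeded ground-truth recovery test.

## Worked example

```python
from beetox.datasets import tested_endpoints, honey_bee_endpoint
from beetox.ssd import fit_ssd, bootstrap_hd_ci, surrogate_comparison
from beetox.allometry import fit_weight_sensitivity, extrapolate_ld50

eps = tested_endpoints() + [honey_bee_endpoint()]   # printed study table
fit = fit_ssd(eps)
hd = bootstrap_hd_ci(fit, p=0.05, n_boot=5000, seed=1)
print(f"SSD: mu={fit.mu_log10:.4f}, sigma={fit.sigma_log10:.4f}, n={fit.n}")
print(f"HD5={hd.hd:.4f}, limits=({hd.lower_limit:.4f}, {hd.upper_limit:.4f})")
print(surrogate_comparison(hd, 0.18, 10).verdict)

model = fit_weight_sensitivity(tested_endpoints(), "dry", include_literature=False)
print(f"a={model.slope_a:.4f}, b={model.intercept_b:.4f}, R2={model.r_squared:.2f}")
for species, weight in [("Hylaeus gredleri (M)", 1.0), ("Nomioides minutissimus (F)", 0.8)]:
    x = extrapolate_ld50(model, weight, species=species)
    print(f"{species}: {x.predicted_ld50:.2f}")
```

prints

```
SSD: mu=0.0074, sigma=0.5376, n=7
HD5=0.1328, limits=(0.0402, 0.6006)
lower-limit HD5 (0.04) is above surrogate LD50/10 (0.02) at 2 decimals
a=1.0441, b=-1.2620, R2=0.70
Hylaeus gredleri (M): 0.05
Nomioides minutissimus (F): 0.04
```

Reading: across the seven endpoint values in the built-in table the SSD
puts the dose affecting 5% of bee species at 0.13 μg a.i./bee with a
bootstrap lower limit of 0.04 — above the honey-bee LD50/10 threshold of
0.018, i.e. the safety factor is protective for this endpoint set. (The
full nine-endpoint analysis of the original study, which adds two further
literature species, gives HD5 = 0.08 and lower limit 0.02.) Dry body
weight explains 70% of the log-LD50 variance; evaluating the power law at
1.0 and 0.8 mg predicts LD50s of 0.05 and 0.04 μg a.i./bee for two of the
smallest European species — both flagged as extrapolations far below the
lightest tested species (3.7 mg).

The same stages are scriptable: `beetox simulate | fit-dr | ssd |
allometry | run-all | report` (see `beetox --help`), each accepting
`--seed` and configuration files so a whole run is reproducible
byte-for-byte.

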