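# Methods

## Dose–response estimation

Cage counts are pooled within treatment and modelled as
`deaths ~ Binomial(n, p(d))` with

```
p(d) = c + (1 − c) · F(s · (log10 d − m))
```

where `c` is the pooled observed control mortality (held fixed, not
estimated), `s > 0` the slope per log₁₀ dose unit, and `m = log₁₀ LD50`.
Mixing `c` into the expected mortality is algebraically the same as
Abbott-correcting the observed proportions but keeps the binomial error
structure and can never produce corrected responses outside [0, 1].
Controls enter only through `c`; log dose is never taken at zero.

Three families `F` are offered, each centred so that `F(0) = 0.5` and the
location parameter is the median:

* log-logistic: `F(z) = 1 / (1 + e^−z)`
* probit (log-normal): `F(z) = Φ(z)`
* Weibull: `F(z) = 1 − exp(−ln 2 · e^z)`

The fit maximises the binomial log-likelihood over `(log s, m)` by
Nelder–Mead from three slope starts (0.5, 2, 5) with the location started
at the interpolated 50%-crossing of the corrected proportions; the
reported model is the AIC minimiser (k = 2 for every family, so this is
likelihood ranking). A family race is only informative when the design
covers both tails at a large number of bees per dose; on five-dose
assays the families are near-indistinguishable and the choice is
effectively cosmetic.

Confidence limits use the delta method: the SE of `m` is taken from the
inverse of a central-finite-difference observed-information matrix
(relative step 1e-4) and the interval is `10^(m ± z·SE)`. A singular
information matrix yields a CI-unavailable flag rather than an error.
Degenerate data raise typed errors: fewer than three distinct non-zero
doses, no control group, all-zero or all-complete mortality.

Replicate runs of the same species/sex are pooled by geometric mean of the
run LD50s; their CIs are pooled the same way (a pragmatic display rule —
the pooled interval has no exact coverage interpretation). Pairwise
species comparisons use the CI-overlap rule: with `m = C(k, 2)`
comparisons, each interval is recomputed at confidence `1 − α/m` (centre
and SE backed out of the stated interval assuming symmetry on the log
scale) and a pair differs when the adjusted intervals are disjoint.
Grouping letters are the connected components of the non-significance
graph, ordered by ascending LD50. Control mortality above a threshold
(default 10%) is flagged for scrutiny, not excluded, since the correction
already absorbs it.

## SSD and hazardous dose

The SSD is a normal ML fit to `log₁₀(LD50)` (mean; SD with divisor `n`,
the convention of distribution-fitting packages — divisor `n − 1` is
available via `sigma_ddof`). `HDp = 10^(μ + σ·z_p)` with p = 0.05 by
default. All logs in the package are base 10.

Bootstrap limits: each of `n_boot` iterations (default 5000) draws `n`
log-endpoints from the fitted normal, refits with the same estimator and
recomputes HDp; the default limits are the 2.5th/97.5th percentiles of the
bootstrap HDp distribution. This mirrors the standard parametric-bootstrap
procedure of the SSD literature, but percentile intervals for an extreme
quantile are anti-conservative at small n: with nine endpoints the
two-sided 95% interval covers the true HD5 in roughly five of six
simulated communities rather than 95% (the coverage simulation in the test
suite measures this directly). `method="basic"` (quantiles reflected
around the estimate on the log scale) together with `sigma_ddof=1`
restores near-nominal coverage and is the recommended variant when
frequentist coverage matters more than convention; the default stays with
the conventional percentile/ML pairing.

The surrogate check reports `surrogate_ld50 / safety_factor` (defaults
0.18 μg a.i./bee and 10), the bootstrap lower limit, their ratio, and a
verdict at a stated rounding precision (default 2 decimals, matching how
such endpoint tables are printed).

Empirical SSD points are plotted at Hazen positions `(i − 0.5)/n`.

## Allometric weight–sensitivity model

OLS of `log₁₀(LD50)` on `log₁₀(weight in mg)` via statsmodels, reported as
slope `a`, intercept `b`, their SEs and t-test p-values, and R². Four
variants are fitted in a pipeline run: fresh/dry weight × literature
included/excluded (literature endpoints are excluded from weight
statistics by default). Species mean weights are used as the predictor.
Extrapolated LD50s are `10^b · w^a`; predictions outside the fitted
log-weight range carry a `beyond_data` flag because the headline use case
evaluates the line far below the lightest fitted species (0.8 mg versus a
3.7 mg minimum). The confidence band resamples `(b, a)` from their
bivariate-normal sampling distribution (`method="residual"` resamples
residuals and refits); by the OLS leverage property the band is narrowest
at the mean log weight.

Refitting from the rounded printed endpoint table reproduces the published
dry-weight no-literature fit quality (R² rounding to 0.70, slope p 0.037)
but the coefficients only approximately (a = 1.0441 vs the published
1.0490): the original fit used unrounded LD50 estimates. Both routes round
to the same extrapolated LD50s (0.05 and 0.04 μg a.i./bee at 1.0 and
0.8 mg).

## Synthetic data

The generators draw from exactly the models above: binomial cage mortality
under the mixed log-logistic curve, log-normal communities, and power-law
allometric endpoints with log-scale Gaussian noise. Defaults follow the
acute contact assay design: five doses on a geometric series
(0.0896–3.5 μg a.i./bee), a water control, three cages per treatment, ten
bees per cage, slope 2 per log₁₀ unit, zero background mortality unless
configured. Each generator takes an explicit seed and creates one private
`numpy` Generator per call; no global random state.

What the generators do *not* emulate — and hence what passing recovery
tests cannot show about real assays: cage-level overdispersion (counts are
exactly binomial, no random cage effects), dose-measurement error,
time-to-death structure (only the 48 h snapshot), non-log-logistic true
curves, correlated endpoints across species within a community, and
laboratory-to-laboratory heterogeneity of the kind that degrades the fit
when literature endpoints are pooled. Parameter-recovery results here are
therefore best-case calibration checks, not field validation.

## Problem sizes and determinism

Simulation-based checks use: 500 assays of 3 cages × 10 bees for LD50
recovery and CI coverage; one 50-cage assay for point recovery; 10⁵
endpoints for SSD parameter recovery; 200 nine-species communities with
1000 bootstrap iterations each for interval coverage; 5000 (against a
50000-iteration reference) for bootstrap self-consistency — sizes chosen
so each study estimates its target rate to within a few percent. Every
stochastic stage is seeded; the pipeline report serialises with sorted
keys so identical config + seed gives byte-identical JSON, and the report
embeds the seed, a config hash and the package version.

## Known limitations

* The built-in endpoint table carries only the values printed in the
  study's summary (six tested entries plus the honey-bee literature mean
  0.18). The original nine-endpoint SSD included two further literature
  species whose LD50s are not reprinted here; the seven-value SSD
  accordingly sits above the published nine-endpoint HD5 (0.13 versus
  0.08 μg a.i./bee).
* Percentile bootstrap limits undercover at small n (see above).
* The CI-overlap comparison is conservative relative to a likelihood-ratio
  or Wald test on the fitted parameters, and the transitive-closure
  lettering merges groups connected through an intermediate species with a
  wide interval.
* Pooled-run CIs (geometric mean of limits) are descriptive only.
* The allometric model treats species as independent observations; no
  phylogenetic correlation structure is modelled.
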