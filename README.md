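# ecborrow

Bayesian external-control borrowing for two-arm clinical trial design with a
normal endpoint: meta-analytic-predictive (MAP) priors from historical
control summaries, robust mixture priors with dynamic borrowing, the
posterior-probability success rule, frequentist operating characteristics of
reduced-control-arm designs, and beta-binomial upper bounds for zero-event
rates.

## Who this is for

Trial statisticians designing studies in rare or slowly progressing diseases,
where randomizing a full concurrent control arm is ethically and practically
costly but completed trials provide relevant control-arm data. The running
case study is a hypothetical pivotal Phase III trial in Progressive
Supranuclear Palsy (PSP), endpoint mean change from baseline in the PSP
Rating Scale (PSPRS) at week 52, with three completed Phase II placebo arms
as the external source.

## The model

Historical control arms report summaries (n_j, y_j, s_j). The hierarchical
(random-effects meta-analysis) model is

    y_j | θ_j      ~ N(θ_j, s_j²)
    θ_j | μ, τ     ~ N(μ, τ²)
    μ              ~ N(0, 100²)
    τ              ~ HalfNormal(1.3)

and the MAP prior is the predictive distribution of a new study's control
mean, θ_new | data, where θ_new ~ N(μ, τ²). The default inference
marginalizes τ on a grid (the model is conjugate given τ), so the predictive
density is an exact normal mixture; an MCMC route (affine-invariant ensemble
sampler) is available for cross-checks. The MAP prior is moment-matched to a
single normal and *robustified* by mixing in a vague component,

    robust prior = (1 − w) · N(m_MAP, s_MAP²) + w · N(15, 10²),  w = 0.5.

The conjugate posterior of any normal mixture under a known-variance normal
likelihood stays a normal mixture, with component weights updated by marginal
likelihood — this is dynamic borrowing: prior–data conflict shifts weight to
the vague component and switches borrowing off.

The trial declares success when P(δ > 0 | data) > 0.975 for the treatment
effect δ, and the design's frequentist operating characteristics (type I
error at δ = 0, power at δ = 4, the clinically meaningful effect) are
computed by Gauss–Hermite quadrature over the sampling distribution of the
arm means, sweeping the true placebo mean.

## Worked example

```python
from ecborrow import fit_map, load_psp_historical, moment_match_normal, robustify
from ecborrow.psp import psp_operating_characteristics

fit = fit_map(load_psp_historical())     # three Phase II placebo arms
print(fit.summary())
map_prior = moment_match_normal(fit)
robust = robustify(map_prior, 0.5, 15.0, 10.0)
oc = psp_operating_characteristics(0.0)  # type I error sweep
print(100 * oc.max_success_prob())
```

prints a predictive mean of 10.91 PSPRS points with 95% interval
(8.48, 13.36) and moment-matched sd 1.19 — the historical placebo arms say a
new placebo arm should worsen by about 11 points, known to about ±1.2 points,
information worth roughly 45 placebo patients at σ = 8. The robust-MAP 2:1
design (85 treatment / 43 placebo) then has a maximum type I error of 6.65%
over true placebo means 5–17 (the peak sits at 14, where the historical
information conflicts with the truth), against 2.5% for a non-borrowing
z-test and against type I errors an order of magnitude larger if the
unrobustified MAP prior is used under the same conflict.

The `examples/` scripts walk one capability each (MAP derivation, dynamic
borrowing, operating characteristics, zero-event bounds) and print annotated
output; `ecborrow --help` exposes the same steps as a CLI
(`map-prior`, `robustify`, `oc`, `samplesize`, `zero-upper`, `simulate`).

## Layout

- `ecborrow.hierarchical_map` — hierarchical model, MAP predictive, moment
  matching, EM mixture approximation
- `ecborrow.mixtures` — exact normal-mixture algebra: robustification,
  conjugate updating, cdf/quantiles/moments, difference probabilities
- `ecborrow.design_oc` — two-arm design, success rule, decision boundary,
  operating characteristics, classical sample-size benchmarks
- `ecborrow.zero_numerator` — beta-binomial zero-event upper bounds
- `ecborrow.psp` — the PSP case-study configuration
- `ecborrow.io`, `ecborrow.synthetic`, `ecborrow.cli` — files, generators,
  command line

See `docs/methods.md` for modeling choices, calibration of the heterogeneity
prior, and known limitations.
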