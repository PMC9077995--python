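# Methods

## Hierarchical model and MAP prior

The package treats each historical control arm as a summary (n_j, y_j, s_j)
with y_j the observed mean endpoint change and s_j its standard error, and
fits the standard normal–normal random-effects model

    y_j | θ_j ~ N(θ_j, s_j²),   θ_j | μ, τ ~ N(μ, τ²),
    μ ~ N(0, 100²),             τ ~ HalfNormal(scale).

The MAP (meta-analytic-predictive) prior for a new study's control mean is
the posterior predictive of θ_new ~ N(μ, τ²). Exchangeability of the
historical and new control parameters is the load-bearing assumption: the
model cannot detect systematic differences between populations, only
between-trial spread.

**Inference.** Conditional on τ the model is conjugate, so the default
route marginalizes τ on an equally spaced grid from 0 to 8·scale (201
points): for each node the posterior of μ and the marginal likelihood are
closed-form, and the predictive density is the exact mixture
Σ_i w_i · N(E[μ|τ_i], Var[μ|τ_i] + τ_i²). All summaries (moments,
quantiles) come from this mixture, so they are deterministic; joint draws
of (μ, τ, θ_new) are additionally sampled for downstream use with the
configured seed. If more than 1e-3 of normalized posterior mass sits on the
last grid node the fit aborts with a diagnostic rather than silently
truncating the τ posterior. An MCMC route (emcee's affine-invariant
ensemble, 32 walkers, 1000-step burn-in, thinning 10) exists to cross-check
the grid; the two agree within Monte-Carlo error on the case-study data.

**Heterogeneity prior calibration.** With three historical trials the data
carry little information about τ and the half-normal scale matters. The
package's default, scale = 1.3 PSPRS points (≈ σ/6 for the case study's
σ = 8), was calibrated so that the predictive distribution for the PSP
historical set matches the case study's published summary (mean ≈ 10.8,
sd ≈ 1.19, 95% interval ≈ (8.4, 13.4)); the exact-grid predictive under
this default is mean 10.906, sd 1.190, interval (8.48, 13.36). This is a
calibration choice of this package, documented here precisely because a
"weakly informative" τ prior is not a uniquely defined object; the scale is
a `MapConfig` field and sensitivity to it should be part of any real design
exercise (σ/4 = 2, for comparison, widens the predictive sd to 1.49).

**Approximations.** `moment_match_normal` collapses the predictive to a
single normal with the predictive's exact first two moments — convenient
because the robust prior and all conjugate updates then stay in small
mixtures. `fit_mixture_em` offers a k-component maximum-likelihood
approximation (EM with 10 restarts, best likelihood kept) when the
predictive's shape, not just its moments, must be preserved; a component sd
collapsing below 1e-8 of the sample sd is reported as a degenerate fit
rather than returned.

## Mixture algebra

Normal mixtures are closed under the operations the workflow needs, so
everything is exact: conjugate updating with a known-variance normal
likelihood updates each component's mean and precision and reweights
components by the marginal likelihood of the observed arm mean (computed in
log space with log-sum-exp, so extreme prior–data conflict degrades
gracefully instead of underflowing); the difference of independent mixtures
is a mixture over component pairs, giving P(δ > 0 | data) in closed form;
quantiles come from bracketed Brent root-finding on the mixture cdf, with
the initial bracket mean ± 12·max(sd) expanded geometrically if needed.

## Design evaluation

A `TwoArmDesign` holds arm sizes, the known sampling SD σ, a prior per arm
and the success threshold. Success is declared when the posterior
probability that the control-slot mean exceeds the treatment-slot mean is
strictly above the threshold (0.975 in the case study). For operating
characteristics the success region is integrated exactly in two steps: the
decision boundary ȳ_t*(ȳ_c) — the treatment sample mean at which the
posterior probability hits the threshold — is found by root-finding
(monotonicity makes it unique), and the success probability at a true
(θ_c, θ_t) is the Gauss–Hermite integral (41 nodes in ȳ_c) of the normal
probability that ȳ_t falls below the boundary. A seeded simulation method
(default 10⁵ replicates per grid point) provides an independent check; the
two agree within binomial error everywhere on the case-study grid. With
vague priors on both arms the whole construction reduces analytically to
the one-sided z-test, which the tests exploit as an oracle.

**Effect-direction convention in the PSP case study.** The published PSP
analysis defines δ as the difference in mean change between the treatment
and placebo groups and declares success when P(δ > 0 | data) > 0.975, with
the power scenario placing the treatment mean 4 points above the placebo
mean; its operating characteristics inflate type I error when the true
placebo mean lies *above* the historical mean (the side guarded by the
vague Normal(15, 10) component) and peak at 6.3%. The generic design
machinery here orients success toward the control slot, so `ecborrow.psp`
evaluates the published rule by an exact reflection of the endpoint scale
(negating all location parameters and mapping the axis back) — a pure
relabeling with no numerical consequence. Note the tension a user should be
aware of: on a worsening scale (higher PSPRS change = worse) a "positive
treatment effect" would naturally mean the *placebo* arm's change exceeds
the treatment arm's; under that opposite orientation the same priors give a
maximum type I error of 9.4%, peaking *below* the historical mean, because
the vague component then guards the wrong side. The case-study module
reproduces the published computation; for a new design the orientation and
the vague component's location should be chosen together.

**Operating-characteristic grid.** True placebo means are swept from 5 to
17 in steps of 0.25 by default — generously covering the historical range
(8.4–13.4) and the conflict regions discussed above — and the maximum type
I error is reported over that grid (6.65% at θ = 14 for the case-study
configuration).

**Classical benchmarks.** `freq_sample_size` is the standard two-sample
normal-approximation formula with allocation ratio r (ceilings per arm);
for the case study it gives 85 per arm at 1:1 (α = 2.5% one-sided, 90%
power, δ = 4, σ = 8). `reduced_control_sizes` encodes the external-control
design's geometry — keep the treatment arm at the 1:1 benchmark and divide
the control arm by the randomization ratio (85/43 at 2:1) — which is *not*
a powered frequentist design: the borrowed prior supplies the missing
control information. `freq_power` gives the z-test power used as the
non-borrowing comparator (0.903 at 85/85; 0.762 at 85/43).

## Zero-event bounds

For x events in n patients with a Beta(a, b) prior, the event-rate
posterior is Beta(a+x, b+n−x) and the reported upper bound is its `level`
quantile (default 0.95). With x = 0 and the uniform prior this is
1 − (1−level)^{1/(n+1)}, which tracks the rule-of-three 3/n for n ≳ 100.
The default prior is uniform with Jeffreys available; no "expert-opinion"
informative prior is shipped because none is uniquely defined — the prior
is an argument everywhere.

## Synthetic data

`generate_historical` draws historical sets from exactly the hierarchical
generative model (θ_j ~ N(μ*, τ*²), ȳ_j ~ N(θ_j, σ²/n_j), reported
se_j = σ/√n_j), so recovery tests probe the fit under its own assumptions:
with 20 studies of sizes 40–120, σ = 8, μ* = 11, τ* = 1 (spread and scale
chosen to resemble the PSP setting), both parameters are recovered within 3
posterior SDs in ≥ 95% of 100 seeded replicates. What the generator does
not emulate — and passing tests therefore do not establish robustness to —
is non-exchangeability: systematically shifted historical populations,
misreported standard errors, or endpoint drift between trial eras.
`simulate_trial` draws one seeded trial replicate and applies the decision
rule, cross-checking the quadrature operating characteristics.

## Numerical choices and degenerate inputs

- Strict inequality at the success threshold, matching the published rule.
- Quantile and boundary root-finding use Brent's method with geometric
  bracket expansion; boundary bracketing failure after 60 doublings raises
  (a pathological prior, not a numerical mystery).
- Mixture weights must sum to 1 within 1e-12 at construction;
  `from_unnormalized` is the sanctioned way to renormalize.
- τ = 0 is on the grid, so the fixed-effect (complete-pooling) limit is
  reached continuously as the τ-prior scale shrinks.
- Problem sizes throughout (201-point τ grid, 41 quadrature nodes, 10⁵
  simulation replicates, 100 recovery replicates) were chosen so the exact
  and simulated routes agree comfortably within Monte-Carlo error while a
  full test run stays interactive.

## Known limitations

Normal endpoint with known σ only; no binary or survival endpoints, no
covariate adjustment, no interim analyses, no prior effective-sample-size
diagnostics, and no power/commensurate-prior alternatives to the robust
mixture. The MAP fit consumes published summaries, not patient-level data,
and inherits whatever reporting conventions those summaries embed.
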