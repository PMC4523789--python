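# Methods

`quicksdt` implements a family of Bayesian adaptive psychophysical methods
that estimate the *sensitivity threshold* — the signal contrast at which the
signal-detection sensitivity index d′ equals 1 — rather than an empirical
%Yes or %Correct threshold. Because the methods estimate decision criteria
jointly with sensitivity, the resulting thresholds are independent of the
observer's response bias and of the task's decision structure. Four task
variants are supported: simple Yes-No detection (qYN), cued Yes-No detection
with instructed lax/strict response states (qYNC), rated Yes-No detection
with a Not-Sure response (qYNR), and two-interval forced choice with an
estimated interval bias (qFC).

## The response model

Sensitivity follows a saturating gain-control transducer,

    d′(c) = β (c/τ)^γ / sqrt((β² − 1) + (c/τ)^{2γ}),

parameterised so that d′(τ) = 1 exactly. τ is the sensitivity threshold
(contrast, a dimensionless fraction in (0, 1)); γ > 0 is the log-contrast
steepness; β is the d′ asymptote, fixed at 5.0 (sensitivity above d′ ≈ 4 is
not reliably measurable, so β is excluded from inference). Numerically the
transducer is clamped one ulp below β so that d′ < β holds strictly at any
finite contrast.

Internal responses are standard normal. Decision criteria are placed in
z units on that axis:

* **Simple:** P(Yes | c) = 1 − Φ(λ − d′(c)); the false-alarm rate is
  1 − Φ(λ).
* **Cued:** the same expression with λ_lax = λ_strict − Δλ, Δλ ≥ 0; the
  method estimates (λ_strict, Δλ) to enforce the order constraint.
* **Rated:** Yes above λ_strict, No below λ_lax, Not Sure in between;
  the three psychometric functions partition unity, and Yes + Not-Sure
  reproduces the cued lax curve exactly.
* **Forced choice:** P(Interval 2) = 1 − Φ(λ_FC − [d′(c₂) − d′(c₁)]/√2).
  The √2 arises because both intervals contribute independent unit-variance
  noise to the difference variable; with a neutral criterion a signal at
  threshold is reported correctly ≈ 76% of the time. λ_FC = 0 means no
  interval bias; the sign convention puts P(Interval 2 | null) = 1 − Φ(λ_FC).

A stimulus-independent lapse mixes every response distribution with a
uniform one over the K response categories, ψ′ = ε/K + (1 − ε)ψ, with
ε = 2% by default; for binary tasks the empirical asymptote is then 99%.
The symmetric ε/K form (rather than an additive ε only on the lower
asymptote) is what makes the stated 99% asymptote come out exactly and
spreads lapses equally over response categories.

## Bayesian adaptive engine

The joint posterior over (τ, γ) plus the task's criterion parameter(s) is
maintained on a fixed grid: τ and γ log-spaced, criteria linearly spaced.
The default "simstudy" grid is τ ∈ [0.0025, 1.25] (59 samples),
γ ∈ [0.4, 10] (58), λ ∈ [−1, 3] (56), with a stimulus space of 120
log-spaced contrasts in [0.001, 0.99]. The criterion grids the original
design leaves open are set to Δλ ∈ [0, 2.5] (28 samples; covers every
strict/lax rate pair used in validation, max Δλ ≈ 1.71) and λ_FC ∈ [−2, 2]
(56 samples; covers the ±20% interval-bias states, |λ_FC| ≈ 0.52, with
margin). A "simstudy-coarse" preset halves every axis for Monte-Carlo work,
and a "demo" preset covers 0.1–99% contrast at 0.25 dB steps.

Priors are normalised products of one-dimensional hyperbolic-secant
marginals, sech(confidence · u), with u = log10(x/mode) for τ and γ and
u = x − mode for criteria; confidence is the reciprocal width in those
units and confidence → 0 gives a flat marginal. This scale convention is an
assumption (the quantitative meaning of "confidence" is not defined in the
source description); it makes the reference weak/strict confidences
(1.6 / 11.5 for τ, 6.1 for γ, 2.1 for criteria) directly usable.

Each trial the engine computes predictive response probabilities
p(r|s) = Σ_θ ψ′(r|s, θ) p(θ) for every candidate condition, scores each
candidate by the expected Shannon entropy of the one-trial-ahead posterior,
and presents the argmin (one-step-ahead minimum-expected-entropy search;
ties broken uniformly from a dedicated seeded stream). The identity

    E[H(s)] = Σ_r [ p(r|s) log p(r|s) − Σ_θ L log L · p(θ) ] − Σ_θ p log p

(the last term independent of s) reduces the sweep to two matrix products
against precomputed L and L·log L tables, which is what makes batched
replication cheap. Entropies are in nats with 0·log 0 = 0 and a 1e-300
floor under the log. After the response, the posterior is updated by Bayes
rule and normalised (unit sum within 1e-10 is asserted in tests). Stimulus
conditions are plain contrasts for qYN/qYNR, (contrast, cue state) pairs for
qYNC — the search chooses the cue as well — and signed contrasts for qFC,
which chooses both level and interval, optionally including the both-blank
condition (included by default, mirroring the constant-stimuli design).

Point estimates report τ and γ as 10^E[log10 ·] (geometric posterior means)
and criteria as arithmetic means; credible intervals are marginal quantiles
(68.2% by default — a ±1 SD-like band; the level shown in the source demo is
unspecified). Sessions stop after a fixed trial count or when the τ interval
width falls below a decimal-log criterion.

## Simulated observers and the validation harness

Observers are matched-model: they respond from the same lapse-adjusted SDT
model the engine assumes (a config switch allows lapse-free observers).
The reference conditions use τ = 10% contrast, γ = 2, ε = 2%, with criteria
specified *operationally* by null-stimulus response rates and converted
through Φ⁻¹:

* qYN: false-alarm rates 2.5, 10, 40% (λ = 1.960, 1.282, 0.253),
* qYNC: (strict, lax) FA pairs (2.5, 10), (2.5, 40), (10, 40)%,
* qYNR: null (Yes, No) rates (2.5, 90), (2.5, 60), (10, 60)%,
* qFC: null Interval-2 rates 30, 50, 70% (interval bias ∓20%).

Rate-based specification resolves the internal inconsistency between a
printed nominal criterion (λ = 1) and the printed per-state false-alarm
rates in the source description of these conditions; the rates are what the
validation figures use. For the rated task the (10, 60)% third state follows
the methods text over a conflicting figure caption.

The study prior is weak and centered on the simulated observer's nominal
parameters — the "weak matched" baseline of the prior-sensitivity study
(confidences 1.6 / 6.1 / 2.1). The source description says only that priors
were "centered on initial guess"; centering on the design's nominal state is
the reading under which the published accuracy outcome (bias below 0.5 dB by
trial 25 in every response state) is reproduced, whereas a fixed criterion
prior mode of 1 leaves a ±1 dB criterion-prior pull at trial 25 for the
extreme states. Interactive use, where the truth is unknown, gets a neutral
`default_prior` (τ mode at the grid's geometric centre, λ mode 1) instead.

`run_study` replicates seeded 25–100-trial sessions (300 replications by
default; 1000 reproduces the original scale) and reports per state and
checkpoint the mean threshold bias 10·log10(τ̂/τ) in dB (1 dB = 0.1 decimal
log units; the mean, not the median, is reported) and the SD of log10 τ̂.
Replications run as one vectorised batch whose per-replicate RNG streams are
spawned exactly as the sequential runner spawns them; a test pins the batch
path to the sequential path trial by trial. Batch tensors default to float32
(the entropy-score contrasts are ~10³ × larger than float32 rounding at
these grid sizes); the sequential engine defaults to float64.

The harness also produces ordinary and cumulative presented-stimulus
histograms, posterior-mean null-response-rate recovery (decision-criterion
recovery at d′ = 0), and the four-variant threshold-prior study
(weak/strict × matched/mismatched, modes 10%/0.9%, confidences 1.6/11.5,
with γ ~ (2.0, 6.1) and λ ~ (1, 2.1) held fixed).

## Constant-stimuli joint fit

`mcs.fit` maximises the likelihood of a unified SDT model over
multi-task count tables: shared (τ, γ), fixed β = 5 and ε = 2%, and up to
six task-specific criteria (one each for simple and FC, a (λ_strict, Δ)
pair each for cued and rated). The default design mirrors the validation
study: 50 trials per condition; null + seven log-linear contrasts 8–60% for
the Yes-No tasks (doubled over cue states), five levels per interval plus
the both-blank condition for FC (~2150 trials). Optimisation uses L-BFGS-B
in transformed coordinates (log10 τ, log10 γ, raw criteria, box-constrained
Δ ≥ 0) with a data-driven first start (criteria from observed null rates via
Φ⁻¹) and seeded jittered restarts. Rated cells use the full trinomial
likelihood.

Goodness of fit is a parametric-bootstrap deviance test against the
saturated multinomial model: simulate tables at the fit, refit, and rank the
observed deviance among replicates (the exact construction of the source's
"bootstrap χ²" is not available; the deviance form is the standard choice).
Bootstrap SEs are SDs of replicate estimates, reported on the log10 scale
for τ and γ; an all-zero-variance replicate set raises instead of returning
0. Requests below 50 bootstrap replicates emit a warning.

## Problem sizes and numerical choices

Monte-Carlo validation (tests and `scripts/acceptance.py`) runs 300
replications per cell on the 2×-coarsened grid — the package's desk-scale
defaults; the full-resolution grid and 1000 replications reproduce the
original scale and were cross-checked for the qYN task (same bias/SD pattern
at trial 25). The long-run consistency check uses the full 59-sample τ axis
with coarsened nuisance axes, since τ-grid resolution is what limits
accuracy at 500 trials. Likelihood tables are cached per (task, grid);
caching is contract-tested not to change results. Degenerate updates (zero
predictive probability) raise rather than renormalise silently.

## What the simulations do and do not show

The simulated observers are stationary, matched-model and lapse-symmetric:
passing validation shows the estimation machinery is consistent and
efficient under the model's own assumptions, plus mild prior mismatch. It
does not demonstrate robustness to criterion drift within a session,
asymmetric or intensity-dependent lapsing, transducer misspecification, or
inter-trial dependencies — all known limitations of real observers that the
source validated separately with human data (not redistributable, hence not
part of this package's validation). The qFC sampling asymmetry is asserted
in the mechanism-consistent direction (sampling concentrates in the interval
carrying the psychometric function's dynamic region, i.e. opposite the
response bias); see the engine's entropy criterion for why responses in the
anti-biased interval are more informative.
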