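# Methods

## Task model

Each trial presents a stimulus whose true proportion is drawn uniformly
on [40, 60] percent. Responses live on a bounded slider spanning
[35, 65], slightly wider than the stimulus range so that advice can fall
symmetrically around any truth. The machine recommendation is drawn
uniformly on truth ± h, with h = 1.5 percent points in the accurate
(*pre* and *post*) phases and h = 10 in the *adjusted* phase. A session
is 110 trials: 5 practice trials (first response only), then 105 trials
soliciting a second response, of which round(0.2 × 105) = 21, placed
uniformly at random, carry no recommendation. Phases are defined by the
adjustment window, one of trials 21–40, 41–60 (default) or 61–80.

Recommendations are **not clipped** to the slider by default (a
`clip_recommendations` flag exists). Unclipped draws keep the mean
absolute recommendation deviance at exactly h/2 — 0.75 and 5.00 for the
two half-widths — which is what the accurate/degraded design targets;
clipping would bias the degraded-phase deviance downward. Responses, by
contrast, are always clipped: the slider is physically bounded. One
consequence worth knowing: when degraded advice falls outside the
slider, even a pure adopter can only respond at the scale edge, so a
small fraction (~2%) of adjusted-phase trials show WOA < 1 for an
adopter. That is a property of the task, not an artefact.

## Synthetic participants

A `StrategyProfile` has a strategy kind, a trust weight, and two noise
parameters:

* **Perceptual noise** — the first response is truth + N(0, σ_p),
  clipped to the slider; default σ_p = 3.0 percent points, which puts
  the mean first-response deviance near 3, a typical human level for
  this kind of proportion judgement. The generator does not model
  learning or lapses.
* **Motor noise** — the second response receives additive N(0, σ_m)
  placement error, default σ_m = 0.5 points. This is the mechanism that
  produces raw weights of advice outside [0, 1]: a participant aiming
  exactly at A or R lands a fraction of a point off, and dividing that
  error by a small advice distance yields WOA far outside the unit
  interval. The rate of outside-unit weights therefore *falls* as
  advice distance grows — visible in the adjusted phase.

Noiseless second-response targets, with D = R − A and weight w:

| kind          | target            |
|---------------|-------------------|
| `stay`        | A                 |
| `adopt`       | R                 |
| `compromise`  | A + w·D           |
| `self_doubt`  | A + w·sign(D)·D²  |
| `agent_doubt` | A + w·sign(D)·√|D| |
| `mixture`     | stay/adopt/compromise drawn per trial from (p₀, p₁, p₂) |

The trust weight may be a single number or a per-phase mapping, so a
profile can emulate the canonical pattern of reduced weight during
degraded advice. On no-advice trials the synthetic participant re-places
their first response (stay target) subject to motor noise.

What passing tests on these synthetic participants show — and don't:
they validate the *measurement and inference machinery* (the WOA
algebra, the filters, the marginal likelihoods, the recovery of known
generating strategies). They do not show that human advice taking is
generated by any of these rules; the generator has no sequential trust
dynamics, no feedback learning, and stationary noise within a phase.

## Metrics

WOA = (B − A)/(R − A) is undefined on no-advice trials and when R = A
exactly (division by zero); undefined values are carried as NaN and
excluded from every mean — clamping them instead would fabricate
boundary mass. Winsorizing maps defined weights onto [0, 1]; winsorized
weights feed all mean-WOA summaries, while raw weights are kept for the
outside-unit analysis and all model fitting. Phase summaries default to
two-stage aggregation (each participant's mean, then the mean of those
means); pooled aggregation is a flag. Histogram bin width defaults to
0.05.

Before model fitting, each participant's table drops the first 10
post-practice observations of the session and the first 5 observations
of the adjusted and post phases — settling-in periods after each change
in advice accuracy — then no-advice and zero-distance trials. The drop
rules are trial-index predicates anchored at phase boundaries inferred
from the retained leading rows of each phase, which makes the filter
idempotent. Participant × phase cells with fewer than 8 remaining
trials are marked unidentifiable and excluded from count tables.

## Model comparison

For each participant × phase, shift y is regressed on a transformed
advice distance x (identity, signed square, or signed square root) with
no intercept — a shift at D = 0 would be meaningless — under the JZS
set-up:

    p(σ²) ∝ 1/σ²,   β | σ², g ~ N(0, g σ² n / (xᵀx)),
    g ~ Inverse-Gamma(1/2, r²/2),   r = √2/4 (exposed as a knob).

The g-prior variance n/(xᵀx) makes the log marginal invariant to
rescaling x, so the three transforms compete on shape, not scale, and
fits are insensitive to the units of advice distance. Rescaling y
shifts all models' log marginals equally (−n log c), leaving Bayes
factors unchanged; data are therefore fitted on the raw percent scale.
The improper σ² prior contributes the same constant to every model, so
equal-prior posterior model probabilities — a stabilised softmax of the
log marginals — are well defined.

**Quadrature (default).** Conditional on g, β and σ² integrate out in
closed form, leaving a 1-D integral over g evaluated by adaptive
quadrature on the log-g axis: the integrand's mode is located
numerically, the integral split there, and exponentials max-shifted
(relative tolerance 1e-10). Posterior moments of β and σ² come from the
same g-mixture. Deterministic and ~milliseconds per fit.

**Bridge sampling.** The posterior is also sampled by a blocked Gibbs
sampler (all three full conditionals are conjugate), 4 chains × 10,000
iterations with 1,000 burn-in. Chains start overdispersed;
convergence is summarised by the maximum rank-normalised split-R̂ over
(β, σ², g), warned about at ≥ 1.01. Draws are mapped to
(β, log σ², log g); the first half of each chain fits a moment-matched
warp (mean and covariance Cholesky factor), the second half is warped,
symmetrised against its reflection through the mean, and bridged
against a standard-normal proposal with the iterative optimal-bridge
estimator (log-space, relative tolerance 1e-10, max 1,000 iterations).
This path exists as a cross-check and for fidelity to samplers used in
this literature; quadrature and bridge agree to well under 0.1 nats on
a 60-trial participant (observed ~0.002).

Ties in posterior model probability (measure-zero) break in the fixed
order linear > self_doubt > agent_doubt, i.e. toward the simplest
account.

## Recovery studies

Model recovery simulates 50 replicates per strategy of 60 advice trials
(a typical filtered phase length), fits all three models, and tabulates
the preferred model against the generating strategy. Calibrated
generator slopes — compromise w = 0.5, self_doubt β = 0.1, agent_doubt
β = 1.0, motor SD 0.5 — were fixed once from a signal-to-noise
calculation: with advice distances of SD ≈ 3.1 points, the residual
variance of the best linear approximation to each curved rule is ≈ 0.41
(self-doubt) and ≈ 0.18 (agent-doubt) against motor-noise variance
0.25, giving roughly 10–30 nats of expected evidence over 60 trials.
At these values every strategy's generating model is recovered in
≥ 90% of replicates (observed 50/50 for all four).

The `stay` strategy is deliberately *not* part of the calibrated
recovery set: with a zero slope all three models predict shift = 0
identically, the three marginal likelihoods differ only through noise,
and "recovery" is undefined. It remains supported and its posterior
slope recovers ≈ 0.

Parameter recovery fits the linear model to compromise generators with
w ∈ {0.2, 0.5, 0.8} (50 replicates × 60 trials); posterior slope means
show |bias| < 0.01 and RMSE ≈ 0.02 — slight shrinkage toward zero from
the g-prior, negligible at this signal strength.

Problem sizes throughout (60-trial recovery phases, 50 replicates,
10⁵-draw generator checks) were chosen as the smallest at which the
Monte-Carlo error is comfortably below the effects being checked,
keeping full runs at minutes on one core.

## Known limitations

* The generator's strategies are stationary within a phase; humans
  plausibly drift, especially just after advice accuracy changes (the
  settling-in filter exists for exactly this reason).
* No-advice second responses are modelled as re-placed first responses;
  other plausible behaviours (genuine re-judgement of the stimulus) are
  not emulated.
* The leap-of-faith contrast compares single trials per participant and
  is correspondingly noisy; the package reports the pairs and cohort
  means, leaving inference to the user.
* Only the three advice-distance model forms are implemented; no
  hierarchical pooling across participants, and no intercept variants.
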