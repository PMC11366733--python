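# advisor-trust

Simulation and Bayesian analysis of **advice taking in a judge–advisor
task**: how much do people trust a machine advisor, and how does that
trust depend on how far the advice lands from their own judgement?

In the task, a participant (the *judge*) estimates a perceptual quantity
— the proportion of blue vs orange pixels, between 40% and 60% — on a
slider spanning 35–65%. They give a first response *A*, see a machine
recommendation *R* drawn uniformly around the truth, then give a second
response *B*. Sessions have 110 trials (5 practice); during an
*adjusted* phase the advice accuracy is degraded (half-width 10 instead
of 1.5 percent points), and 20% of trials carry no advice.

The behavioural trust measure is the **weight of advice**

```
WOA = (B − A) / (R − A)
```

(0 = advice ignored, 1 = fully adopted, conventionally winsorized to
[0, 1]). Writing the *shift* B − A against the *advice distance*
D = R − A, three accounts of advice taking are compared per participant
and phase:

| model         | shift =              | interpretation                          |
|---------------|----------------------|-----------------------------------------|
| `linear`      | β·D                  | constant averaging (stay/adopt/compromise) |
| `self_doubt`  | β·sign(D)·D²         | distant advice weighted *more*          |
| `agent_doubt` | β·sign(D)·√\|D\|     | distant advice weighted *less*          |

Each model is a no-intercept regression under the
Jeffreys–Zellner–Siow prior: p(σ²) ∝ 1/σ², β | σ², g ~ N(0, g σ² n/(xᵀx)),
g ~ Inverse-Gamma(1/2, r²/2) with r = √2/4. Marginal likelihoods are
computed two ways — deterministic adaptive quadrature over g (the
default; β and σ² integrate out analytically) and MCMC with Warp-III
bridge sampling (4 chains × 10,000 iterations, 1,000 burn-in; 36,000
retained draws; split-R̂ convergence check) — and converted to
equal-prior posterior model probabilities.

No human data are required: the `simulator` module generates synthetic
participants following stay / adopt / compromise / self-doubt /
agent-doubt / mixture strategies with perceptual and motor noise, and
the `recovery` module verifies that the fitting machinery identifies
the generating strategy and recovers its weight.

## Worked example

```python
import advisor_trust as at

design = at.SessionDesign()   # 110 trials, adjustment window 41–60
profile = at.StrategyProfile(
    kind="compromise",
    trust_weight={"pre": 0.7, "adjusted": 0.3, "post": 0.5},
)
trials = at.generate_cohort(20, profile, design, seed=42)
print(at.phase_summary(trials).round(3).to_string(index=False))

filtered = at.model_fit_filter(trials)
result, fits = at.fit_participant_phase(filtered, "p001", "post")
for f in fits:
    print(f"{f.model:<12} log ml = {f.log_marginal:8.2f}   "
          f"slope = {f.slope_mean:.3f} +/- {f.slope_sd:.3f}")
print("preferred:", result.preferred)
```

prints

```
   phase  mean_deviance_first  mean_deviance_rec  mean_deviance_second  mean_woa_winsorized  n_trials  fraction_outside_unit
     pre                2.427              0.758                 1.288                0.664       700                  0.213
adjusted                2.262              4.925                 2.244                0.318       400                  0.110
    post                2.384              0.754                 1.511                0.501      1000                  0.197
linear       log ml =   -32.48   slope = 0.482 +/- 0.030
self_doubt   log ml =   -39.41   slope = 0.095 +/- 0.007
agent_doubt  log ml =   -41.74   slope = 0.901 +/- 0.078
preferred: linear
```

Read the summary row-wise: recommendations average 0.75 points from the
truth in the accurate phases and ~5 points in the adjusted phase; the
cohort's mean winsorized WOA drops from 0.66 to 0.32 when advice
degrades and recovers only partly (0.50) afterwards; about a fifth of
raw weights fall outside [0, 1] — motor noise on the slider, not
deliberate over/under-shooting. The fit identifies the post-phase
strategy as linear averaging with slope ≈ 0.5, matching the generating
weight.

The same pipeline is available from a shell:

```sh
advisor-trust simulate --n 20 --seed 42 --out trials.csv
advisor-trust metrics  --in trials.csv --out-dir results/
advisor-trust fit      --in trials.csv --out-dir results/
advisor-trust recover  --mode model --out-dir results/
advisor-trust report   --n 20 --seed 42 --out-dir results/
```

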