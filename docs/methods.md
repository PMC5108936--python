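# Methods

## Model

An agent's emotional state is core affect: valence `v` (pleasure–displeasure)
and arousal `a` (activation–deactivation), both dimensionless on [−1, 1].
While reading an online discussion with emotional charge `h ∈ [−1, 1]`
(−1 negative, 0 neutral, +1 positive in the experimental designs emulated
here), the state follows a Brownian-agent dynamics with three forces:

```
dv/dt = −γ_v (v − b) + h  · (b0 + b1 v + b2 v² + b3 v³) + A_v ξ(t)
da/dt = −γ_a (a − d) + |h| · (d0 + d1 a + d2 a² + d3 a³) + A_a ξ(t)
```

* **Eigendynamics** — exponential relaxation toward the baselines `(b, d)`
  at rates `γ_v`, `γ_a` (per minute).  The fitted arousal baseline is
  negative: at rest, people deactivate.
* **Perception dynamics** — a polynomial field coupling.  Valence responds
  to the *sign* of the field, arousal to its *absolute value*: charged
  content of either polarity is activating.
* **Noise** — additive white noise with amplitudes `A_v`, `A_a`,
  taken Gaussian (the residual checks of the fits support approximate
  normality; the original analysis left the distribution open).

Expression of a post is gated by an arousal threshold,
`s = f_s(v) · Θ[a − τ_expr]`, with the boundary convention `Θ[0] = 1` (the
rule fires exactly at threshold).  The encoding `f_s` of valence into text
polarity is an open modelling question; it is pluggable (`identity` default,
`sign` variant).  After writing, arousal shrinks proportionally,
`a ← λ_a·a` (an empirical revision of the older hard reset `a ← 0`, which is
the `λ_a = 0` limit), and replying in a negative mood partially repairs
valence, `v ← λ_v·v` for `v < 0`.  The intention to participate follows a
threshold-linear (hinge) rule `p(a) = clip(p0 + α·a·Θ[a − τ_p], 0, 1)`.
The two thresholds `τ_expr` and `τ_p` are distinct parameters even though
both act as activation knots.

Individual differences are out of scope: all participants share one
parameter set, mirroring the pooled estimation the reference tables report.

## Reference parameter set

`emodyn/data/params_paper.json` carries the published point estimates:
γ_v=0.367, b=0.056, b0=0.14, b2=0.057, b3=−0.047 (b1=0, dropped by term
selection); γ_a=0.414, d=−0.442, d0=0.178, d1=0.14469 (d2=d3=0); p0=0.199,
α=0.438, τ_p=0.  Rates are per minute.  The noise amplitudes were never
published; A_v=0.35 and A_a=0.32 are this package's calibration (below).
λ_a=λ_v=0.5 are round defaults consistent with the reported proportional
(not full) post-writing arousal decrease; the feedback regressions identify
λ−1 as their slope, so any other choice is recoverable the same way.
τ_expr=0 matches the fitted participation knot.

## Synthetic-study generators

No raw data are deposited, so estimation is validated on synthetic studies.

**Reading studies.**  Per participant: a randomized thread order with fixed
polarity counts (default 9 negative / 9 positive / 2 neutral, 65
participants ⇒ 1300 events; a 3/3/1 × 53 lab-style design is used in the
analysis scripts).  Reading durations are lognormal (median 2 min,
σ=0.4) truncated to [0.5, 3] min: durations are unpublished, and 3 min is
the largest step for which the discrete event map keeps every state inside
[−1, 1] for the reference parameters (longer steps overshoot the box and
clipping would distort the very rates being fitted).  The latent state is
advanced by **one Euler–Maruyama step per thread, with the drift evaluated
at the pre-thread state**.  This convention makes the generator and the
event-timescale regression (below) agree exactly: with all noise off, the
observed rate (post−pre)/Δt *is* the drift at the pre-state, and the fits
recover the generating parameters to machine precision.  Each boundary
state is reported once — with additive Gaussian report noise (sd 0.1,
clipped) and optional 7-point Likert quantization — and serves as the post
report of one event and the pre report of the next, as in the real
between-thread questionnaires.  Initial states scatter around the baselines
(sd 0.25, draws truncated at ±2 sd).  The participation intention is the
hinge rule evaluated at the *reported* post-thread arousal plus truncated
Gaussian noise (sd 0.15).  Behavioural rules are evaluated at reported
rather than latent states deliberately: the report is the participant's own
reading of the experienced state and is the observable the refits use;
evaluating at the latent state would impose an errors-in-variables
attenuation of ~10–15% on the recovered slopes.

**Writing studies.**  Four posts per participant (positive/negative reply,
positive/negative initiation).  Pre-writing states are uniform on
[−0.6, 0.6] with valence shifted ±0.15 toward the task polarity (the topic
nudges mood); the pre-state distribution is unpublished, so this prior is a
design choice.  Post-writing states apply the feedback of expression, then
report noise.  Content flags are Bernoulli draws from the logistic models
(reference coefficients: positive −0.4203 + 0.9462·v; negative
0.2194 − 0.9777·v) at the reported pre-writing valence, and the per-post
sentiment scores are generated to be *exactly* consistent with those flags
under both classification rules (integer strengths ≥3 / ≤−3; per-sentence
polarities beyond ±0.25), so classification recovers the flags without
error.

**Noise calibration.**  A_v=0.35, A_a=0.32 were calibrated once so the
event-level regressions attain the published explained-variance regimes.
Attained: R² ≈ 0.52 for valence (target ≈0.5) and ≈ 0.32 for arousal
(target ≈0.28).  The arousal R² cannot be pushed lower by raising A_a:
extra process noise also disperses the states, which adds genuine
relaxation signal, and R² saturates near 0.31.  The attained participation
R² (≈0.38 at intention-noise sd 0.15) likewise exceeds the published 0.14;
matching it would require intention noise so large that the clip to [0, 1]
distorts the recovered intercept.  These are acknowledged mismatches
between generator and data, not tuning targets.

**What passing recovery does and does not show.**  The generator contains
exactly the model's mechanisms plus simple measurement error.  Recovery
therefore validates the estimation chain (identifiability, absence of
implementation bias at study scale), not the model's adequacy for real
forum data — real reports have individual differences, serial dependence
beyond the model, and non-Gaussian measurement error, none of which are
emulated.

## Estimation chain

* **Event deltas** — one record per reading event:
  `dv_rate = (v_post − v_pre)/Δt`, likewise arousal; non-positive durations
  are dropped with a warning.
* **Term selection** — exhaustive search over the 16 subsets of
  field-coupling orders {0,1,2,3} (rate and baseline always free), Gaussian
  likelihood, minimal AIC with `AIC = 2k − 2ℓ`; `k` counts the drift
  parameters and excludes the error variance (constant across candidates,
  so the ranking is unaffected).  Ties resolve toward fewer parameters,
  then lower maximal order.  Note the intrinsic limit: a true-zero
  coefficient is still admitted with probability P(χ²₁>2) ≈ 16%, so with
  two absent arousal terms the joint exclusion rate is bounded near 0.71
  even for a perfectly specified generator; observed rates (≈0.5–0.65) are
  further depressed because the weak true b2/b3 terms partially project
  onto the order-1 regressor over the narrow state range, and because state
  clipping at ±1 induces curvature the spare terms absorb.
* **Least squares** — the drift is linear in its parameters at fixed `h`,
  but the fit goes through a general nonlinear least-squares interface
  (Levenberg–Marquardt, warm-started from the linearized OLS solution) so
  nonlinear `f_s` extensions keep the same entry point.  Reported:
  estimates, standard errors from the Jacobian, R², residuals, Gaussian
  log-likelihood at the MLE variance, AIC.
* **Posterior** — random-walk Metropolis over the selected parameters:
  Gaussian likelihood with the error scale profiled at its least-squares
  value, independent normal(0, 10) priors, proposal scales initialized at
  2.4/√k times the NLS standard errors and adapted during a 2000-draw
  burn-in toward 20–40% acceptance, then exactly 10 000 recorded draws
  (thinning 1).  Histograms use Sturges' rule ⌈1 + log₂ n⌉ (15 bins at
  10 000 draws).  Degenerate inputs (constant rates, rank-deficient
  designs) raise before sampling.
* **Residual diagnostics** — R² of a moment-matched normal density against
  the Sturges-binned residual histogram, plus the Shapiro–Wilk W statistic.
* **Participation** — the knot is located by exhaustive search over the
  unique observed arousal values with OLS of intention on
  `[1, a·Θ(a−τ)]` at each candidate; minimum SSE wins, ties toward the knot
  nearest 0.  This is the single-knot special case of an adaptive
  regression-spline fit.  The regressor is the *literal* `a·Θ[a−τ]` (not
  the centred hinge), which is discontinuous for τ≠0; at the fitted τ=0 the
  two forms coincide.  Intention is treated as a continuous [0, 1] response
  fitted by least squares (the published fit reports R², not a likelihood).
  A flat response leaves the knot undetermined; it is then reported as 0 by
  the tie-break and flagged non-identifiable.  An optional second knot
  (greedy forward step) covers exploratory two-break fits.
* **Content classification** — dual-strength rule: positive iff positive
  strength ≥ 3, negative iff negative strength ≤ −3; per-sentence rule:
  positive iff max sentence polarity > 0.25, negative iff min < −0.25
  (strict inequalities).  Both allow simultaneous positive and negative
  content.  The sentiment lexicons themselves are out of scope — scores
  arrive as data.
* **Expression content** — maximum-likelihood logistic regression of each
  flag on one predictor; deviance ≡ −2·log-likelihood by construction;
  complete separation raises.
* **Feedback** — per-kind OLS of `(a_post − a_pre)` on `a_pre`; under the
  shrink model the slope identifies `λ_a − 1` (−1 = full reset, 0 = none).

## Pipeline and reproducibility

One master seed deterministically spawns a 31-bit seed per stage
(`numpy` generator on the master seed), so every stage can be re-run
standalone on its CSV interfaces.  Datasets carry sidecar manifests (seed,
config hash, file hash); a run manifest hashes every artifact.  Identical
config + seed gives byte-identical tables.

Problem sizes used throughout (tests, recovery experiments, acceptance):
20 seeds per recovery protocol, ~1300 reading events or 5000 posts per
dataset, 10 000 posterior draws — the scale of the original studies'
pooled event count.

## Known limitations

* The community simulation's field update
  (`h ← decay·h + gain·mean(expressed)`) is illustrative plumbing for the
  closed loop, not a calibrated model of any real forum or chat corpus.
* AIC subset selection at study scale keeps spurious terms in a
  substantial minority of runs (see above); the selected *orders* should
  be read as a typical-case summary, while the coefficient recovery is the
  reliable statement.
* Arousal R² and participation R² of the generator exceed the published
  values (0.32 vs 0.28; 0.38 vs 0.14) for the structural reasons given.
* Data-driven session comparisons are qualitative only: the real thread
  sequences and reading times of individual participants are unpublished.
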