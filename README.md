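# emodyn

Agent-based modelling and estimation of emotion dynamics under online
interaction.

Reading and writing in online discussions changes how people feel, and
coupled individual changes are what turn a heated thread into a collective
emotional episode.  `emodyn` implements a Brownian-agent model of that
microdynamics — core affect (valence `v`, arousal `a`) on [−1, 1]² relaxing
toward baselines while driven by the emotional charge `h` of the discussion
being read —

```
dv/dt = −γ_v (v − b) + h  · (b0 + b1 v + b2 v² + b3 v³) + A_v ξ(t)
da/dt = −γ_a (a − d) + |h| · (d0 + d1 a + d2 a² + d3 a³) + A_a ξ(t)
```

together with the behavioural rules around it (threshold-gated expression
`s = f_s(v)·Θ[a − τ]`, hinge participation `p = p0 + α·a·Θ[a − τ_p]`,
proportional post-writing arousal decrease) and the **full estimation
pipeline** used to fit such a model to reading/writing experiments:
event-timescale rate regression with exhaustive AIC term selection,
nonlinear least squares, random-walk Metropolis posteriors, threshold
(hinge) regression of participation, sentiment-threshold classification and
logistic models of expressed content.  Because the underlying human-subject
data are not deposited, the package ships synthetic-study generators with
the same statistical structure, and validates the whole chain by parameter
recovery: data generated with the published point estimates as ground truth
must be re-estimated near those values.

Intended users: computational social scientists and affective-computing
researchers who want a tested, reproducible implementation of this model
family to simulate, extend, or re-estimate on their own experiments.

## Worked example

```python
import numpy as np
from emodyn import (
    reference_params, ReadingStudyDesign, generate_reading_study,
    event_deltas, select_subset, fit_nls, fixed_point,
)

params = reference_params()          # published point estimates + calibrated noise
print(fixed_point(params.valence, h=0.0), fixed_point(params.arousal, h=0.0))
# 0.056 -0.442     <- resting states: slightly pleasant, clearly deactivated

design = ReadingStudyDesign(seed=3)  # 65 participants x 20 threads = 1300 events
data = generate_reading_study(design, params)
deltas = event_deltas(data)

spec = select_subset(deltas, "valence")
fit = fit_nls(deltas, spec)
print(spec.orders, round(fit.r_squared, 3))
for name, est in fit.estimates.items():
    print(f"{name:8s} {est:+.4f}  (se {fit.standard_errors[name]:.4f})")
```

Output from this exact snippet:

```
0.056 -0.442
(0, 2, 3) 0.52
gamma_v  +0.3954  (se 0.0126)
b        +0.0059  (se 0.0174)
b0       +0.1180  (se 0.0100)
b2       +0.0640  (se 0.0230)
b3       -0.0525  (se 0.0190)
```

Read: the AIC search keeps the constant, quadratic and cubic field
couplings and drops the linear one — the structure of the generating model
— and the relaxation rate (≈0.40/min vs 0.367 generating) and constant
field push (≈0.12 vs 0.14) are recovered within sampling error at the
scale of one study, with R² ≈ 0.5.

The numbered scripts under `analysis/` run the complete story — generate
the three studies, fit dynamics and behaviour, run the 20-seed recovery
experiments, and simulate a reading session and a coupled community
(`python analysis/01_generate_studies.py`, then 02…05); tables land under
`results/`.  The same stages are available as a CLI
(`emodyn generate|simulate|fit-dynamics|fit-participation|fit-expression|report|all`).

## Layout

```
src/emodyn/        model kernel, simulator, generators, estimators, pipeline
analysis/          numbered narrative drivers (01_generate ... 05_simulate)
scripts/           acceptance.py
tests/             pytest suite (unit, property, end-to-end recovery)
docs/methods.md    model, generator conventions, numerics, limitations
```
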