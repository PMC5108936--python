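#!/usr/bin/env python
"""Parameter-recovery validation of the whole estimation chain.

Generates 20 seeded synthetic datasets per protocol with the reference
estimates as ground truth, re-runs each estimator, and compares the mean
recovered values with the generating ones.  Also tallies how often the AIC
subset search keeps exactly the generating term structure.  Writes the
per-seed results under results/tables/.
"""

import sys
import warnings
from pathlib import Path

from emodyn.params import reference_expression_coeffs, reference_params
from emodyn.recovery import (
    dynamics_recovery,
    expression_recovery,
    feedback_recovery,
    participation_recovery,
)

OUT = Path("results/tables")
BASE_SEED = 0


def report(label: str, mean: float, truth: float) -> None:
    print(f"  {label:10s} mean {mean:+.4f}  generating {truth:+.4f}  "
          f"delta {mean - truth:+.4f}")


def main() -> None:
    warnings.filterwarnings("ignore", message="skipping subset")
    OUT.mkdir(parents=True, exist_ok=True)
    params = reference_params()
    coeffs = reference_expression_coeffs()

    print("dynamics recovery (20 seeds, ~1300 events each):")
    dyn = dynamics_recovery(params, n_seeds=20, base_seed=BASE_SEED, run_selection=True)
    dyn.to_csv(OUT / "recovery_dynamics.csv", index=False)
    for name, truth in (
        ("gamma_v", params.valence.gamma_v), ("b", params.valence.b),
        ("b0", params.valence.b0), ("gamma_a", params.arousal.gamma_a),
        ("d", params.arousal.d), ("d0", params.arousal.d0),
    ):
        report(name, dyn[name].mean(), truth)
    excl_v1 = (~dyn["valence_orders"].str.contains("1")).mean()
    excl_a23 = (~dyn["arousal_orders"].str.contains("[23]", regex=True)).mean()
    print(f"  AIC drops the absent order-1 valence term in {excl_v1:.0%} of seeds")
    print(f"  AIC drops both absent arousal terms (orders 2,3) in {excl_a23:.0%} of seeds")
    print("  (a true-zero term still enters with ~16% chance per term under AIC,")
    print("   so joint exclusion rates sit well below 100% by construction)")

    print("\nparticipation recovery (20 seeds):")
    part = participation_recovery(params, n_seeds=20, base_seed=BASE_SEED)
    part.to_csv(OUT / "recovery_participation.csv", index=False)
    report("p0", part["p0"].mean(), params.participation.p0)
    report("alpha", part["alpha"].mean(), params.participation.alpha)
    report("tau", part["tau"].mean(), params.participation.tau_p)

    print("\nexpression-content recovery (20 seeds, 5000 posts each):")
    expr = expression_recovery(params, coeffs, n_posts=5000, n_seeds=20, base_seed=BASE_SEED)
    expr.to_csv(OUT / "recovery_expression.csv", index=False)
    report("pos slope", expr["pos_slope"].mean(), coeffs["pos"]["slope"])
    report("neg slope", expr["neg_slope"].mean(), coeffs["neg"]["slope"])

    print("\nfeedback recovery (20 seeds, 65 writers each):")
    fb = feedback_recovery(params, coeffs, n_participants=65, n_seeds=20, base_seed=BASE_SEED)
    fb.to_csv(OUT / "recovery_feedback.csv", index=False)
    lam = params.expression.lambda_a
    report("first c1", fb["first_c1"].mean(), lam - 1)
    report("reply c1", fb["reply_c1"].mean(), lam - 1)
    print(f"\nper-seed tables written to {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
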