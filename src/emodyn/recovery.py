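"""Parameter-recovery protocols.

The published regression tables were fitted to human-subject data that are
not deposited, so the estimation chain is validated by *recovery*: synthetic
datasets are generated with the published point estimates as ground truth
and the chain must return estimates near those values.  Each protocol here
runs one such experiment over a set of seeds and returns the per-seed
estimates; callers average over seeds.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .fit_behavior import (
    classify_writing_records,
    fit_feedback,
    fit_hinge_participation,
    fit_logistic_expression,
)
from .fit_dynamics import ModelSpec, event_deltas, fit_nls, select_subset
from .params import ModelParams
from .synth import ReadingStudyDesign, generate_reading_study, generate_writing_study

__all__ = [
    "spawn_seeds",
    "dynamics_recovery",
    "participation_recovery",
    "expression_recovery",
    "feedback_recovery",
]

#: Term subsets retained by the reference fits: the linear valence coupling
#: and the quadratic/cubic arousal couplings are dropped.
VALENCE_ORDERS = frozenset({0, 2, 3})
AROUSAL_ORDERS = frozenset({0, 1})


def spawn_seeds(base_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit seeds from one master seed."""
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n)


def _design_with_seed(design: ReadingStudyDesign, seed: int) -> ReadingStudyDesign:
    d = design.to_dict()
    d["seed"] = int(seed)
    d["thread_counts"] = tuple(d["thread_counts"])
    if d["noise"] is not None:
        d["noise"] = tuple(d["noise"])
    return ReadingStudyDesign(**d)


def dynamics_recovery(
    params: ModelParams,
    design: Optional[ReadingStudyDesign] = None,
    n_seeds: int = 20,
    base_seed: int = 0,
    run_selection: bool = False,
) -> pd.DataFrame:
    """Recovery of the drift parameters from synthetic reading studies.

    Per seed: generate a reading study with ``params`` as ground truth,
    reduce it to event deltas, and fit the valence and arousal drifts by
    least squares on the reference term subsets.  With ``run_selection``
    the exhaustive AIC subset search is also run and the selected orders
    recorded (as sorted strings, e.g. ``"023"``).
    """
    if design is None:
        design = ReadingStudyDesign()
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        data = generate_reading_study(_design_with_seed(design, seed), params)
        deltas = event_deltas(data)
        vfit = fit_nls(deltas, ModelSpec("valence", VALENCE_ORDERS))
        afit = fit_nls(deltas, ModelSpec("arousal", AROUSAL_ORDERS))
        row = {"seed": int(seed), "n_events": len(deltas)}
        row.update(vfit.estimates)
        row["r2_valence"] = vfit.r_squared
        row.update(afit.estimates)
        row["r2_arousal"] = afit.r_squared
        if run_selection:
            vsel = select_subset(deltas, "valence")
            asel = select_subset(deltas, "arousal")
            row["valence_orders"] = "".join(map(str, vsel.orders))
            row["arousal_orders"] = "".join(map(str, asel.orders))
        rows.append(row)
    return pd.DataFrame(rows)


def participation_recovery(
    params: ModelParams,
    design: Optional[ReadingStudyDesign] = None,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Recovery of the hinge participation parameters (p0, alpha, tau) from
    the intention reports of synthetic reading studies."""
    if design is None:
        design = ReadingStudyDesign()
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        data = generate_reading_study(_design_with_seed(design, seed), params)
        fit = fit_hinge_participation(data["a_post"], data["intention"])
        rows.append(
            {
                "seed": int(seed),
                "p0": fit.p0,
                "alpha": fit.alpha,
                "tau": fit.tau,
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)


def expression_recovery(
    params: ModelParams,
    expression_coeffs: dict,
    n_posts: int = 5000,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Recovery of the logistic content-model slopes from synthetic posts.

    Per seed: generate a writing study large enough to yield ``n_posts``
    posts, classify the posts back into content flags with the strength
    thresholds, and refit both logistic models of flag on reported
    pre-writing valence.
    """
    n_participants = max(1, int(round(n_posts / 4)))
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        posts = generate_writing_study(
            n_participants, params, expression_coeffs, seed=int(seed)
        )
        posts = classify_writing_records(posts, method="strength")
        pos = fit_logistic_expression(posts["v_pre"], posts["is_pos"], "valence")
        neg = fit_logistic_expression(posts["v_pre"], posts["is_neg"], "valence")
        rows.append(
            {
                "seed": int(seed),
                "pos_intercept": pos.intercept,
                "pos_slope": pos.slope,
                "pos_deviance": pos.deviance,
                "pos_loglik": pos.loglik,
                "neg_intercept": neg.intercept,
                "neg_slope": neg.slope,
                "neg_deviance": neg.deviance,
                "neg_loglik": neg.loglik,
                "n": len(posts),
            }
        )
    return pd.DataFrame(rows)


def feedback_recovery(
    params: ModelParams,
    expression_coeffs: dict,
    n_participants: int = 65,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Recovery of the feedback-of-expression slope (lambda_a - 1) from the
    pre/post arousal reports of synthetic writing studies."""
    rows = []
    for seed in spawn_seeds(base_seed, n_seeds):
        posts = generate_writing_study(
            n_participants, params, expression_coeffs, seed=int(seed)
        )
        fits = fit_feedback(posts)
        row = {"seed": int(seed)}
        for kind, fit in fits.items():
            row[f"{kind}_c0"] = fit.c0
            row[f"{kind}_c1"] = fit.c1
            row[f"{kind}_n"] = fit.n
        rows.append(row)
    return pd.DataFrame(rows)
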