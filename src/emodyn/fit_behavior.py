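"""Estimation of the behavioural rules: participation, expression, feedback.

Covers the hinge (single-knot threshold) regression of participation
intention on arousal, the threshold classification of post sentiment into
positive/negative content flags, logistic models linking those flags to the
writer's emotional state, and the linear regression quantifying how writing
a post feeds back on arousal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ParticipationFit",
    "PolarityFlags",
    "LogisticFit",
    "FeedbackFit",
    "fit_hinge_participation",
    "classify_sentistrength",
    "classify_qdap",
    "classify_writing_records",
    "fit_logistic_expression",
    "fit_feedback",
]


@dataclass
class ParticipationFit:
    """Hinge-model fit p(a) = p0 + alpha * a * Theta[a - tau]."""

    p0: float
    alpha: float
    tau: float
    r_squared: float
    n: int
    diagnostics: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=float) + "\n")


@dataclass(frozen=True)
class PolarityFlags:
    """Positive/negative content indicators of one post.  A post can carry
    both kinds of content at once."""

    is_pos: bool
    is_neg: bool


@dataclass
class LogisticFit:
    """Logistic regression of a content flag on one emotional predictor."""

    predictor: str
    intercept: float
    slope: float
    loglik: float
    deviance: float
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


@dataclass
class FeedbackFit:
    """OLS of the arousal change after writing on the pre-writing arousal.

    Under a shrink-toward-zero feedback with factor ``lambda``, the slope
    ``c1`` identifies ``lambda - 1`` (full reset gives -1, no feedback 0).
    """

    kind: str
    c0: float
    c1: float
    r_squared: float
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


def fit_hinge_participation(
    arousal: Sequence[float],
    intention: Sequence[float],
    max_knots: int = 1,
) -> ParticipationFit:
    """Single-knot threshold regression of intention on arousal.

    The knot tau is located by exhaustive search over the unique observed
    arousal values; at each candidate an OLS of intention on
    ``[1, a * Theta(a - tau)]`` is solved and the minimum-SSE knot wins,
    ties resolved toward the knot nearest 0.  This is the one-term special
    case of an adaptive regression-spline fit, matching the model's single
    activation threshold.  With ``max_knots=2`` a second hinge term is added
    greedily (exploratory; the primary model has one knot).

    The regressor is ``a * Theta(a - tau)`` (not the centred hinge
    ``(a - tau) * Theta``), so the fitted mean is discontinuous at a nonzero
    knot; with the knot at 0 the two parameterizations coincide.
    """
    a = np.asarray(arousal, dtype=float)
    y = np.asarray(intention, dtype=float)
    if len(a) != len(y):
        raise ValueError("arousal and intention must have equal length")
    n = len(a)
    if n < 10:
        raise ValueError(f"need at least 10 pairs, got {n}")
    knots = np.unique(a)
    if len(knots) < 2:
        raise ValueError("degenerate fit: all arousal values identical")

    sst = float(np.sum((y - y.mean()) ** 2))
    best = None  # (sse, |tau|, tau, coef)
    for tau in knots:
        x = a * (a >= tau)
        if np.ptp(x) == 0:  # all arousals on one side -> collinear with intercept
            continue
        X = np.column_stack([np.ones(n), x])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 2:
            continue
        resid = y - X @ coef
        sse = float(resid @ resid)
        tol = 1e-12 * max(sst, 1.0)
        better = best is None or sse < best[0] - tol
        tied_closer = best is not None and sse <= best[0] + tol and abs(tau) < best[1]
        if better or tied_closer:
            best = (sse, abs(tau), float(tau), coef)
    if best is None:
        raise ValueError("degenerate fit: no candidate knot separates the data")
    sse, _, tau, coef = best

    diagnostics: dict = {"knots": [tau]}
    # alpha ~ 0 leaves the knot undetermined: flag it
    diagnostics["identifiable"] = bool(sst - sse > 1e-12 * max(sst, 1.0))

    if max_knots >= 2:
        x1 = a * (a >= tau)
        best2 = None
        for tau2 in knots:
            if tau2 == tau:
                continue
            x2 = a * (a >= tau2)
            X = np.column_stack([np.ones(n), x1, x2])
            if np.linalg.matrix_rank(X) < 3:
                continue
            coef2, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef2
            sse2 = float(resid @ resid)
            if best2 is None or sse2 < best2[0]:
                best2 = (sse2, float(tau2), coef2)
        if best2 is not None and best2[0] < sse:
            diagnostics["knots"] = [tau, best2[1]]
            diagnostics["second_knot_coef"] = float(best2[2][2])

    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return ParticipationFit(
        p0=float(coef[0]),
        alpha=float(coef[1]),
        tau=tau,
        r_squared=r2,
        n=n,
        diagnostics=diagnostics,
    )


def classify_sentistrength(pos_strength: int, neg_strength: int) -> PolarityFlags:
    """Dual-scale strength scores -> content flags.

    A post is positive when its positive strength reaches 3 (scale 1..5) and
    negative when its negative strength reaches -3 (scale -1..-5); the two
    judgements are independent.
    """
    if not (1 <= pos_strength <= 5):
        raise ValueError(f"pos_strength={pos_strength!r} outside 1..5")
    if not (-5 <= neg_strength <= -1):
        raise ValueError(f"neg_strength={neg_strength!r} outside -5..-1")
    return PolarityFlags(is_pos=pos_strength >= 3, is_neg=neg_strength <= -3)


def classify_qdap(sentence_polarities: Sequence[float]) -> PolarityFlags:
    """Per-sentence polarity scores -> content flags.

    Negative when the minimum sentence polarity falls strictly below -0.25,
    positive when the maximum rises strictly above +0.25.
    """
    pols = np.asarray(list(sentence_polarities), dtype=float)
    if pols.size == 0:
        raise ValueError("sentence polarity list must be non-empty")
    if np.any(np.abs(pols) > 1.0):
        raise ValueError("sentence polarities must lie in [-1, 1]")
    return PolarityFlags(
        is_pos=bool(pols.max() > 0.25), is_neg=bool(pols.min() < -0.25)
    )


def classify_writing_records(records: pd.DataFrame, method: str = "strength") -> pd.DataFrame:
    """Add ``is_pos``/``is_neg`` columns to writing records.

    ``method='strength'`` applies the dual-strength thresholds;
    ``method='sentence'`` applies the per-sentence polarity thresholds to
    the JSON-encoded ``sentence_polarities`` field.
    """
    if method == "strength":
        flags = [
            classify_sentistrength(int(p), int(q))
            for p, q in zip(records["pos_strength"], records["neg_strength"])
        ]
    elif method == "sentence":
        flags = [
            classify_qdap(json.loads(s)) for s in records["sentence_polarities"]
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    out = records.copy()
    out["is_pos"] = [f.is_pos for f in flags]
    out["is_neg"] = [f.is_neg for f in flags]
    return out


def fit_logistic_expression(
    predictor: Sequence[float],
    flag: Sequence[bool],
    predictor_name: str = "valence",
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a content flag on one
    emotional predictor (valence or arousal)."""
    x = np.asarray(predictor, dtype=float)
    yy = np.asarray(flag, dtype=float)
    if set(np.unique(yy)) != {0.0, 1.0}:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            model = sm.Logit(yy, X).fit(disp=0)
        except Exception as exc:
            raise ValueError(f"logistic fit failed: complete separation suspected ({exc})") from exc
    params = np.asarray(model.params)
    if np.any(np.abs(params) > 1e3) or not np.all(np.isfinite(params)):
        raise ValueError("complete separation: coefficient estimates diverged")
    ll = float(model.llf)
    return LogisticFit(
        predictor=predictor_name,
        intercept=float(params[0]),
        slope=float(params[1]),
        loglik=ll,
        deviance=-2.0 * ll,
        n=len(yy),
    )


def fit_feedback(records: pd.DataFrame) -> dict:
    """Per-kind OLS of the post-writing arousal change on pre-writing arousal.

    ``records`` needs columns ``a_pre``, ``a_post`` and either ``kind``
    ('first'/'reply') or ``task`` (reply_*/init_* mapped accordingly).
    Returns ``{kind: FeedbackFit}``; a kind with no data is skipped with a
    warning.
    """
    df = records.copy()
    if "kind" not in df.columns:
        if "task" not in df.columns:
            raise KeyError("records need a 'kind' or 'task' column")
        df["kind"] = np.where(
            df["task"].astype(str).str.startswith("reply"), "reply", "first"
        )
    fits: dict = {}
    for kind in ("first", "reply"):
        sub = df[df["kind"] == kind]
        if len(sub) == 0:
            warnings.warn(f"no records of kind {kind!r}; skipping", stacklevel=2)
            continue
        if len(sub) < 10:
            raise ValueError(f"need at least 10 records of kind {kind!r}, got {len(sub)}")
        a_pre = sub["a_pre"].to_numpy(float)
        delta = sub["a_post"].to_numpy(float) - a_pre
        X = np.column_stack([np.ones(len(sub)), a_pre])
        coef, *_ = np.linalg.lstsq(X, delta, rcond=None)
        resid = delta - X @ coef
        sse = float(resid @ resid)
        sst = float(np.sum((delta - delta.mean()) ** 2))
        fits[kind] = FeedbackFit(
            kind=kind,
            c0=float(coef[0]),
            c1=float(coef[1]),
            r_squared=1.0 - sse / sst if sst > 0 else float("nan"),
            n=len(sub),
        )
    return fits
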