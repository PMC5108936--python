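"""Synthetic reading- and writing-study generators.

The three laboratory studies this package emulates are not deposited as raw
data, so every estimation stage is exercised on synthetic datasets with the
same statistical structure:

* a *reading study*: each participant reads a randomized sequence of
  negatively / positively / neutrally charged threads, reporting valence,
  arousal (7-point Likert scales mapped to [-1, 1]) and an intention to
  participate after each thread;
* a *writing study*: each participant produces four posts (positive and
  negative replies and thread initiations) with emotion reports before and
  after writing, and per-post sentiment scores.

Generation conventions that matter for estimation are documented on the
functions; in particular the reading generator advances the latent state
with a single Euler step per thread, evaluating the drift at the pre-thread
state, so that noise-free generation and the event-level regression agree
exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import participation_probability, valence_drift, arousal_drift
from .params import EmotionState, ExpressionParams, ModelParams
from .simulate import apply_expression_feedback

__all__ = [
    "ReadingStudyDesign",
    "generate_reading_study",
    "generate_writing_study",
    "quantize_likert",
    "composite_valence",
    "write_dataset",
    "READING_COLUMNS",
    "WRITING_COLUMNS",
]

READING_COLUMNS = [
    "participant_id", "event_index", "h", "duration_min",
    "v_pre", "a_pre", "v_post", "a_post", "intention",
]
WRITING_COLUMNS = [
    "participant_id", "task", "v_pre", "a_pre", "v_post", "a_post",
    "pos_strength", "neg_strength", "sentence_polarities",
]

WRITING_TASKS = ("reply_pos", "reply_neg", "init_pos", "init_neg")


@dataclass(frozen=True)
class ReadingStudyDesign:
    """Design of a synthetic reading study.

    Defaults give ~1300 events (65 participants x 20 threads with the
    9 negative / 9 positive / 2 neutral mix of the larger study design).
    Reading durations are lognormal with a 2-minute median; report noise is
    additive Gaussian measurement error on each Likert report, distinct
    from the process noise of the dynamics.
    """

    n_participants: int = 65
    thread_counts: tuple[int, int, int] = (9, 9, 2)  # (negative, positive, neutral)
    duration_median_min: float = 2.0
    duration_sigma: float = 0.4
    duration_clip: tuple[float, float] = (0.5, 3.0)
    noise: Optional[tuple[float, float]] = None  # (A_v, A_a); None -> params'
    report_noise_sd: float = 0.1
    quantize: bool = False
    intention_noise_sd: float = 0.15
    initial_state_sd: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(c < 0 for c in self.thread_counts) or sum(self.thread_counts) < 1:
            raise ValueError(
                f"thread_counts must be non-negative with at least one thread, "
                f"got {self.thread_counts!r}"
            )
        for name in ("report_noise_sd", "intention_noise_sd", "initial_state_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_median_min <= 0 or self.duration_sigma < 0:
            raise ValueError("invalid duration distribution")
        lo, hi = self.duration_clip
        if not (0 < lo <= hi):
            raise ValueError("duration_clip must satisfy 0 < lo <= hi")

    @property
    def n_threads(self) -> int:
        return int(sum(self.thread_counts))

    def to_dict(self) -> dict:
        return asdict(self)


def generate_reading_study(
    design: ReadingStudyDesign, params: ModelParams
) -> pd.DataFrame:
    """Simulate a reading study; one row per (participant, thread) event.

    Per participant: a randomized thread order with the designed polarity
    counts; the latent state starts near the relaxation baselines and is
    advanced across each thread by one Euler–Maruyama step of the thread's
    duration (drift evaluated at the pre-thread state).  Each boundary state
    is reported once — with additive Gaussian report noise and optional
    Likert quantization — and serves both as the post-report of one event
    and the pre-report of the next, as in the real between-thread reports.
    The participation intention is the hinge model evaluated at the
    *reported* post-thread arousal plus truncated Gaussian noise.
    """
    rng = np.random.default_rng(design.seed)
    n_p, n_t = design.n_participants, design.n_threads
    n_neg, n_pos, n_neu = design.thread_counts
    A_v, A_a = design.noise if design.noise is not None else (
        params.valence.A_v, params.arousal.A_a
    )

    base = np.concatenate(
        [np.full(n_neg, -1.0), np.full(n_pos, 1.0), np.zeros(n_neu)]
    )
    H = np.tile(base, (n_p, 1))
    H = rng.permuted(H, axis=1)

    mu = np.log(design.duration_median_min)
    D = rng.lognormal(mu, design.duration_sigma, size=(n_p, n_t))
    # bounded reading times keep the per-event Euler map inside the state box
    D = np.clip(D, *design.duration_clip)

    vp, ap = params.valence, params.arousal
    # initial latent states scatter around the baselines (draws truncated at
    # +-2 sd so sessions start away from the hard state bounds)
    z_v = np.clip(rng.standard_normal(n_p), -2, 2)
    z_a = np.clip(rng.standard_normal(n_p), -2, 2)
    v = np.clip(vp.b + design.initial_state_sd * z_v, -1, 1)
    a = np.clip(ap.d + design.initial_state_sd * z_a, -1, 1)

    def report(v_true: np.ndarray, a_true: np.ndarray):
        rv = v_true + design.report_noise_sd * rng.standard_normal(n_p)
        ra = a_true + design.report_noise_sd * rng.standard_normal(n_p)
        rv, ra = np.clip(rv, -1, 1), np.clip(ra, -1, 1)
        if design.quantize:
            rv = quantize_likert_array(rv)
            ra = quantize_likert_array(ra)
        return rv, ra

    rv, ra = report(v, a)
    rows = []
    for j in range(n_t):
        h, dt = H[:, j], D[:, j]
        sq = np.sqrt(dt)
        v_new = v + valence_drift(v, h, vp) * dt + A_v * sq * rng.standard_normal(n_p)
        a_new = a + arousal_drift(a, h, ap) * dt + A_a * sq * rng.standard_normal(n_p)
        v_new, a_new = np.clip(v_new, -1, 1), np.clip(a_new, -1, 1)
        rv_new, ra_new = report(v_new, a_new)
        intent = participation_probability(ra_new, params.participation)
        intent = np.clip(
            intent + design.intention_noise_sd * rng.standard_normal(n_p), 0, 1
        )
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": np.arange(n_p),
                    "event_index": j,
                    "h": h,
                    "duration_min": dt,
                    "v_pre": rv,
                    "a_pre": ra,
                    "v_post": rv_new,
                    "a_post": ra_new,
                    "intention": intent,
                }
            )
        )
        v, a, rv, ra = v_new, a_new, rv_new, ra_new
    df = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["participant_id", "event_index"])
        .reset_index(drop=True)
    )
    return df[READING_COLUMNS]


def generate_writing_study(
    n_participants: int,
    params: ModelParams,
    expression_coeffs: dict,
    feedback: Optional[ExpressionParams] = None,
    seed: Optional[int] = None,
    report_noise_sd: float = 0.1,
    prior_halfwidth: float = 0.6,
    task_shift: float = 0.15,
) -> pd.DataFrame:
    """Simulate a writing study; four posts (rows) per participant.

    Pre-writing states are uniform on ``[-prior_halfwidth, prior_halfwidth]``
    with valence shifted by ``+-task_shift`` toward the task's polarity (the
    topic choice nudges mood).  Post-writing states apply the feedback of
    expression to the latent pre-state, then report noise.  Post content
    flags are Bernoulli draws from the logistic models evaluated at the
    *reported* pre-writing valence — the observable the downstream refit
    uses — and the per-post sentiment scores are generated to be exactly
    consistent with those flags under the classification threshold rules
    (integer strengths >= 3 / <= -3; per-sentence polarity beyond +-0.25).

    ``expression_coeffs`` must map ``"pos"``/``"neg"`` to
    ``{"intercept", "slope"}`` on the log-odds scale.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    for key in ("pos", "neg"):
        if key not in expression_coeffs or not {
            "intercept", "slope"
        } <= set(expression_coeffs[key]):
            raise KeyError(f"expression_coeffs missing {key!r} intercept/slope")
    if feedback is None:
        feedback = params.expression
    rng = np.random.default_rng(seed)

    rows = []
    for pid in range(n_participants):
        for task in WRITING_TASKS:
            pol = 1.0 if task.endswith("pos") else -1.0
            kind = "reply" if task.startswith("reply") else "first"
            v_true = float(
                np.clip(
                    rng.uniform(-prior_halfwidth, prior_halfwidth) + pol * task_shift,
                    -1, 1,
                )
            )
            a_true = float(rng.uniform(-prior_halfwidth, prior_halfwidth))
            post = apply_expression_feedback(EmotionState(v_true, a_true), kind, feedback)

            def rep(x: float) -> float:
                return float(np.clip(x + report_noise_sd * rng.standard_normal(), -1, 1))

            v_pre, a_pre = rep(v_true), rep(a_true)
            v_post, a_post = rep(post.valence), rep(post.arousal)

            def flag(which: str) -> bool:
                c = expression_coeffs[which]
                eta = c["intercept"] + c["slope"] * v_pre
                return bool(rng.random() < 1.0 / (1.0 + np.exp(-eta)))

            is_pos, is_neg = flag("pos"), flag("neg")
            pos_strength = int(rng.integers(3, 6) if is_pos else rng.integers(1, 3))
            neg_strength = int(-rng.integers(3, 6) if is_neg else -rng.integers(1, 3))
            n_sent = int(rng.integers(max(1, is_pos + is_neg), 5))
            sents = rng.uniform(-0.2, 0.2, size=n_sent)
            slots = rng.permutation(n_sent)
            if is_pos:
                sents[slots[0]] = rng.uniform(0.3, 1.0)
            if is_neg:
                sents[slots[1] if is_pos else slots[0]] = rng.uniform(-1.0, -0.3)
            rows.append(
                {
                    "participant_id": pid,
                    "task": task,
                    "v_pre": v_pre,
                    "a_pre": a_pre,
                    "v_post": v_post,
                    "a_post": a_post,
                    "pos_strength": pos_strength,
                    "neg_strength": neg_strength,
                    "sentence_polarities": json.dumps(
                        [round(float(s), 4) for s in sents]
                    ),
                }
            )
    return pd.DataFrame(rows, columns=WRITING_COLUMNS)


def quantize_likert(x: float, points: int = 7) -> float:
    """Snap ``x`` in [-1, 1] to the nearest of ``points`` evenly spaced
    values spanning [-1, 1]; exact midpoint ties resolve toward 0."""
    if points < 2:
        raise ValueError("points must be >= 2")
    if abs(x) > 1.0:
        raise ValueError(f"x={x!r} outside [-1, 1]")
    grid = np.linspace(-1.0, 1.0, points)
    d = np.abs(grid - x)
    dmin = d.min()
    ties = grid[np.isclose(d, dmin, rtol=0.0, atol=1e-12)]
    return float(ties[np.argmin(np.abs(ties))])


def quantize_likert_array(x: np.ndarray, points: int = 7) -> np.ndarray:
    """Vectorized :func:`quantize_likert` (same tie-toward-0 convention)."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0):
        raise ValueError("values outside [-1, 1]")
    grid = np.linspace(-1.0, 1.0, points)
    d = np.abs(x.reshape(-1, 1) - grid[None, :])
    dmin = d.min(axis=1, keepdims=True)
    tie = np.isclose(d, dmin, rtol=0.0, atol=1e-12)
    # among tied grid points, pick the one with smallest |value|
    penal = np.where(tie, np.abs(grid)[None, :], np.inf)
    out = grid[np.argmin(penal, axis=1)]
    return out.reshape(x.shape)


def composite_valence(pos_item: int, neg_item: int) -> float:
    """Two-item valence composite: ``(positive - negative) / 6`` maps a pair
    of 7-point Likert ratings onto [-1, 1]."""
    for name, item in (("pos_item", pos_item), ("neg_item", neg_item)):
        if not (1 <= item <= 7):
            raise ValueError(f"{name}={item!r} outside the 7-point scale")
    return (pos_item - neg_item) / 6.0


def write_dataset(
    df: pd.DataFrame,
    path: str | Path,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> Path:
    """Write a dataset CSV plus a sidecar ``<name>.manifest.json`` recording
    the seed, a hash of the generating configuration, and the file hash."""
    path = Path(path)
    df.to_csv(path, index=False)
    payload = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "file": path.name,
        "n_rows": int(len(df)),
        "seed": seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "data_sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }
    mpath = path.with_suffix(".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=1) + "\n")
    return mpath
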