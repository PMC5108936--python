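"""Stochastic integration of the agent dynamics.

Euler–Maruyama integration of the valence/arousal equations, session-level
simulation of a participant reading a sequence of emotionally charged
threads, the feedback of expression on the writer's state, and a small
illustrative community simulation in which the field itself is driven by the
agents' expressed posts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import arousal_drift, expression, valence_drift
from .params import EmotionState, ExpressionParams, ModelParams

__all__ = [
    "ThreadStimulus",
    "Trajectory",
    "step",
    "simulate_session",
    "apply_expression_feedback",
    "simulate_community",
]

#: Default inner integration step (minutes) for session simulations.
DEFAULT_DT = 0.01


@dataclass(frozen=True)
class ThreadStimulus:
    """One thread to be read: emotional charge and reading duration."""

    h: float
    duration: float = 2.0

    def __post_init__(self) -> None:
        if abs(self.h) > 1.0:
            raise ValueError(f"thread charge h={self.h!r} outside [-1, 1]")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration!r}")


@dataclass
class Trajectory:
    """A simulated emotional path with per-thread reported states.

    ``times``/``valence``/``arousal``/``h`` sample the fine-grained path;
    ``reports`` holds one row per thread boundary (the states a participant
    would report between threads).
    """

    times: np.ndarray
    valence: np.ndarray
    arousal: np.ndarray
    h: np.ndarray
    reports: pd.DataFrame
    seed: Optional[int] = None
    params: Optional[dict] = None
    stimuli: Sequence[ThreadStimulus] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        """Write the fine-grained path as CSV with the seed in a header comment."""
        buf = io.StringIO()
        buf.write(f"# seed={self.seed}\n")
        pd.DataFrame(
            {
                "time_min": self.times,
                "valence": self.valence,
                "arousal": self.arousal,
                "h": self.h,
                "expressed": np.full(len(self.times), np.nan),
            }
        ).to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())


def step(
    state: EmotionState,
    h: float,
    dt: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> EmotionState:
    """One Euler–Maruyama step of length ``dt`` minutes.

    ``v' = v + drift dt + A_v sqrt(dt) z`` with ``z`` standard normal,
    independently for arousal; the result is clipped to [-1, 1] (subjective
    reports are bounded, so the state space is treated as a hard box).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    zv, za = rng.standard_normal(2)
    sq = np.sqrt(dt)
    v = (
        state.valence
        + valence_drift(state.valence, h, params.valence) * dt
        + params.valence.A_v * sq * zv
    )
    a = (
        state.arousal
        + arousal_drift(state.arousal, h, params.arousal) * dt
        + params.arousal.A_a * sq * za
    )
    return EmotionState(float(np.clip(v, -1, 1)), float(np.clip(a, -1, 1)))


def simulate_session(
    initial: EmotionState,
    threads: Sequence[ThreadStimulus],
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    report_noise: float = 0.0,
    quantize: bool = False,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = None,
) -> Trajectory:
    """Integrate one participant's state across a sequence of threads.

    The state evolves at fixed inner step ``dt`` during each thread's
    reading time; after each thread one state is "reported" (true state plus
    optional Gaussian report noise, optionally snapped to the 7-point Likert
    grid).  Deterministic given the generator/seed.
    """
    from .synth import quantize_likert  # local import to avoid a cycle

    threads = list(threads)
    if not threads:
        raise ValueError("thread list must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)

    times = [0.0]
    vs = [initial.valence]
    as_ = [initial.arousal]
    hs = [threads[0].h]
    reports = []
    state = initial
    t = 0.0
    for idx, th in enumerate(threads):
        n_steps = max(1, int(round(th.duration / dt)))
        inner = th.duration / n_steps
        for _ in range(n_steps):
            state = step(state, th.h, inner, params, rng)
            t += inner
            times.append(t)
            vs.append(state.valence)
            as_.append(state.arousal)
            hs.append(th.h)
        rv = state.valence + report_noise * rng.standard_normal()
        ra = state.arousal + report_noise * rng.standard_normal()
        rv, ra = float(np.clip(rv, -1, 1)), float(np.clip(ra, -1, 1))
        if quantize:
            rv, ra = quantize_likert(rv), quantize_likert(ra)
        reports.append(
            {"thread": idx, "time_min": t, "h": th.h, "valence": rv, "arousal": ra}
        )
    return Trajectory(
        times=np.array(times),
        valence=np.array(vs),
        arousal=np.array(as_),
        h=np.array(hs),
        reports=pd.DataFrame(reports),
        seed=seed,
        params=params.to_flat_dict(),
        stimuli=tuple(threads),
    )


def apply_expression_feedback(
    state: EmotionState, kind: str, p: ExpressionParams
) -> EmotionState:
    """Instantaneous regulation after writing a post.

    Arousal shrinks toward zero by ``lambda_a`` from either sign (writing is
    calming: negative arousal rises, positive arousal falls).  Replying while
    in a negative-valence state additionally shrinks valence by ``lambda_v``
    (partial mood repair); initiating a thread leaves valence untouched.
    """
    if kind not in ("first", "reply"):
        raise KeyError(f"unknown expression kind {kind!r}; expected 'first' or 'reply'")
    a = p.lambda_a * state.arousal
    v = state.valence
    if kind == "reply" and v < 0:
        v = p.lambda_v * v
    return EmotionState(float(v), float(a))


def simulate_community(
    n_agents: int,
    params: ModelParams,
    field_decay: float,
    field_gain: float,
    steps: int,
    rng: Optional[np.random.Generator] = None,
    dt: float = 0.1,
    h0: float = 0.0,
    initial_states: Optional[np.ndarray] = None,
) -> dict:
    """Illustrative closed-loop community: agents <-> shared field.

    Each step: every agent advances one Euler–Maruyama step under the
    current field ``h``; agents whose arousal meets the expression threshold
    post ``s = f_s(v)`` and receive the feedback of expression; the field
    then relaxes, ``h <- field_decay * h + field_gain * mean(expressed s)``
    (zero contribution when nobody expresses), clipped to [-1, 1].

    This update rule is a deliberately simple aggregation of expressed
    polarity and is not calibrated to any real corpus.

    Returns a dict with ``h`` (length ``steps+1``), ``valence``/``arousal``
    arrays of shape ``(steps+1, n_agents)`` and the boolean ``expressed``
    mask of shape ``(steps, n_agents)``.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    if not (0.0 <= field_decay <= 1.0 and 0.0 <= field_gain <= 1.0):
        raise ValueError("field_decay and field_gain must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()

    vp, ap, ep = params.valence, params.arousal, params.expression
    if initial_states is None:
        v = np.full(n_agents, vp.b)
        a = np.full(n_agents, ap.d)
    else:
        v = np.array(initial_states[:, 0], dtype=float)
        a = np.array(initial_states[:, 1], dtype=float)

    h = float(h0)
    hs = [h]
    vs = [v.copy()]
    as_ = [a.copy()]
    expr_mask = np.zeros((steps, n_agents), dtype=bool)
    sq = np.sqrt(dt)
    for k in range(steps):
        zv = rng.standard_normal(n_agents)
        za = rng.standard_normal(n_agents)
        v = v + valence_drift(v, h, vp) * dt + vp.A_v * sq * zv
        a = a + arousal_drift(a, h, ap) * dt + ap.A_a * sq * za
        v = np.clip(v, -1, 1)
        a = np.clip(a, -1, 1)
        mask = a >= ep.tau_expr
        expr_mask[k] = mask
        if mask.any():
            s = np.array([ep.fs(x) for x in v[mask]])
            contribution = float(np.mean(s))
            # feedback of expression for the writers
            a[mask] *= ep.lambda_a
            neg = mask & (v < 0)
            v[neg] *= ep.lambda_v
        else:
            contribution = 0.0
        h = float(np.clip(field_decay * h + field_gain * contribution, -1, 1))
        hs.append(h)
        vs.append(v.copy())
        as_.append(a.copy())
    return {
        "h": np.array(hs),
        "valence": np.array(vs),
        "arousal": np.array(as_),
        "expressed": expr_mask,
    }
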