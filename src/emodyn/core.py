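"""Deterministic kernel of the emotional-agent model.

Drift functions of the valence/arousal dynamics, their fixed points, and the
expression and participation rules.  Everything here is pure and
deterministic; the stochastic integrator lives in :mod:`emodyn.simulate`.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .params import (
    ArousalParams,
    EmotionState,
    ExpressionParams,
    ParticipationParams,
    ValenceParams,
)

__all__ = [
    "valence_drift",
    "arousal_drift",
    "fixed_point",
    "expression",
    "participation_probability",
    "FixedPointError",
]

DynParams = Union[ValenceParams, ArousalParams]


class FixedPointError(RuntimeError):
    """No stable root of the drift exists inside [-1, 1]."""


def _check_field(h: float) -> float:
    h = float(h)
    if abs(h) > 1.0:
        raise ValueError(f"field charge h={h!r} outside [-1, 1]")
    return h


def valence_drift(v, h: float, p: ValenceParams):
    """Deterministic rate of change of valence (per minute).

    ``-gamma_v (v - b) + h (b0 + b1 v + b2 v^2 + b3 v^3)``: exponential
    relaxation toward the baseline plus a polarity-driven force from the
    field.  Accepts scalar or ndarray ``v`` and ``h``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(v) > 1.0):
        raise ValueError("valence outside [-1, 1]")
    h = np.asarray(h, dtype=float)
    if np.any(np.abs(h) > 1.0):
        raise ValueError("field charge outside [-1, 1]")
    force = h * (p.b0 + p.b1 * v + p.b2 * v**2 + p.b3 * v**3)
    out = -p.gamma_v * (v - p.b) + force
    return out if out.ndim else float(out)


def arousal_drift(a, h: float, p: ArousalParams):
    """Deterministic rate of change of arousal (per minute).

    ``-gamma_a (a - d) + |h| (d0 + d1 a + d2 a^2 + d3 a^3)``: the field
    enters through its absolute value, so emotional content of either
    polarity is equally activating.
    """
    a = np.asarray(a, dtype=float)
    if np.any(np.abs(a) > 1.0):
        raise ValueError("arousal outside [-1, 1]")
    h = np.asarray(h, dtype=float)
    if np.any(np.abs(h) > 1.0):
        raise ValueError("field charge outside [-1, 1]")
    force = np.abs(h) * (p.d0 + p.d1 * a + p.d2 * a**2 + p.d3 * a**3)
    out = -p.gamma_a * (a - p.d) + force
    return out if out.ndim else float(out)


def drift(x, h: float, p: DynParams):
    """Dispatch to the valence or arousal drift based on the parameter type."""
    if isinstance(p, ValenceParams):
        return valence_drift(x, h, p)
    return arousal_drift(x, h, p)


def _drift_poly_coeffs(p: DynParams, h: float) -> np.ndarray:
    # drift(x) = (rate*baseline + g*c0) + (-rate + g*c1) x + g*c2 x^2 + g*c3 x^3
    # with g = h (valence) or |h| (arousal); coefficients in increasing order.
    g = h if p.signed_field else abs(h)
    c0, c1, c2, c3 = p.coeffs
    return np.array(
        [
            p.rate * p.baseline + g * c0,
            -p.rate + g * c1,
            g * c2,
            g * c3,
        ]
    )


def fixed_point(p: DynParams, h: float = 0.0, tol: float = 1e-12) -> float:
    """Stable stationary state of the drift within [-1, 1] nearest the baseline.

    The drift is a cubic polynomial in the state, so the roots are found
    exactly; candidates outside [-1, 1] or with non-negative drift slope
    (unstable or marginal) are discarded, and the surviving root closest to
    the relaxation baseline is polished with Newton steps.

    Raises
    ------
    FixedPointError
        If no stable root lies inside [-1, 1].
    """
    h = _check_field(h)
    coeffs = _drift_poly_coeffs(p, h)
    poly = np.polynomial.Polynomial(coeffs)
    dpoly = poly.deriv()
    roots = poly.roots()
    real = roots[np.abs(roots.imag) < 1e-9].real
    candidates = [
        r for r in real if -1.0 - 1e-12 <= r <= 1.0 + 1e-12 and dpoly(r) < 0
    ]
    if not candidates:
        raise FixedPointError(
            f"no stable root of the drift in [-1, 1] for h={h} "
            f"(real roots at {sorted(real.tolist())})"
        )
    root = min(candidates, key=lambda r: abs(r - p.baseline))
    # Newton polish; np.roots is already near machine precision
    for _ in range(5):
        f, fp = poly(root), dpoly(root)
        if abs(f) < tol or fp == 0:
            break
        root -= f / fp
    root = float(min(1.0, max(-1.0, root)))
    assert abs(poly(root)) < 1e-10 and dpoly(root) < 0
    return root


def expression(state: EmotionState, p: ExpressionParams) -> Optional[float]:
    """Polarity of the post the agent would express, or ``None``.

    Expression is gated by the Heaviside threshold on arousal
    (``Theta[a - tau_expr]`` with ``Theta[0] = 1``, i.e. the rule fires
    exactly at threshold); the expressed polarity is ``f_s(valence)``.
    """
    if state.arousal < p.tau_expr:
        return None
    return float(p.fs(state.valence))


def participation_probability(a, p: ParticipationParams):
    """Intention to participate given arousal: hinge model clipped to [0, 1].

    ``clip(p0 + alpha * a * Theta[a - tau_p], 0, 1)`` — constant baseline
    tendency below the knot, linear growth with arousal above it.
    """
    a = np.asarray(a, dtype=float)
    if np.any(np.abs(a) > 1.0):
        raise ValueError("arousal outside [-1, 1]")
    val = p.p0 + p.alpha * a * (a >= p.tau_p)
    out = np.clip(val, 0.0, 1.0)
    return out if out.ndim else float(out)
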