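"""Parameter containers for the emotional-agent model.

The agent carries a two-dimensional core-affect state: valence ``v`` (degree
of pleasure) and arousal ``a`` (degree of activation), both dimensionless on
[-1, 1].  The online discussion an agent reads carries an emotional charge
``h`` on [-1, 1] (the *field*); in the experimental designs emulated here
``h`` is restricted to {-1, 0, +1}.

Valence and arousal each follow a stochastic relaxation dynamics,

    dv/dt = -gamma_v (v - b) + h  * (b0 + b1 v + b2 v^2 + b3 v^3) + A_v xi(t)
    da/dt = -gamma_a (a - d) + |h|* (d0 + d1 a + d2 a^2 + d3 a^3) + A_a xi(t)

so valence responds to the *polarity* of the field while arousal responds to
the *presence* of emotional content regardless of its sign.  Expression of a
post is gated by an arousal threshold and carries a polarity that is a
function of valence; after writing, arousal (and, for replies written in a
negative state, valence) shrinks proportionally toward zero.

All parameter sets serialize to/from a single flat JSON mapping so a whole
model configuration is one small text file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

__all__ = [
    "EmotionState",
    "ValenceParams",
    "ArousalParams",
    "ExpressionParams",
    "ParticipationParams",
    "ModelParams",
    "FS_KINDS",
    "reference_params",
    "reference_expression_coeffs",
]


def _check_unit_interval(name: str, x: float) -> None:
    if not (-1.0 <= x <= 1.0):
        raise ValueError(f"{name}={x!r} outside [-1, 1]")


@dataclass(frozen=True)
class EmotionState:
    """Core-affect state (valence, arousal), each on [-1, 1]."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        _check_unit_interval("valence", self.valence)
        _check_unit_interval("arousal", self.arousal)


@dataclass(frozen=True)
class ValenceParams:
    """Relaxation + field-coupling parameters of the valence equation.

    gamma_v : relaxation rate toward the baseline ``b`` (per minute, > 0)
    b       : valence baseline on [-1, 1]
    b0..b3  : polynomial field-coupling coefficients multiplying ``h``
    A_v     : white-noise amplitude (>= 0)
    """

    gamma_v: float
    b: float
    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    A_v: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_v <= 0:
            raise ValueError(f"gamma_v must be > 0, got {self.gamma_v!r}")
        if self.A_v < 0:
            raise ValueError(f"A_v must be >= 0, got {self.A_v!r}")
        _check_unit_interval("b", self.b)

    @property
    def baseline(self) -> float:
        return self.b

    @property
    def rate(self) -> float:
        return self.gamma_v

    @property
    def coeffs(self) -> tuple[float, float, float, float]:
        return (self.b0, self.b1, self.b2, self.b3)

    @property
    def noise(self) -> float:
        return self.A_v

    # arousal couples through |h|, valence through signed h
    signed_field: bool = field(default=True, init=False, repr=False)


@dataclass(frozen=True)
class ArousalParams:
    """Relaxation + field-coupling parameters of the arousal equation.

    The field enters through its absolute value |h|: emotional content
    activates regardless of polarity.
    """

    gamma_a: float
    d: float
    d0: float = 0.0
    d1: float = 0.0
    d2: float = 0.0
    d3: float = 0.0
    A_a: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_a <= 0:
            raise ValueError(f"gamma_a must be > 0, got {self.gamma_a!r}")
        if self.A_a < 0:
            raise ValueError(f"A_a must be >= 0, got {self.A_a!r}")
        _check_unit_interval("d", self.d)

    @property
    def baseline(self) -> float:
        return self.d

    @property
    def rate(self) -> float:
        return self.gamma_a

    @property
    def coeffs(self) -> tuple[float, float, float, float]:
        return (self.d0, self.d1, self.d2, self.d3)

    @property
    def noise(self) -> float:
        return self.A_a

    signed_field: bool = field(default=False, init=False, repr=False)


def _fs_identity(v: float) -> float:
    return v


def _fs_sign(v: float) -> float:
    return math.copysign(1.0, v) if v != 0 else 0.0


#: Named valence -> expressed-polarity mappings.  The encoding of subjective
#: valence into text is an open modelling question; the identity is the
#: default and a hard sign readout is provided as a variant.
FS_KINDS: dict[str, Callable[[float], float]] = {
    "identity": _fs_identity,
    "sign": _fs_sign,
}


@dataclass(frozen=True)
class ExpressionParams:
    """Expression rule and feedback-of-expression parameters.

    tau_expr : arousal threshold above which the agent expresses (the
               Heaviside gate fires at the threshold itself)
    fs_kind  : name of the valence->polarity mapping (see ``FS_KINDS``)
    lambda_a : multiplicative arousal shrink applied after writing any post
               (0 = full reset to neutral, 1 = no feedback)
    lambda_v : multiplicative valence shrink applied after *replying* while
               in a negative-valence state (partial mood repair)
    """

    tau_expr: float = 0.0
    fs_kind: str = "identity"
    lambda_a: float = 0.5
    lambda_v: float = 0.5

    def __post_init__(self) -> None:
        _check_unit_interval("tau_expr", self.tau_expr)
        if not (0.0 <= self.lambda_a <= 1.0):
            raise ValueError(f"lambda_a must be in [0, 1], got {self.lambda_a!r}")
        if not (0.0 <= self.lambda_v <= 1.0):
            raise ValueError(f"lambda_v must be in [0, 1], got {self.lambda_v!r}")
        if self.fs_kind not in FS_KINDS:
            raise KeyError(
                f"unknown fs_kind {self.fs_kind!r}; known: {sorted(FS_KINDS)}"
            )

    @property
    def fs(self) -> Callable[[float], float]:
        return FS_KINDS[self.fs_kind]


@dataclass(frozen=True)
class ParticipationParams:
    """Threshold-linear (hinge) model of the intention to participate.

    p(a) = clip(p0 + alpha * a * Theta[a - tau_p], 0, 1)

    p0    : baseline tendency on [0, 1]
    alpha : slope above the knot (>= 0)
    tau_p : arousal knot; distinct from the expression threshold even though
            both play the role of an activation threshold
    """

    p0: float
    alpha: float
    tau_p: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError(f"p0 must be in [0, 1], got {self.p0!r}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha!r}")
        _check_unit_interval("tau_p", self.tau_p)


_FLAT_KEYS = (
    "gamma_v b b0 b1 b2 b3 A_v gamma_a d d0 d1 d2 d3 A_a "
    "tau_expr fs_kind lambda_a lambda_v p0 alpha tau_p"
).split()


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one emotional agent."""

    valence: ValenceParams
    arousal: ArousalParams
    expression: ExpressionParams = ExpressionParams()
    participation: ParticipationParams = ParticipationParams(p0=0.2, alpha=0.4)

    def to_flat_dict(self) -> dict:
        v, a, e, p = self.valence, self.arousal, self.expression, self.participation
        return {
            "gamma_v": v.gamma_v, "b": v.b,
            "b0": v.b0, "b1": v.b1, "b2": v.b2, "b3": v.b3, "A_v": v.A_v,
            "gamma_a": a.gamma_a, "d": a.d,
            "d0": a.d0, "d1": a.d1, "d2": a.d2, "d3": a.d3, "A_a": a.A_a,
            "tau_expr": e.tau_expr, "fs_kind": e.fs_kind,
            "lambda_a": e.lambda_a, "lambda_v": e.lambda_v,
            "p0": p.p0, "alpha": p.alpha, "tau_p": p.tau_p,
        }

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(_FLAT_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(_FLAT_KEYS) - set(d)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(
            valence=ValenceParams(
                gamma_v=d["gamma_v"], b=d["b"],
                b0=d["b0"], b1=d["b1"], b2=d["b2"], b3=d["b3"], A_v=d["A_v"],
            ),
            arousal=ArousalParams(
                gamma_a=d["gamma_a"], d=d["d"],
                d0=d["d0"], d1=d["d1"], d2=d["d2"], d3=d["d3"], A_a=d["A_a"],
            ),
            expression=ExpressionParams(
                tau_expr=d["tau_expr"], fs_kind=d["fs_kind"],
                lambda_a=d["lambda_a"], lambda_v=d["lambda_v"],
            ),
            participation=ParticipationParams(
                p0=d["p0"], alpha=d["alpha"], tau_p=d["tau_p"],
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_flat_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_flat_dict(json.loads(Path(path).read_text()))


def reference_params() -> ModelParams:
    """Point estimates of the dynamics and participation parameters fitted
    to the laboratory reading/writing studies this package emulates.

    Terms dropped by the information-criterion subset selection (the linear
    valence coupling and the quadratic/cubic arousal couplings) are set to
    zero.  The noise amplitudes were never reported; the shipped values are
    this package's calibration, chosen so the event-level regressions on
    synthetic data attain the reported explained-variance regimes
    (R^2 ~ 0.5 for valence, ~ 0.28 for arousal).
    """
    with resources.files("emodyn.data").joinpath("params_paper.json").open() as fh:
        return ModelParams.from_flat_dict(json.load(fh))


def reference_expression_coeffs() -> dict:
    """Logistic-regression coefficients linking pre-writing valence to the
    polarity of the produced post: ``{"pos": {"intercept", "slope"}, "neg":
    {...}}`` where the response is the binary positive/negative-content flag.
    """
    with resources.files("emodyn.data").joinpath(
        "expression_coeffs.json"
    ).open() as fh:
        return json.load(fh)
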