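"""Estimation chain for the valence/arousal dynamics.

The continuous dynamics are estimated on an *event* timescale: each reading
event contributes one observed rate of change, (post - pre) / duration, and
the drift is regressed on the pre-event state and the thread charge.  The
chain is: event deltas -> exhaustive AIC subset selection over the
field-coupling polynomial orders -> nonlinear least squares on the selected
terms -> random-walk Metropolis posterior over the point estimates ->
normality diagnostics of the residuals.

The drift is linear in its parameters at fixed ``h``, so the least-squares
problem has a closed-form solution; it is nevertheless solved through a
general nonlinear least-squares interface so that nonlinear extensions of
the model keep the same entry point.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EventDelta",
    "ModelSpec",
    "FitResult",
    "PosteriorSamples",
    "event_deltas",
    "select_subset",
    "fit_nls",
    "posterior_sample",
    "residual_diagnostics",
    "sturges_bins",
    "binned_rates",
]

_ALL_ORDERS = (0, 1, 2, 3)


def sturges_bins(n: int) -> int:
    """Histogram bin count by Sturges' rule, ``ceil(1 + log2 n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(math.ceil(1.0 + math.log2(n)))


@dataclass(frozen=True)
class EventDelta:
    """One reading event reduced to a regression record."""

    v_pre: float
    a_pre: float
    h: float
    dt_min: float
    dv_rate: float
    da_rate: float


@dataclass(frozen=True)
class ModelSpec:
    """Which field-coupling polynomial orders enter the drift regression.

    The relaxation rate and baseline are always estimated; ``included_orders``
    selects which of the coefficients multiplying h (valence) or |h|
    (arousal) are free, the rest being fixed at zero.
    """

    target: str  # "valence" | "arousal"
    included_orders: frozenset = dc_field(default_factory=lambda: frozenset(_ALL_ORDERS))

    def __post_init__(self) -> None:
        if self.target not in ("valence", "arousal"):
            raise ValueError(f"target must be 'valence' or 'arousal', got {self.target!r}")
        object.__setattr__(self, "included_orders", frozenset(self.included_orders))
        if not self.included_orders <= set(_ALL_ORDERS):
            raise ValueError(f"orders must be a subset of {_ALL_ORDERS}")

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted(self.included_orders))

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.target == "valence":
            return ("gamma_v", "b") + tuple(f"b{k}" for k in self.orders)
        return ("gamma_a", "d") + tuple(f"d{k}" for k in self.orders)


@dataclass
class FitResult:
    """Point estimates and fit quality of one drift regression."""

    spec: ModelSpec
    estimates: dict
    standard_errors: dict
    r_squared: float
    n: int
    residuals: np.ndarray
    loglik: float
    aic: float

    def to_dict(self, include_residuals: bool = False) -> dict:
        out = {
            "target": self.spec.target,
            "included_orders": list(self.spec.orders),
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "r_squared": self.r_squared,
            "n": self.n,
            "loglik": self.loglik,
            "aic": self.aic,
        }
        if include_residuals:
            out["residuals"] = [float(r) for r in self.residuals]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


@dataclass
class PosteriorSamples:
    """Posterior draws for the parameters of one drift regression."""

    samples: dict  # parameter name -> np.ndarray of draws
    acceptance_rate: float
    bin_count: int
    warnings: list = dc_field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "acceptance_rate": self.acceptance_rate,
            "bin_count": self.bin_count,
            "warnings": self.warnings,
            "samples": {k: v.tolist() for k, v in self.samples.items()},
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def event_deltas(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce reading records to per-event rates of change.

    ``dv_rate = (v_post - v_pre) / duration`` and likewise for arousal.
    Records with non-positive duration are dropped with a warning.
    """
    bad = records["duration_min"] <= 0
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} record(s) with non-positive duration",
            stacklevel=2,
        )
        records = records.loc[~bad]
    out = pd.DataFrame(
        {
            "v_pre": records["v_pre"].to_numpy(float),
            "a_pre": records["a_pre"].to_numpy(float),
            "h": records["h"].to_numpy(float),
            "dt_min": records["duration_min"].to_numpy(float),
        }
    )
    out["dv_rate"] = (records["v_post"].to_numpy(float) - out["v_pre"]) / out["dt_min"]
    out["da_rate"] = (records["a_post"].to_numpy(float) - out["a_pre"]) / out["dt_min"]
    return out


def _regression_arrays(deltas: pd.DataFrame, spec: ModelSpec):
    if spec.target == "valence":
        s = deltas["v_pre"].to_numpy(float)
        g = deltas["h"].to_numpy(float)
        y = deltas["dv_rate"].to_numpy(float)
    else:
        s = deltas["a_pre"].to_numpy(float)
        g = np.abs(deltas["h"].to_numpy(float))
        y = deltas["da_rate"].to_numpy(float)
    return s, g, y


def _predict(theta: np.ndarray, s: np.ndarray, g: np.ndarray, orders) -> np.ndarray:
    rate, baseline = theta[0], theta[1]
    force = np.zeros_like(s)
    for coeff, k in zip(theta[2:], orders):
        force += coeff * s**k
    return -rate * (s - baseline) + g * force


def _gaussian_loglik(ssr: float, n: int) -> float:
    sigma2 = max(ssr / n, 1e-30)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_nls(deltas: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Nonlinear least-squares fit of the drift on event rates.

    Minimizes ``sum((observed rate - drift)^2)`` over the relaxation rate,
    baseline and the included field-coupling coefficients; reports R^2,
    residuals, the Gaussian log-likelihood at the MLE error variance, and
    ``AIC = 2k - 2 loglik`` with ``k`` the number of drift parameters.
    """
    orders = spec.orders
    k = 2 + len(orders)
    n = len(deltas)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} events to fit {k} parameters, got {n}")
    s, g, y = _regression_arrays(deltas, spec)

    # OLS warm start in the linearized coordinates: y = c0 + c1 s + sum g s^k
    X = np.column_stack([np.ones_like(s), s] + [g * s**o for o in orders])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for orders {orders} (rank {rank} < {X.shape[1]}); "
            "collinear field-coupling terms"
        )
    c, *_ = np.linalg.lstsq(X, y, rcond=None)
    rate0 = max(-c[1], 1e-3)
    base0 = float(np.clip(c[0] / rate0, -1.0, 1.0))
    x0 = np.concatenate([[rate0, base0], c[2:]])

    res = optimize.least_squares(
        lambda th: _predict(th, s, g, orders) - y, x0, method="lm", xtol=1e-14
    )
    if not res.success:
        raise RuntimeError(f"least-squares solver failed: {res.message}")
    theta = res.x
    resid = y - _predict(theta, s, g, orders)
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    ll = _gaussian_loglik(ssr, n)
    aic = 2.0 * k - 2.0 * ll

    J = res.jac
    dof = max(n - k, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * (ssr / dof)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)

    names = spec.param_names
    return FitResult(
        spec=spec,
        estimates={nm: float(v) for nm, v in zip(names, theta)},
        standard_errors={nm: float(v) for nm, v in zip(names, se)},
        r_squared=r2,
        n=n,
        residuals=resid,
        loglik=ll,
        aic=aic,
    )


def select_subset(deltas: pd.DataFrame, target: str) -> ModelSpec:
    """Exhaustive AIC search over the 16 subsets of field-coupling orders.

    Each candidate keeps the relaxation rate and baseline and frees a subset
    of {0,1,2,3}; the subset with minimal AIC wins, ties resolved toward
    fewer parameters, then lower maximal order.  Candidates whose fit fails
    (e.g. singular designs) are skipped with a warning.
    """
    if len(deltas) < 20:
        raise ValueError(f"need at least 20 events for subset selection, got {len(deltas)}")
    subsets = []
    for mask in range(16):
        sub = frozenset(k for k in _ALL_ORDERS if mask & (1 << k))
        subsets.append(sub)
    subsets.sort(key=lambda sub: (len(sub), max(sub, default=-1), tuple(sorted(sub))))

    best_spec, best_aic = None, math.inf
    for sub in subsets:
        spec = ModelSpec(target=target, included_orders=sub)
        try:
            fit = fit_nls(deltas, spec)
        except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
            warnings.warn(f"skipping subset {sorted(sub)}: {exc}", stacklevel=2)
            continue
        if fit.aic < best_aic - 1e-9:
            best_spec, best_aic = spec, fit.aic
    if best_spec is None:
        raise RuntimeError("every candidate subset failed to fit")
    return best_spec


def posterior_sample(
    deltas: pd.DataFrame,
    spec: ModelSpec,
    n_samples: int = 10_000,
    seed: Optional[int] = None,
    burn_in: int = 2000,
    prior_sd: float = 10.0,
) -> PosteriorSamples:
    """Random-walk Metropolis posterior over the drift parameters.

    Gaussian likelihood with the error scale profiled at its least-squares
    estimate; independent normal(0, ``prior_sd``) priors on every parameter.
    The proposal is adapted during burn-in toward a 20-40% acceptance rate;
    exactly ``n_samples`` post-burn-in draws are returned together with the
    Sturges bin count for histogramming them.
    """
    fit = fit_nls(deltas, spec)  # raises on degenerate data
    s, g, y = _regression_arrays(deltas, spec)
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: observed rates are constant")
    orders = spec.orders
    names = spec.param_names
    theta = np.array([fit.estimates[nm] for nm in names])
    k = len(theta)
    n = len(y)
    sigma2 = max(float(fit.residuals @ fit.residuals) / n, 1e-12)

    def log_post(th: np.ndarray) -> float:
        r = y - _predict(th, s, g, orders)
        return float(-(r @ r) / (2.0 * sigma2) - (th @ th) / (2.0 * prior_sd**2))

    rng = np.random.default_rng(seed)
    scale = np.array(
        [
            fit.standard_errors[nm] if np.isfinite(fit.standard_errors[nm]) else 0.1
            for nm in names
        ]
    )
    scale = np.where(scale > 0, scale, 0.1) * 2.4 / math.sqrt(k)

    lp = log_post(theta)
    accepted_window = 0
    for i in range(burn_in):
        prop = theta + scale * rng.standard_normal(k)
        lp_prop = log_post(prop)
        if math.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted_window += 1
        if (i + 1) % 200 == 0:
            rate = accepted_window / 200.0
            scale = scale * math.exp(rate - 0.30)
            accepted_window = 0

    draws = np.empty((n_samples, k))
    accepted = 0
    for i in range(n_samples):
        prop = theta + scale * rng.standard_normal(k)
        lp_prop = log_post(prop)
        if math.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        draws[i] = theta
    acc = accepted / n_samples
    warn_list = []
    if not (0.05 <= acc <= 0.8):
        warn_list.append(
            f"acceptance rate {acc:.3f} outside [0.05, 0.8] after adaptation"
        )
        warnings.warn(warn_list[-1], stacklevel=2)
    return PosteriorSamples(
        samples={nm: draws[:, j].copy() for j, nm in enumerate(names)},
        acceptance_rate=acc,
        bin_count=sturges_bins(n_samples),
        warnings=warn_list,
    )


def residual_diagnostics(residuals: Sequence[float]) -> tuple[float, float]:
    """Normality diagnostics: (R^2 of a moment-matched normal fit to the
    Sturges-binned residual histogram, Shapiro–Wilk W statistic)."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 8:
        raise ValueError(f"need at least 8 residuals, got {len(r)}")
    sd = r.std()
    if sd == 0:
        raise ValueError("residuals are constant; no scale to fit")
    nb = sturges_bins(len(r))
    hist, edges = np.histogram(r, bins=nb, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = stats.norm.pdf(centers, loc=r.mean(), scale=sd)
    ss_res = float(np.sum((hist - pdf) ** 2))
    ss_tot = float(np.sum((hist - hist.mean()) ** 2))
    normal_fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-sample p-value caveat
        w = float(stats.shapiro(r).statistic)
    return normal_fit_r2, w


def binned_rates(
    deltas: pd.DataFrame, target: str, max_exact_levels: int = 15
) -> pd.DataFrame:
    """Mean observed rate per pre-state bin and field charge (figure data).

    When the pre-states take few distinct values (Likert-quantized reports)
    each level is its own bin; otherwise pre-states are cut into
    Sturges-count equal-width bins.  Returns columns
    ``(h, state, mean_rate, se_rate, n)``.
    """
    spec_col = "v_pre" if target == "valence" else "a_pre"
    rate_col = "dv_rate" if target == "valence" else "da_rate"
    df = deltas[["h", spec_col, rate_col]].rename(
        columns={spec_col: "state", rate_col: "rate"}
    )
    if df["state"].nunique() > max_exact_levels:
        nb = sturges_bins(len(df))
        bins = pd.cut(df["state"], bins=nb)
        df = df.assign(state=bins.map(lambda iv: iv.mid).astype(float))
    grouped = df.groupby(["h", "state"], observed=True)["rate"]
    out = grouped.agg(
        mean_rate="mean",
        se_rate=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="size",
    ).reset_index()
    return out
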