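"""Event deltas, AIC subset selection, NLS, posterior, residual diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emodyn.core import valence_drift
from emodyn.fit_dynamics import (
    ModelSpec,
    binned_rates,
    event_deltas,
    fit_nls,
    posterior_sample,
    residual_diagnostics,
    select_subset,
    sturges_bins,
)
from emodyn.params import ValenceParams
from emodyn.recovery import AROUSAL_ORDERS, VALENCE_ORDERS
from emodyn.synth import ReadingStudyDesign, generate_reading_study


def _records(v_pre, v_post, dt, h=0.0):
    n = len(v_pre)
    return pd.DataFrame(
        {
            "v_pre": v_pre,
            "v_post": v_post,
            "a_pre": np.zeros(n),
            "a_post": np.zeros(n),
            "h": np.full(n, h),
            "duration_min": dt,
        }
    )


class TestEventDeltas:
    def test_rate_arithmetic(self):
        df = _records([0.2, 0.1], [0.5, 0.1], [1.0, 2.0])
        out = event_deltas(df)
        assert out["dv_rate"].tolist() == pytest.approx([0.3, 0.0])

    def test_nonpositive_duration_dropped_with_warning(self):
        df = _records([0.2, 0.1], [0.5, 0.1], [1.0, 0.0])
        with pytest.warns(UserWarning, match="non-positive duration"):
            out = event_deltas(df)
        assert len(out) == 1

    def test_noise_free_generation_convention(self, params, noise_free_design):
        deltas = event_deltas(generate_reading_study(noise_free_design, params))
        np.testing.assert_allclose(
            deltas["dv_rate"],
            valence_drift(deltas["v_pre"], deltas["h"], params.valence),
            atol=1e-12,
        )


class TestFitNLS:
    def test_noise_free_recovery_to_machine_precision(self, params, noise_free_design):
        deltas = event_deltas(generate_reading_study(noise_free_design, params))
        fit = fit_nls(deltas, ModelSpec("valence", VALENCE_ORDERS))
        truth = params.valence
        for name, val in (
            ("gamma_v", truth.gamma_v), ("b", truth.b),
            ("b0", truth.b0), ("b2", truth.b2), ("b3", truth.b3),
        ):
            assert fit.estimates[name] == pytest.approx(val, abs=1e-6)
        afit = fit_nls(deltas, ModelSpec("arousal", AROUSAL_ORDERS))
        assert afit.estimates["gamma_a"] == pytest.approx(params.arousal.gamma_a, abs=1e-6)
        assert afit.estimates["d1"] == pytest.approx(params.arousal.d1, abs=1e-6)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        gamma=st.floats(0.1, 1.0),
        b=st.floats(-0.3, 0.3),
        b0=st.floats(-0.2, 0.2),
        b2=st.floats(-0.2, 0.2),
    )
    def test_zero_noise_identification_over_parameter_space(self, gamma, b, b0, b2):
        """Any admissible generating parameter set is recovered exactly from
        exact rates (the regression is the generating model)."""
        rng = np.random.default_rng(99)
        p = ValenceParams(gamma_v=gamma, b=b, b0=b0, b2=b2)
        v = rng.uniform(-0.8, 0.8, 300)
        h = rng.choice([-1.0, 0.0, 1.0], 300)
        rates = valence_drift(v, h, p)
        deltas = pd.DataFrame(
            {"v_pre": v, "a_pre": v, "h": h, "dt_min": 1.0, "dv_rate": rates, "da_rate": rates}
        )
        fit = fit_nls(deltas, ModelSpec("valence", frozenset({0, 2})))
        assert fit.estimates["gamma_v"] == pytest.approx(gamma, abs=1e-6)
        assert fit.estimates["b"] == pytest.approx(b, abs=1e-5)
        assert fit.estimates["b0"] == pytest.approx(b0, abs=1e-6)
        assert fit.estimates["b2"] == pytest.approx(b2, abs=1e-6)

    def test_r_squared_matches_hand_decomposition(self):
        # three points, intercept-plus-relaxation model fitted by hand
        deltas = pd.DataFrame(
            {
                "v_pre": [-1.0, 0.0, 1.0],
                "a_pre": [0.0] * 3,
                "h": [0.0] * 3,
                "dt_min": [1.0] * 3,
                "dv_rate": [0.5, 0.1, -0.5],
                "da_rate": [0.0] * 3,
            }
        )
        fit = fit_nls(deltas, ModelSpec("valence", frozenset()))
        # OLS line: slope -0.5, intercept 0.0333...; SSR = sum r^2
        pred = 0.1 / 3 - 0.5 * deltas["v_pre"]
        ssr = float(((deltas["dv_rate"] - pred) ** 2).sum())
        sst = float(((deltas["dv_rate"] - deltas["dv_rate"].mean()) ** 2).sum())
        assert fit.r_squared == pytest.approx(1 - ssr / sst, abs=1e-9)

    def test_aic_formula(self, params, noise_free_design):
        deltas = event_deltas(
            generate_reading_study(
                ReadingStudyDesign(n_participants=10, seed=12), params
            )
        )
        fit = fit_nls(deltas, ModelSpec("valence", frozenset({0})))
        k = 3  # gamma, baseline, one coupling coefficient
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)

    def test_rank_deficiency_reported(self):
        deltas = pd.DataFrame(
            {
                "v_pre": np.zeros(30),
                "a_pre": np.zeros(30),
                "h": np.zeros(30),
                "dt_min": np.ones(30),
                "dv_rate": np.zeros(30),
                "da_rate": np.zeros(30),
            }
        )
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            fit_nls(deltas, ModelSpec("valence", frozenset({0, 1})))


class TestSelectSubset:
    def test_requires_minimum_events(self):
        deltas = pd.DataFrame(
            {
                "v_pre": np.zeros(5), "a_pre": np.zeros(5), "h": np.zeros(5),
                "dt_min": np.ones(5), "dv_rate": np.zeros(5), "da_rate": np.zeros(5),
            }
        )
        with pytest.raises(ValueError, match="at least 20"):
            select_subset(deltas, "valence")

    def test_strong_term_always_kept(self, params):
        """With the reference generating model the constant coupling term
        (the dominant field effect) survives selection."""
        design = ReadingStudyDesign(seed=21)
        deltas = event_deltas(generate_reading_study(design, params))
        for target in ("valence", "arousal"):
            spec = select_subset(deltas, target)
            assert 0 in spec.included_orders


class TestPosterior:
    def test_mean_agrees_with_nls_and_sturges_count(self, params):
        design = ReadingStudyDesign(n_participants=30, seed=31)
        deltas = event_deltas(generate_reading_study(design, params))
        spec = ModelSpec("valence", VALENCE_ORDERS)
        fit = fit_nls(deltas, spec)
        post = posterior_sample(deltas, spec, n_samples=10_000, seed=2, burn_in=1500)
        assert post.n_samples == 10_000
        assert post.bin_count == 15
        assert 0.05 <= post.acceptance_rate <= 0.8
        for name in ("gamma_v", "b0"):
            draws = post.samples[name]
            se = draws.std(ddof=1) / math.sqrt(_ess(draws))
            assert abs(draws.mean() - fit.estimates[name]) < 3 * max(se, 1e-4)

    def test_degenerate_data_raises(self):
        deltas = pd.DataFrame(
            {
                "v_pre": np.full(50, 0.3), "a_pre": np.full(50, 0.3),
                "h": np.zeros(50), "dt_min": np.ones(50),
                "dv_rate": np.full(50, 0.1), "da_rate": np.full(50, 0.1),
            }
        )
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            posterior_sample(deltas, ModelSpec("valence", frozenset({0})), n_samples=100)


def _ess(x: np.ndarray) -> float:
    """Crude effective sample size from the lag-1 autocorrelation."""
    x = x - x.mean()
    rho = float(np.dot(x[:-1], x[1:]) / np.dot(x, x))
    rho = min(max(rho, 0.0), 0.999)
    return len(x) * (1 - rho) / (1 + rho)


class TestResidualDiagnostics:
    def test_gaussian_sample_scores_high(self):
        r = np.random.default_rng(0).standard_normal(10_000)
        r2, w = residual_diagnostics(r)
        assert r2 > 0.95
        assert w > 0.99

    def test_bimodal_sample_scores_low(self):
        rng = np.random.default_rng(1)
        r = np.concatenate([rng.normal(-1, 0.05, 5000), rng.normal(1, 0.05, 5000)])
        r2, _ = residual_diagnostics(r)
        assert r2 < 0.5

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            residual_diagnostics(np.ones(100))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            residual_diagnostics([0.1, -0.2, 0.3])


class TestBinnedRates:
    def test_quantized_levels_bin_exactly_and_symmetrically(self, params):
        design = ReadingStudyDesign(n_participants=40, quantize=True, seed=8)
        deltas = event_deltas(generate_reading_study(design, params))
        out = binned_rates(deltas, "arousal")
        assert set(out.columns) == {"h", "state", "mean_rate", "se_rate", "n"}
        assert set(out["h"].unique()) <= {-1.0, 0.0, 1.0}
        assert out["n"].sum() == len(deltas)
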