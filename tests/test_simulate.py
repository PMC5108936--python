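"""Stochastic integrator, session simulation, feedback, community loop."""

import numpy as np
import pytest

from emodyn.params import (
    ArousalParams,
    EmotionState,
    ExpressionParams,
    ModelParams,
    ValenceParams,
)
from emodyn.simulate import (
    ThreadStimulus,
    apply_expression_feedback,
    simulate_community,
    simulate_session,
    step,
)


def _params(A_v=0.0, A_a=0.0, **expr):
    return ModelParams(
        valence=ValenceParams(gamma_v=0.367, b=0.056, b0=0.14, b2=0.057, b3=-0.047, A_v=A_v),
        arousal=ArousalParams(gamma_a=0.414, d=-0.442, d0=0.178, d1=0.14469, A_a=A_a),
        expression=ExpressionParams(**expr),
    )


class TestStep:
    def test_fixed_point_is_stationary_without_noise(self):
        p = _params()
        s = EmotionState(p.valence.b, p.arousal.d)
        out = step(s, 0.0, 0.5, p, np.random.default_rng(0))
        assert out.valence == pytest.approx(s.valence)
        assert out.arousal == pytest.approx(s.arousal)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            step(EmotionState(0, 0), 0.0, 0.0, _params(), np.random.default_rng(0))

    def test_matches_exponential_relaxation(self):
        """Zero noise, h=0: v(t) = b + (v0-b) exp(-gamma t) up to O(dt)."""
        p = _params()
        rng = np.random.default_rng(0)
        dt, T = 0.01, 5.0
        state = EmotionState(1.0, p.arousal.d)
        for _ in range(int(T / dt)):
            state = step(state, 0.0, dt, p, rng)
        exact = p.valence.b + (1.0 - p.valence.b) * np.exp(-p.valence.gamma_v * T)
        assert state.valence == pytest.approx(exact, abs=5e-3)

    def test_integrator_error_halves_with_dt(self):
        p = _params()
        rng = np.random.default_rng(0)

        def max_err(dt):
            state, t, worst = EmotionState(1.0, p.arousal.d), 0.0, 0.0
            for _ in range(int(2.0 / dt)):
                state = step(state, 0.0, dt, p, rng)
                t += dt
                exact = p.valence.b + (1.0 - p.valence.b) * np.exp(-p.valence.gamma_v * t)
                worst = max(worst, abs(state.valence - exact))
            return worst

        e1, e2 = max_err(0.02), max_err(0.01)
        assert e2 < e1
        assert e2 / e1 == pytest.approx(0.5, abs=0.15)

    def test_long_run_average_near_baseline(self):
        """Monte-Carlo: with noise and h=0 the time-average of v sits at b."""
        p = _params(A_v=0.1, A_a=0.1)
        rng = np.random.default_rng(42)
        state = EmotionState(p.valence.b, p.arousal.d)
        total, n = 0.0, 100_000
        for _ in range(n):
            state = step(state, 0.0, 0.05, p, rng)
            total += state.valence
        # stationary sd of the OU process is A/sqrt(2 gamma) ~ 0.12
        assert total / n == pytest.approx(p.valence.b, abs=0.02)

    def test_states_stay_in_box_under_huge_noise(self):
        p = _params(A_v=5.0, A_a=5.0)
        rng = np.random.default_rng(1)
        state = EmotionState(0.0, 0.0)
        for _ in range(200):
            state = step(state, 1.0, 0.1, p, rng)
            assert -1 <= state.valence <= 1 and -1 <= state.arousal <= 1


class TestSession:
    def test_empty_thread_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(EmotionState(0, 0), [], _params())

    def test_neutral_threads_decay_toward_baselines(self):
        p = _params()
        threads = [ThreadStimulus(0.0, 2.0)] * 6
        traj = simulate_session(EmotionState(0.9, 0.9), threads, p, seed=0)
        v = traj.reports["valence"].to_numpy()
        a = traj.reports["arousal"].to_numpy()
        assert np.all(np.diff(v) < 0) and v[-1] > p.valence.b
        assert np.all(np.diff(a) < 0) and a[-1] > p.arousal.d

    def test_positive_thread_raises_valence_from_neutral(self):
        p = _params()
        traj = simulate_session(
            EmotionState(0.0, 0.0), [ThreadStimulus(1.0, 2.0)], p, seed=0
        )
        assert traj.reports["valence"].iloc[0] > 0.0

    def test_arousal_blind_to_field_sign(self):
        p = _params()
        pos = simulate_session(EmotionState(0, 0), [ThreadStimulus(1.0, 2.0)], p, seed=0)
        neg = simulate_session(EmotionState(0, 0), [ThreadStimulus(-1.0, 2.0)], p, seed=0)
        assert pos.reports["arousal"].iloc[0] == pytest.approx(
            neg.reports["arousal"].iloc[0]
        )

    def test_identical_seed_identical_trajectory(self):
        p = _params(A_v=0.3, A_a=0.3)
        threads = [ThreadStimulus(h, 1.5) for h in (1, -1, 0)]
        t1 = simulate_session(EmotionState(0, 0), threads, p, seed=11)
        t2 = simulate_session(EmotionState(0, 0), threads, p, seed=11)
        np.testing.assert_array_equal(t1.valence, t2.valence)
        np.testing.assert_array_equal(t1.arousal, t2.arousal)

    def test_emotional_threads_raise_arousal_from_baseline(self):
        """From rest, reading charged content activates; the session report
        pattern follows each thread's polarity for valence."""
        p = _params()
        threads = [ThreadStimulus(1.0, 2.0), ThreadStimulus(-1.0, 2.0)]
        traj = simulate_session(
            EmotionState(p.valence.b, p.arousal.d), threads, p, seed=0
        )
        assert traj.reports["arousal"].iloc[0] > p.arousal.d
        assert traj.reports["valence"].iloc[0] > p.valence.b
        assert traj.reports["valence"].iloc[1] < traj.reports["valence"].iloc[0]

    def test_csv_roundtrip_header_records_seed(self, tmp_path):
        p = _params()
        traj = simulate_session(EmotionState(0, 0), [ThreadStimulus(0, 1.0)], p, seed=9)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        text = path.read_text()
        assert text.startswith("# seed=9\n")
        assert "time_min,valence,arousal,h,expressed" in text


class TestFeedback:
    def test_zero_arousal_preserved(self):
        p = ExpressionParams(lambda_a=0.5)
        out = apply_expression_feedback(EmotionState(0.2, 0.0), "first", p)
        assert out.arousal == 0.0

    def test_full_reset_limit(self):
        # lambda_a = 0 reproduces the hard reset-to-zero hypothesis
        p = ExpressionParams(lambda_a=0.0)
        out = apply_expression_feedback(EmotionState(0.2, 0.9), "first", p)
        assert out.arousal == 0.0

    def test_proportional_shrink(self):
        p = ExpressionParams(lambda_a=0.5)
        out = apply_expression_feedback(EmotionState(0.2, 0.8), "first", p)
        assert out.arousal == pytest.approx(0.4)

    def test_negative_arousal_rises_toward_zero(self):
        p = ExpressionParams(lambda_a=0.5)
        out = apply_expression_feedback(EmotionState(0.2, -0.8), "first", p)
        assert out.arousal == pytest.approx(-0.4)

    def test_reply_repairs_negative_valence_only(self):
        p = ExpressionParams(lambda_a=0.5, lambda_v=0.5)
        reply = apply_expression_feedback(EmotionState(-0.6, 0.2), "reply", p)
        assert reply.valence == pytest.approx(-0.3)
        first = apply_expression_feedback(EmotionState(-0.6, 0.2), "first", p)
        assert first.valence == pytest.approx(-0.6)
        pos = apply_expression_feedback(EmotionState(0.6, 0.2), "reply", p)
        assert pos.valence == pytest.approx(0.6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(KeyError):
            apply_expression_feedback(EmotionState(0, 0), "retweet", ExpressionParams())


class TestCommunity:
    def test_zero_gain_field_frozen(self):
        p = _params(A_v=0.1, A_a=0.1, tau_expr=0.0)
        out = simulate_community(
            5, p, field_decay=0.9, field_gain=0.0, steps=20,
            rng=np.random.default_rng(0), h0=0.5,
        )
        assert np.allclose(out["h"], 0.5 * 0.9 ** np.arange(21))

    def test_silent_agents_geometric_field_decay(self):
        # baseline arousal below the expression threshold, zero noise
        p = _params(tau_expr=0.5)
        out = simulate_community(
            3, p, field_decay=0.8, field_gain=0.3, steps=15,
            rng=np.random.default_rng(0), h0=1.0,
        )
        assert not out["expressed"].any()
        assert np.allclose(out["h"], 0.8 ** np.arange(16))

    def test_forced_expression_field_converges_to_geometric_sum(self):
        """One agent pinned at positive valence expressing every step drives
        h toward gain * v / (1 - decay), the geometric-series limit."""
        decay, gain = 0.5, 0.4
        # tau_expr at -1 keeps the gate always open; no noise, no dynamics drift
        p = ModelParams(
            valence=ValenceParams(gamma_v=1.0, b=0.6, b0=0.0),
            arousal=ArousalParams(gamma_a=1.0, d=0.2, d0=0.0),
            expression=ExpressionParams(tau_expr=-1.0, lambda_a=1.0),
        )
        out = simulate_community(
            1, p, field_decay=decay, field_gain=gain, steps=300,
            rng=np.random.default_rng(0), dt=0.01,
        )
        v_final = out["valence"][-1, 0]
        expected = gain * v_final / (1 - decay)
        assert out["h"][-1] == pytest.approx(expected, abs=0.02)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            simulate_community(1, _params(), field_decay=1.2, field_gain=0.1, steps=1)
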