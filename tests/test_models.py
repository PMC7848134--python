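import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import revlearn as rl
from revlearn.models import _hgf_step, THETA_FIXED

# frozen from a 30-digit arbitrary-precision evaluation
LOGISTIC_2_98 = 0.951662371280094790770938881003
INV_1_PLUS_E = 0.268941421369995120748840758178


class TestLogisticSoftmax:
    def test_logistic_values(self):
        assert rl.logistic(0.0) == 0.5
        assert rl.logistic(2.98) == pytest.approx(LOGISTIC_2_98, abs=1e-14)
        assert rl.logistic(800.0) == 1.0 and rl.logistic(-800.0) == 0.0

    def test_softmax_symmetry_and_noise_limit(self):
        assert rl.softmax_prob(0.3, 0.3, 7.7) == 0.5
        assert rl.softmax_prob(12.0, -3.0, 0.0) == 0.5

    def test_softmax_at_childrens_mean_beta(self):
        # value difference 0.5 at beta = 5.96 -> logistic(2.98)
        assert rl.softmax_prob(0.75, 0.25, 5.96) == pytest.approx(
            LOGISTIC_2_98, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0, 30))
    def test_softmax_normalisation(self, va, vb, beta):
        p = rl.softmax_prob(va, vb, beta)
        q = rl.softmax_prob(vb, va, beta)
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestRW:
    @pytest.mark.parametrize("v,chosen,r,alpha,exp_delta,exp_v", [
        ((0.5, 0.5), "A", 1, 0.2, 0.5, (0.6, 0.4)),
        ((1.0, 0.0), "A", 1, 0.3, 0.0, (1.0, 0.0)),
        ((0.6, 0.4), "A", 0, 0.5, -0.6, (0.3, 0.7)),
    ])
    def test_update_arithmetic(self, v, chosen, r, alpha, exp_delta, exp_v):
        state, delta = rl.rw_update(rl.RWState(*v), chosen, r, alpha)
        assert delta == pytest.approx(exp_delta)
        assert (state.v_a, state.v_b) == pytest.approx(exp_v)

    @given(st.lists(st.tuples(st.sampled_from("AB"), st.integers(0, 1)),
                    min_size=1, max_size=60),
           st.floats(0.01, 0.99))
    def test_value_sum_conserved_exactly(self, trials, alpha):
        state = rl.RWState()
        total0 = state.v_a + state.v_b
        for chosen, r in trials:
            state, _ = rl.rw_update(state, chosen, r, alpha)
            assert state.v_a + state.v_b == pytest.approx(total0, abs=1e-12)


class TestHGFStep:
    def test_prediction_at_neutral_belief(self):
        beliefs = rl.hgf_predict(rl.HGFState(), rl.HGFParams(omega=0, beta=1))
        assert beliefs.s_hat == 0.5
        assert beliefs.pi_hat_1 == pytest.approx(4.0)

    def test_prediction_precision_level2(self):
        state = rl.HGFState(mu2=0, sigma2=1, mu3=1, sigma3=1)
        beliefs = rl.hgf_predict(state, rl.HGFParams(omega=0, beta=1))
        assert beliefs.pi_hat_2 == pytest.approx(1 / (1 + math.e), abs=1e-12)

    def test_vanishing_phasic_volatility_limit(self):
        state = rl.HGFState(mu2=0.3, sigma2=0.4, mu3=-12, sigma3=1)
        beliefs = rl.hgf_predict(state, rl.HGFParams(omega=-20, beta=1))
        assert beliefs.pi_hat_2 == pytest.approx(1 / 0.4, rel=1e-6)

    def test_zero_prediction_error_leaves_mu2(self):
        # engineered so that reward exactly equals the prediction
        state = rl.HGFState(mu2=0.0, sigma2=0.3, mu3=-4, sigma3=1)
        params = rl.HGFParams(omega=0.0, beta=1.0)
        beliefs = rl.hgf_predict(state, params)
        new = rl.hgf_update(state, beliefs, reward=0.5, params=params)
        assert beliefs.delta1 == 0.0
        assert new.mu2 == state.mu2

    def test_update_fills_beliefs(self):
        state = rl.HGFState()
        params = rl.HGFParams(omega=-1.0, beta=2.0)
        beliefs = rl.hgf_predict(state, params)
        new = rl.hgf_update(state, beliefs, reward=1, params=params)
        assert beliefs.delta1 == pytest.approx(0.5)
        assert beliefs.learning_rate > 0
        assert new.sigma2 > 0 and new.sigma3 > 0
        assert new.mu2 == pytest.approx(
            state.mu2 + beliefs.learning_rate * beliefs.delta1)

    def test_sigma2_two_printed_forms_agree(self, operating_states):
        """sigma2 = pihat1/(pihat2*pihat1 + 1) == 1/(pihat2 + 1/pihat1)."""
        rng = np.random.default_rng(4)
        for mu2, s2, mu3 in rng.permutation(operating_states)[:200]:
            state = rl.HGFState(mu2=mu2, sigma2=s2, mu3=mu3, sigma3=1.0)
            b = rl.hgf_predict(state, rl.HGFParams(omega=0.5, beta=1))
            ratio = b.pi_hat_1 / (b.pi_hat_2 * b.pi_hat_1 + 1.0)
            recip = 1.0 / (b.pi_hat_2 + 1.0 / b.pi_hat_1)
            assert ratio == pytest.approx(recip, rel=1e-13)

    def test_one_step_matches_grid_laplace_oracle(self, operating_states):
        """The precision-weighted update lands on the grid-located posterior
        mode of p(x2 | R) to within 1e-2 across 100 operating states."""
        rng = np.random.default_rng(0)
        idx = rng.choice(len(operating_states), 100, replace=False)
        for i in idx:
            mu2, s2, mu3 = operating_states[i]
            omega = float(rng.uniform(-1.0, 1.5))
            u = float(rng.integers(2))
            mu2_new = _hgf_step(mu2, s2, mu3, 1.0, u, omega,
                                THETA_FIXED, 1.0)[0]
            var = s2 + math.exp(mu3 + omega)
            x = np.linspace(mu2 - 10 * math.sqrt(var),
                            mu2 + 10 * math.sqrt(var), 80001)
            log_post = -(x - mu2) ** 2 / (2 * var) + np.where(
                u > 0, -np.log1p(np.exp(-x)), -np.log1p(np.exp(x)))
            mode = x[np.argmax(log_post)]
            assert abs(mu2_new - mode) < 1e-2

    def test_frozen_level3_under_tiny_meta_volatility(self):
        """theta -> -inf freezes mu3 near its start: the model degenerates
        toward a single fixed-volatility learner."""
        rng = np.random.default_rng(1)
        outcomes = rng.integers(2, size=240).astype(float)
        missed = np.zeros(240, dtype=bool)
        traj = rl.run_hgf_trajectory(outcomes, missed, omega=0.5, theta=-30.0)
        assert np.max(np.abs(traj["mu3"] - traj["mu3"][0])) < 0.05

    def test_learning_rate_monotone_in_omega(self):
        """Mean per-trial sigma2 is non-decreasing in omega on a fixed
        feedback sequence, omega grid {-3..2}."""
        rng = np.random.default_rng(2)
        outcomes = rng.integers(2, size=200).astype(float)
        missed = np.zeros(200, dtype=bool)
        means = [np.nanmean(rl.run_hgf_trajectory(outcomes, missed,
                                                  omega=om)["learning_rate"])
                 for om in range(-3, 3)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_kappa_is_pinned(self):
        with pytest.raises(ValueError):
            rl.HGFParams(omega=0, beta=1, kappa=2.0)


class TestSimulateAgent:
    def test_same_seed_same_log(self, task_config):
        params = rl.HGFParams(omega=0.5, beta=5.0)
        a = rl.simulate_agent("hgf_fixed_theta", params, task_config, seed=5)
        b = rl.simulate_agent("hgf_fixed_theta", params, task_config, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_exploiting_agent_beats_noise_agent(self, task_config):
        """A high-beta agent's overall error rate is strictly below the
        ~50% of a beta=0 (coin-flip) agent, over 20 runs each."""
        def mean_err(beta, seeds):
            rates = []
            for s in seeds:
                df = rl.simulate_agent(
                    "hgf_fixed_theta", rl.HGFParams(omega=1.2, beta=beta),
                    task_config, seed=s)
                rates.append(1.0 - df["correct"].mean())
            return np.mean(rates)
        assert mean_err(15.0, range(20)) < mean_err(0.0, range(100, 120))

    def test_hgf_value_mapping(self, hgf_run):
        """The softmax sees V_A = s(mu2hat), V_B = 1 - V_A: the recorded
        s_hat is the prediction, i.e. the sigmoid of the previous mu2."""
        s_hat = hgf_run["s_hat"].to_numpy()
        mu2 = hgf_run["mu2"].to_numpy()
        expect = np.concatenate([[0.5], 1 / (1 + np.exp(-mu2[:-1]))])
        assert np.allclose(s_hat, expect, atol=1e-8)

    def test_rw_agent_runs_and_conserves(self, task_config):
        df = rl.simulate_agent("rw", rl.RWParams(alpha=0.3, beta=4.0),
                               task_config, seed=2)
        assert len(df) >= 30
        assert df["feedback"].isin((0, 1)).all()

    def test_unknown_model_rejected(self, task_config):
        with pytest.raises(ValueError):
            rl.simulate_agent("q_learning", rl.RWParams(0.1, 1.0),
                              task_config, seed=0)

    def test_misses_skip_updates(self):
        cfg = rl.TaskConfig(miss_prob=0.2)
        df = rl.simulate_agent("hgf_fixed_theta",
                               rl.HGFParams(omega=0.3, beta=5.0), cfg, seed=8)
        missed = df["missed"].to_numpy(dtype=bool)
        assert missed.any()
        assert df.loc[missed, "learning_rate"].isna().all()
        assert df.loc[missed, "mu2"].isna().all()  # no update was applied
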