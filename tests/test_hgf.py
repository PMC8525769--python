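import math

import numpy as np
import pytest

from dualhgf.hgf import (
    RwParameters,
    StreamParameters,
    combine_beliefs,
    filter_trajectory,
    predict_nonsocial,
    predict_social,
    recency_bias,
    rw_trajectory,
    update_level2,
)
from dualhgf.task import TaskConfig, generate_bets, generate_stimulus_sequence


class TestRecencyBias:
    def test_balanced_image_gives_zero(self):
        assert recency_bias(50) == 0.0

    def test_extrema(self):
        assert recency_bias(100) == 1.0
        assert recency_bias(0) == -1.0

    def test_linearity(self):
        assert recency_bias(75) == 0.5

    @pytest.mark.parametrize("pct", [-1, 100.5, 200])
    def test_out_of_range_rejected(self, pct):
        with pytest.raises(ValueError):
            recency_bias(pct)


class TestPredictions:
    def test_social_symmetry_at_zero(self):
        for eta, omega in [(0.1, 0.1), (1.0, 2.0), (5.0, 0.3)]:
            assert predict_social(0.0, eta, omega) == 0.5

    def test_social_hand_value(self):
        # eta=1, omega=2, mu2=1 -> sigmoid(2)
        assert predict_social(1.0, 1.0, 2.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-12
        )

    def test_social_saturation(self):
        assert predict_social(1e6, 1.0, 1.0) == pytest.approx(1.0)

    def test_social_requires_positive_params(self):
        with pytest.raises(ValueError):
            predict_social(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            predict_social(0.0, 1.0, -1.0)

    def test_nonsocial_symmetry(self):
        assert predict_nonsocial(0.0, 0.0) == 0.5

    def test_nonsocial_cancellation(self):
        assert predict_nonsocial(0.5, -0.5) == 0.5

    def test_nonsocial_hand_value(self):
        assert predict_nonsocial(1.0, 1.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-12
        )

    def test_nonsocial_bias_range_enforced(self):
        with pytest.raises(ValueError):
            predict_nonsocial(0.0, 1.5)


class TestUpdateLevel2:
    def test_hand_evaluated_update(self):
        st = update_level2(0.0, 1.0, 0.5, 1.0, 1.0)
        assert st.pi2_hat == pytest.approx(0.5)
        assert st.pi1_hat == pytest.approx(4.0)
        assert st.pi2 == pytest.approx(0.75)
        assert st.mu2 == pytest.approx(0.5 / 0.75)
        assert st.sigma2 == pytest.approx(1.0 / 0.75)

    def test_zero_prediction_error_keeps_mean(self):
        st = update_level2(0.3, 1.0, 0.5, 0.5, 0.5)
        assert st.delta1 == 0.0
        assert st.mu2 == 0.3
        # posterior variance still contracts below the predicted variance
        assert st.sigma2 < 1.0 + 0.5

    def test_update_magnitude_monotone_in_omega(self):
        deltas = [
            abs(update_level2(0.0, 1.0, 0.5, 1.0, w).mu2)
            for w in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(a < b for a, b in zip(deltas, deltas[1:]))

    def test_extreme_prediction_clipped(self):
        st = update_level2(0.0, 1.0, 1.0, 0.0, 1.0)
        assert np.isfinite(st.mu2)
        assert np.isfinite(st.pi1_hat)

    def test_input_domain_enforced(self):
        with pytest.raises(ValueError):
            update_level2(0.0, 1.0, 0.5, 1.5, 1.0)


class TestCombineBeliefs:
    def test_agreeing_streams(self):
        b, a = combine_beliefs(0.5, 0.5, 1)
        assert b == 0.5 and a == 0.5

    def test_hand_value(self):
        # pi_s = 4 at 0.5, pi_ns = 1/0.09 at 0.9
        b, a = combine_beliefs(0.5, 0.9, 1)
        expect = (4 * 0.5 + (1 / 0.09) * 0.9) / (4 + 1 / 0.09)
        assert b == pytest.approx(expect, abs=1e-12)
        assert a == 0.9

    def test_equal_precisions_give_mean(self):
        # beliefs p and 1-p have identical binomial precision
        b, _ = combine_beliefs(0.3, 0.7, 1)
        assert b == pytest.approx(0.5, abs=1e-12)

    def test_agreement_space_mapping(self):
        _, a_scene = combine_beliefs(0.5, 0.8, 1)
        _, a_face = combine_beliefs(0.5, 0.8, 0)
        assert a_scene == 0.8
        assert a_face == pytest.approx(0.2)

    def test_convexity(self, rng):
        for _ in range(200):
            s, ns = rng.uniform(0.01, 0.99, size=2)
            b, a = combine_beliefs(s, ns, int(rng.integers(2)))
            assert min(s, a) - 1e-12 <= b <= max(s, a) + 1e-12


def _oracle_trajectory(params_s, params_ns, trials):
    """Straight-line re-implementation of the printed equations, kept
    deliberately independent of the package's filtering loop."""
    n = trials.n_trials
    mu2_s, sig_s = params_s.mu2_0, params_s.sigma2_0
    mu2_ns, sig_ns = params_ns.mu2_0, params_ns.sigma2_0
    b_out = np.empty(n)
    mu2s_out = np.empty(n)
    mu2ns_out = np.empty(n)
    for t in range(n):
        bias = 0.0 if t == 0 else (trials.scene_pct[t - 1] - 50.0) / 50.0
        m1s = 1.0 / (1.0 + math.exp(-params_s.eta * params_s.omega * mu2_s))
        m1ns = 1.0 / (1.0 + math.exp(-(mu2_ns + bias)))
        a = m1ns if trials.bet_direction[t] == 1 else 1.0 - m1ns
        ps = 1.0 / (m1s * (1.0 - m1s))
        pa = 1.0 / (a * (1.0 - a))
        b_out[t] = (ps * m1s + pa * a) / (ps + pa)
        # social update
        p2h = 1.0 / (sig_s + params_s.omega)
        p2 = p2h + m1s * (1.0 - m1s)
        mu2_s = mu2_s + (trials.bet_correct[t] - m1s) / p2
        sig_s = 1.0 / p2
        # non-social update
        p2h = 1.0 / (sig_ns + params_ns.omega)
        p2 = p2h + m1ns * (1.0 - m1ns)
        mu2_ns = mu2_ns + (trials.scene_pct[t] / 100.0 - m1ns) / p2
        sig_ns = 1.0 / p2
        mu2s_out[t] = mu2_s
        mu2ns_out[t] = mu2_ns
    return b_out, mu2s_out, mu2ns_out


class TestFilterTrajectory:
    def test_matches_independent_oracle(self, c2_trials):
        ps = StreamParameters(omega=0.7, mu2_0=0.8, eta=1.3)
        pns = StreamParameters(omega=0.25, mu2_0=-0.2)
        traj = filter_trajectory(ps, pns, c2_trials)
        b, mu2s, mu2ns = _oracle_trajectory(ps, pns, c2_trials)
        np.testing.assert_allclose(traj.b, b, atol=1e-12)
        np.testing.assert_allclose(traj.mu2_s, mu2s, atol=1e-12)
        np.testing.assert_allclose(traj.mu2_ns, mu2ns, atol=1e-12)

    def test_zero_information_nonsocial_stationary(self):
        # all-50% stimuli with mu2_0 = 0: prediction 0.5 equals input 0.5
        cfg = TaskConfig(n_trials=30, scene_grid=(50,), seed=3)
        trials = generate_bets(generate_stimulus_sequence(cfg), 0.5, seed=4)
        traj = filter_trajectory(
            StreamParameters(omega=0.5, mu2_0=1.0, eta=1.0),
            StreamParameters(omega=0.5, mu2_0=0.0),
            trials,
        )
        np.testing.assert_allclose(traj.mu2_ns, 0.0, atol=1e-12)
        np.testing.assert_allclose(traj.delta1_ns, 0.0, atol=1e-12)

    def test_perfect_bets_drive_social_belief_up(self):
        cfg = TaskConfig(n_trials=40, seed=5)
        trials = generate_bets(generate_stimulus_sequence(cfg), 1.0, seed=6)
        traj = filter_trajectory(
            StreamParameters(omega=1.0, mu2_0=1.0, eta=1.0),
            StreamParameters(omega=0.3, mu2_0=0.0),
            trials,
        )
        diffs = np.diff(traj.mu1_hat_s)
        assert np.all(diffs >= -1e-12)
        assert traj.mu1_hat_s[-1] > traj.mu1_hat_s[0]

    def test_deterministic(self, c2_trials):
        ps = StreamParameters(omega=0.4, mu2_0=0.1, eta=0.9)
        pns = StreamParameters(omega=0.2)
        a = filter_trajectory(ps, pns, c2_trials)
        b = filter_trajectory(ps, pns, c2_trials)
        assert np.array_equal(a.b, b.b)
        assert np.array_equal(a.mu2_s, b.mu2_s)

    def test_beliefs_and_precisions_stay_finite(self, c2_trials):
        # extreme parameters: beliefs must stay inside (0,1)
        traj = filter_trajectory(
            StreamParameters(omega=100.0, mu2_0=5.0, eta=10.0),
            StreamParameters(omega=100.0, mu2_0=-5.0),
            c2_trials,
        )
        for arr in (traj.mu1_hat_s, traj.mu1_hat_ns, traj.a_ns, traj.b):
            assert np.all((arr > 0) & (arr < 1))
        assert np.all(np.isfinite(traj.mu2_s))
        assert np.all(np.isfinite(traj.sigma2_s))
        assert np.all(traj.sigma2_s > 0)

    def test_requires_bets(self):
        seq = generate_stimulus_sequence(TaskConfig(seed=0))
        with pytest.raises(ValueError):
            filter_trajectory(
                StreamParameters(omega=1.0, eta=1.0),
                StreamParameters(omega=1.0),
                seq,
            )

    def test_social_links_differ(self, c2_trials):
        ps = StreamParameters(omega=0.5, mu2_0=1.0, eta=2.0)
        pns = StreamParameters(omega=0.3)
        scaled = filter_trajectory(ps, pns, c2_trials, social_link="scaled")
        mult = filter_trajectory(ps, pns, c2_trials, social_link="multiplicative")
        add = filter_trajectory(ps, pns, c2_trials, social_link="additive")
        assert not np.allclose(scaled.mu1_hat_s, mult.mu1_hat_s)
        assert not np.allclose(scaled.mu1_hat_s, add.mu1_hat_s)

    def test_recency_influence_shrinks_with_omega_ns(self, c2_trials):
        """Larger omega_ns lets the level-2 tendency dominate the recency
        bias, weakening the recency-choice coupling."""
        corrs = []
        for omega_ns in (0.01, 50.0):
            traj = filter_trajectory(
                StreamParameters(omega=0.01, mu2_0=0.0, eta=1.0),
                StreamParameters(omega=omega_ns, mu2_0=0.0),
                c2_trials,
            )
            p_scene = traj.mu1_hat_ns  # scene-space prediction
            mask = traj.recency != 0
            corrs.append(np.corrcoef(traj.recency[mask], p_scene[mask])[0, 1])
        assert abs(corrs[1]) < abs(corrs[0])


class TestRescorlaWagner:
    def test_alpha_one_tracks_previous_input(self, c2_trials):
        traj = rw_trajectory(RwParameters(alpha_s=1.0, alpha_ns=1.0), c2_trials)
        # V after trial t equals input at t, so the prediction at t+1
        # equals the previous input
        np.testing.assert_allclose(
            traj.mu1_hat_ns[1:],
            np.clip(c2_trials.scene_pct[:-1] / 100.0, 1e-8, 1 - 1e-8),
            atol=1e-12,
        )

    def test_hand_iteration(self):
        cfg = TaskConfig(n_trials=2, scene_grid=(100,), seed=0)
        trials = generate_bets(generate_stimulus_sequence(cfg), 1.0, seed=0)
        traj = rw_trajectory(RwParameters(alpha_s=0.5, alpha_ns=0.5), trials)
        # u = 1, 1 for both streams: V = 0.75 then 0.875
        np.testing.assert_allclose(traj.mu2_s, [0.75, 0.875], atol=1e-12)
        np.testing.assert_allclose(traj.mu2_ns, [0.75, 0.875], atol=1e-12)

    def test_geometric_convergence_to_stationary_input(self):
        cfg = TaskConfig(n_trials=30, scene_grid=(80,), seed=0)
        trials = generate_bets(generate_stimulus_sequence(cfg), 1.0, seed=0)
        alpha = 0.3
        traj = rw_trajectory(RwParameters(alpha_s=0.9, alpha_ns=alpha), trials)
        err = np.abs(traj.mu2_ns - 0.8)
        ratio = err[1:] / err[:-1]
        np.testing.assert_allclose(ratio, 1 - alpha, atol=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            RwParameters(alpha_s=0.0, alpha_ns=0.5)
        with pytest.raises(ValueError):
            RwParameters(alpha_s=0.5, alpha_ns=0.5, V0_s=1.0)
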