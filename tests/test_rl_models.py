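"""Model-family semantics: softmax, updates, likelihood, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strifun import bandit_task as bt
from strifun import rl_models as rl


SPEC_FULL = rl.ModelSpec(neg_alpha=True, effector_bias=True, lapse=True,
                         decay=True, perseverance=True)


class TestModelSpec:
    def test_flag_string_round_trip(self):
        spec = rl.ModelSpec.from_string("neg_alpha,decay")
        assert spec.neg_alpha and spec.decay and not spec.lapse
        assert spec.to_string() == "neg_alpha,decay"
        assert rl.ModelSpec.from_string("").to_string() == "base"

    def test_param_names(self):
        assert rl.ModelSpec().param_names == ("alpha_pos", "beta")
        assert SPEC_FULL.param_names == ("alpha_pos", "alpha_neg", "beta",
                                         "bias", "lapse", "decay",
                                         "perseverance")

    def test_unknown_flag(self):
        with pytest.raises(ValueError):
            rl.ModelSpec.from_string("neg_alpha,typo")


class TestTransforms:
    @given(st.lists(st.floats(-5, 5), min_size=7, max_size=7))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_full_spec(self, x):
        x = np.array(x)
        p = rl.RLParams.from_transformed(x, SPEC_FULL)
        back = p.to_transformed(SPEC_FULL)
        np.testing.assert_allclose(back, x, rtol=1e-10, atol=1e-10)

    def test_natural_ranges(self):
        p = rl.RLParams.from_transformed(np.full(7, 3.0), SPEC_FULL)
        assert 0 < p.alpha_pos < 1 and 0 < p.alpha_neg < 1
        assert p.beta > 0
        assert 0 < p.lapse < 0.5
        assert 0 < p.decay < 1

    def test_batch_matches_scalar(self, rng):
        X = rng.normal(size=(20, 7))
        rows = rl.transformed_to_rows(X, SPEC_FULL)
        for k in range(20):
            p = rl.RLParams.from_transformed(X[k], SPEC_FULL)
            np.testing.assert_allclose(rows[k], p.to_row(SPEC_FULL),
                                       rtol=1e-12)

    def test_inactive_params_neutral(self, rng):
        spec = rl.ModelSpec.from_string("neg_alpha")
        rows = rl.transformed_to_rows(rng.normal(size=(5, 3)), spec)
        assert np.all(rows[:, 3:] == [0.0, 0.0, 0.0, 0.0])


class TestInitialQ:
    def test_symmetric_start(self):
        q = rl.initial_q()
        assert np.all(q.q == 0.5)
        assert np.all(q.last_action == bt.NO_ACTION)
        p = rl.action_probabilities(q, 0, rl.RLParams(0.3, 7.0),
                                    rl.ModelSpec())
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_decay_fixed_point(self):
        q = rl.initial_q()
        spec = rl.ModelSpec.from_string("decay")
        out = rl.apply_update(q, 0, None, None,
                              rl.RLParams(0.3, 1.0, decay=0.5), spec)
        assert np.all(out.q.q == 0.5)


class TestActionProbabilities:
    def test_softmax_value(self):
        # beta=5, Q=(0.8, 0.2): p(hand) = 1 / (1 + e^-3)
        q = rl.QTable(q=np.array([[0.8, 0.2], [0.5, 0.5]]))
        p = rl.action_probabilities(q, 0, rl.RLParams(0.5, 5.0),
                                    rl.ModelSpec())
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-3.0)), abs=1e-10)
        assert p[0] == pytest.approx(0.95257, abs=5e-6)

    def test_lapse_compression(self):
        q = rl.QTable(q=np.array([[0.8, 0.2], [0.5, 0.5]]))
        spec = rl.ModelSpec.from_string("lapse")
        p = rl.action_probabilities(q, 0, rl.RLParams(0.5, 5.0, lapse=0.1),
                                    spec)
        assert p[0] == pytest.approx(0.1 + 0.8 * 0.95257, abs=5e-6)
        assert np.all(p >= 0.1) and np.all(p <= 0.9)

    def test_probabilities_sum_to_one(self, rng):
        spec = SPEC_FULL
        for _ in range(20):
            q = rl.QTable(q=rng.uniform(0, 1, (2, 2)),
                          last_action=rng.integers(-1, 2, 2))
            params = rl.RLParams.from_transformed(rng.normal(size=7), spec)
            p = rl.action_probabilities(q, 0, params, spec)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bias_and_perseverance_shift_choice(self):
        q = rl.initial_q()
        spec = rl.ModelSpec.from_string("effector_bias,perseverance")
        p = rl.action_probabilities(q, 0, rl.RLParams(0.5, 1.0, bias=2.0),
                                    spec)
        assert p[0] > 0.8
        q.last_action[0] = 1
        p = rl.action_probabilities(
            q, 0, rl.RLParams(0.5, 1.0, perseverance=2.0), spec)
        assert p[1] > 0.8


class TestApplyUpdate:
    def test_positive_feedback_update(self):
        spec = rl.ModelSpec.from_string("neg_alpha")
        out = rl.apply_update(rl.initial_q(), 0, 0, 1,
                              rl.RLParams(0.6, 1.0, alpha_neg=0.32), spec)
        assert out.rpe == pytest.approx(0.5)
        assert out.q.q[0, 0] == pytest.approx(0.8)

    def test_negative_feedback_update(self):
        spec = rl.ModelSpec.from_string("neg_alpha")
        out = rl.apply_update(rl.initial_q(), 0, 0, 0,
                              rl.RLParams(0.6, 1.0, alpha_neg=0.32), spec)
        assert out.rpe == pytest.approx(-0.5)
        assert out.q.q[0, 0] == pytest.approx(0.5 - 0.32 * 0.5)

    def test_decay_of_unsampled_pair(self):
        spec = rl.ModelSpec.from_string("decay")
        q = rl.QTable(q=np.array([[0.5, 0.9], [0.5, 0.5]]))
        out = rl.apply_update(q, 0, 0, 1, rl.RLParams(0.0, 1.0, decay=0.5),
                              spec)
        assert out.q.q[0, 1] == pytest.approx(0.7)  # 0.9 + 0.5*(0.5-0.9)

    def test_zero_learning_rate(self):
        out = rl.apply_update(rl.initial_q(), 1, 1, 1,
                              rl.RLParams(0.0, 1.0), rl.ModelSpec())
        assert out.q.q[1, 1] == pytest.approx(0.5)

    def test_none_action_decays_all(self):
        spec = rl.ModelSpec.from_string("decay")
        q = rl.QTable(q=np.array([[0.1, 0.9], [0.3, 0.7]]))
        out = rl.apply_update(q, 0, None, None,
                              rl.RLParams(0.5, 1.0, decay=0.5), spec)
        np.testing.assert_allclose(out.q.q, [[0.3, 0.7], [0.4, 0.6]])
        assert out.rpe is None

    def test_invalid_reward(self):
        with pytest.raises(ValueError):
            rl.apply_update(rl.initial_q(), 0, 0, 2, rl.RLParams(0.5, 1.0),
                            rl.ModelSpec())

    def test_rpe_exact_identity(self, rng):
        spec = SPEC_FULL
        for _ in range(20):
            q = rl.QTable(q=rng.uniform(0, 1, (2, 2)))
            params = rl.RLParams.from_transformed(rng.normal(size=7), spec)
            s, a, r = rng.integers(2), rng.integers(2), rng.integers(2)
            out = rl.apply_update(q, s, a, r, params, spec)
            assert out.rpe == r - q.q[s, a]


def _python_replay_nll(session, params, spec):
    """Independent replay oracle built from the public per-trial operations."""
    q = rl.initial_q()
    nll = 0.0
    for t in range(session.n_trials):
        s = int(session.stimulus[t])
        a = int(session.action[t])
        if session.kind[t] == 1 and a != bt.NO_ACTION:
            p = rl.action_probabilities(q, s, params, spec)
            nll -= np.log(p[a])
            q = rl.apply_update(q, s, a, int(session.reward[t]), params,
                                spec).q
        else:
            q = rl.apply_update(q, s, None, None, params, spec).q
    return nll


class TestSessionNLL:
    def test_empty_likelihood(self):
        s = bt.BehavioralSession(stimulus=np.array([0, 1]),
                                 kind=np.array([0, 0]),
                                 action=np.array([-1, -1]),
                                 reward=np.array([-1, -1]))
        assert rl.session_nll(s, rl.RLParams(0.5, 3.0), rl.ModelSpec()) == 0.0

    def test_single_trial_is_log2(self):
        s = bt.BehavioralSession(stimulus=np.array([0]), kind=np.array([1]),
                                 action=np.array([0]), reward=np.array([1]))
        for beta in (0.0, 1.0, 10.0):
            nll = rl.session_nll(s, rl.RLParams(0.5, beta), rl.ModelSpec())
            assert nll == pytest.approx(np.log(2), abs=1e-12)

    def test_agrees_with_python_replay(self, rng):
        # compiled kernel vs independent replay over the full model family
        walks = bt.generate_walks(n_trials=60, seed=1)
        for i in range(100):
            flags = [rl.FLAG_NAMES[j] for j in range(5) if rng.random() < 0.5]
            spec = rl.ModelSpec.from_string(",".join(flags))
            params = rl.RLParams.from_transformed(
                rng.normal(scale=1.0, size=spec.n_params), spec)
            seq = bt.generate_trial_sequence(15, 3, seed=100 + i)
            sess = rl.simulate_session(walks, seq, params, spec,
                                       seed=200 + i, miss_prob=0.05)
            fast = rl.session_nll(sess, params, spec)
            slow = _python_replay_nll(sess, params, spec)
            assert fast == pytest.approx(slow, rel=1e-10, abs=1e-10)

    def test_lapse_bounds_every_choice_probability(self, rng):
        spec = rl.ModelSpec.from_string("lapse")
        params = rl.RLParams(0.7, 20.0, lapse=0.15)
        walks = bt.generate_walks(n_trials=120, seed=2)
        seq = bt.generate_trial_sequence(30, 3, seed=3)
        sess = rl.simulate_session(walks, seq, params, spec, seed=4)
        q = rl.initial_q()
        for t in range(sess.n_trials):
            s = int(sess.stimulus[t])
            a = int(sess.action[t])
            if sess.kind[t] == 1 and a != bt.NO_ACTION:
                p = rl.action_probabilities(q, s, params, spec)
                assert 0.15 <= p[a] <= 0.85
                q = rl.apply_update(q, s, a, int(sess.reward[t]), params,
                                    spec).q
            else:
                q = rl.apply_update(q, s, None, None, params, spec).q


class TestSimulateSession:
    def test_uniform_choice_at_zero_beta(self):
        walks = bt.generate_walks(n_trials=20000, seed=5,
                                  max_attempts=100_000)
        types = np.random.default_rng(6).permutation(
            np.repeat(np.arange(4), 5000))
        seq = bt.TrialSequence(stimulus=types // 2, kind=types % 2)
        sess = rl.simulate_session(walks, seq, rl.RLParams(0.5, 0.0),
                                   rl.ModelSpec(), seed=7)
        chosen = sess.action[sess.action != bt.NO_ACTION]
        p_hand = np.mean(chosen == 0)
        se = np.sqrt(0.25 / chosen.size)
        assert abs(p_hand - 0.5) < 3 * se

    def test_deterministic_per_seed(self):
        walks = bt.generate_walks(n_trials=64, seed=8)
        seq = bt.generate_trial_sequence(16, 3, seed=9)
        params = rl.RLParams(0.6, 4.0)
        a = rl.simulate_session(walks, seq, params, rl.ModelSpec(), seed=10,
                                miss_prob=0.05)
        b = rl.simulate_session(walks, seq, params, rl.ModelSpec(), seed=10,
                                miss_prob=0.05)
        np.testing.assert_array_equal(a.action, b.action)
        np.testing.assert_array_equal(a.reward, b.reward)

    def test_response_trial_count(self):
        walks = bt.generate_walks(n_trials=512, seed=11)
        seq = bt.generate_trial_sequence(128, 3, seed=12)
        sess = rl.simulate_session(walks, seq, rl.RLParams(0.6, 4.0),
                                   rl.ModelSpec(), seed=13)
        assert sess.n_choices == 256

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_q_stays_bounded_along_trajectories(self, seed):
        # with rewards in {0,1} and rates in (0,1), Q stays in [0,1]
        r = np.random.default_rng(seed)
        spec = SPEC_FULL
        params = rl.RLParams.from_transformed(r.normal(size=7), spec)
        walks = bt.generate_walks(n_trials=40, seed=seed)
        seq = bt.generate_trial_sequence(10, 3, seed=seed)
        q = rl.initial_q()
        sess = rl.simulate_session(walks, seq, params, spec, seed=seed)
        for t in range(sess.n_trials):
            s, a = int(sess.stimulus[t]), int(sess.action[t])
            if sess.kind[t] == 1 and a != bt.NO_ACTION:
                q = rl.apply_update(q, s, a, int(sess.reward[t]), params,
                                    spec).q
            else:
                q = rl.apply_update(q, s, None, None, params, spec).q
            assert np.all(q.q >= 0.0) and np.all(q.q <= 1.0)


class TestLikelihoodProfile:
    def test_nll_minimized_near_generative_alpha(self):
        # long-session profile over alpha_pos attains its minimum within
        # +-0.1 of the generative value
        walks = bt.generate_walks(n_trials=5000, seed=14,
                                  max_attempts=100_000)
        types = np.random.default_rng(15).permutation(
            np.repeat(np.arange(4), 1250))
        seq = bt.TrialSequence(stimulus=types // 2, kind=types % 2)
        gen = rl.RLParams(0.55, 5.0)
        sess = rl.simulate_session(walks, seq, gen, rl.ModelSpec(), seed=16)
        grid = np.arange(0.05, 1.0, 0.05)
        nlls = [rl.session_nll(sess, rl.RLParams(a, 5.0), rl.ModelSpec())
                for a in grid]
        assert abs(grid[int(np.argmin(nlls))] - 0.55) <= 0.1
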