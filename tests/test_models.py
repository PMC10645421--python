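"""Q-learning updates, action weights, softmax choice, likelihoods, agents."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aarl
from aarl.models import (MODEL_NAMES, ModelSpec, ParamVector, SessionData,
                         action_weights, choice_probs,
                         negative_log_likelihood, simulate_agent, update_q)


class TestUpdateQ:
    def test_half_step_toward_outcome(self):
        assert update_q(0.5, 1, 0.5) == pytest.approx(0.75)

    def test_zero_learning_rate_freezes_estimate(self):
        for o in (0, 1):
            assert update_q(0.3, o, 0.0) == pytest.approx(0.3)

    def test_repeated_update_matches_closed_form(self):
        # q_t = 1 - (1 - alpha)^t (1 - q0)
        q = 0.0
        for _ in range(3):
            q = update_q(q, 1, 0.3)
        assert q == pytest.approx(1 - 0.7 ** 3)
        assert q == pytest.approx(0.657)

    @given(q=st.floats(0, 1), a=st.floats(0, 1),
           o=st.sampled_from([0, 1]))
    @settings(deadline=None, max_examples=100)
    def test_estimate_stays_in_unit_interval(self, q, a, o):
        assert 0.0 <= update_q(q, o, a) <= 1.0

    @pytest.mark.parametrize("kwargs", [
        {"q": 1.5, "outcome": 1, "alpha": 0.5},
        {"q": 0.5, "outcome": 2, "alpha": 0.5},
        {"q": 0.5, "outcome": 1, "alpha": -0.1},
    ])
    def test_out_of_range_inputs(self, kwargs):
        with pytest.raises(ValueError):
            update_q(kwargs["q"], kwargs["outcome"], kwargs["alpha"])


class TestParamVector:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_transform_round_trip(self, name):
        spec = ModelSpec(name)
        rng = np.random.default_rng(hash(name) % 2**31)
        h = rng.normal(0, 2, spec.n_params)
        back = spec.untransform(spec.transform(h))
        np.testing.assert_allclose(back, h, atol=1e-10)

    def test_transformed_values_respect_bounds(self):
        spec = ModelSpec("asym_lr_asym_sens_lapse")
        t = spec.transform(np.array([5.0, -5.0, 4.0, -4.0, 0.0]))
        assert 0 < t["alpha_r"] < 1 and 0 < t["alpha_p"] < 1 and 0 < t["xi"] < 1
        assert t["beta_r"] > 0 and t["beta_p"] > 0

    def test_unknown_model_name(self):
        with pytest.raises(ValueError):
            ModelSpec("extra_special_model")


class TestActionWeights:
    def test_split_form_reduces_to_symmetric(self):
        q = (0.8, 0.3, 0.6, 0.1)
        sym = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.3, beta=2.0)
        asym = ParamVector.from_transformed(
            ModelSpec("asym_sens"), alpha=0.3, beta_r=2.0, beta_p=2.0)
        np.testing.assert_allclose(
            action_weights(q, ModelSpec("sym"), sym),
            action_weights(q, ModelSpec("asym_sens"), asym))

    def test_equal_estimates_give_zero_weight(self):
        p = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.3, beta=2.0)
        w = action_weights((0.4, 0.4, 0.4, 0.4), ModelSpec("sym"), p)
        np.testing.assert_allclose(w, 0.0)

    def test_weighted_difference_arithmetic(self):
        p = ParamVector.from_transformed(
            ModelSpec("asym_sens"), alpha=0.5, beta_r=2.0, beta_p=3.0)
        w = action_weights((0.6, 0.0, 0.2, 0.0), ModelSpec("asym_sens"), p)
        assert w[0] == pytest.approx(2 * 0.6 - 3 * 0.2)


class TestChoiceProbs:
    def test_equal_weights_split_evenly(self):
        np.testing.assert_allclose(choice_probs([1.3, 1.3]), [0.5, 0.5])

    def test_full_lapse_ignores_weights(self):
        np.testing.assert_allclose(choice_probs([9.0, -9.0], lapse=1.0),
                                   [0.5, 0.5])

    def test_logistic_closed_form(self):
        p = choice_probs([0.6, 0.0])
        assert p[0] == pytest.approx(1 / (1 + np.exp(-0.6)))

    @given(w=st.floats(-50, 50), shift=st.floats(-100, 100),
           lapse=st.floats(0, 1))
    @settings(deadline=None, max_examples=100)
    def test_proper_distribution_and_shift_invariance(self, w, shift, lapse):
        p = choice_probs([w, 0.0], lapse=lapse)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)
        np.testing.assert_allclose(choice_probs([w + shift, shift]),
                                   choice_probs([w, 0.0]), atol=1e-12)


def _session(choices, rewards, punishments, **kw):
    return SessionData("t", 1, np.array(choices, dtype=np.int8),
                       np.array(rewards, dtype=np.int8),
                       np.array(punishments, dtype=np.int8), **kw)


class TestNegativeLogLikelihood:
    def test_single_trial_equal_weights_is_ln2(self):
        s = _session([1], [1], [0])
        p = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.5, beta=1.0)
        assert negative_log_likelihood(s, ModelSpec("sym"), p) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_all_missed_trials_contribute_nothing(self):
        s = _session([-1, -1, -1], [-1, -1, -1], [-1, -1, -1])
        p = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.5, beta=1.0)
        assert negative_log_likelihood(s, ModelSpec("sym"), p) == 0.0

    def test_empty_session_is_an_error(self):
        s = _session([], [], [])
        p = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.5, beta=1.0)
        with pytest.raises(ValueError):
            negative_log_likelihood(s, ModelSpec("sym"), p)

    def test_three_trial_hand_worked_trace(self):
        """Step-by-step manual computation, alpha=0.5, beta=1, q0=0.5."""
        s = _session([1, 0, 1], [1, 0, 1], [0, 0, 1])
        p = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.5, beta=1.0)
        # trial 1: all Q = 0.5, weights equal -> P(conflict) = 1/2
        nll = np.log(2.0)
        # update conflict: qrc = 0.75, qpc = 0.25
        # trial 2 (safe chosen): Wc = 0.75 - 0.25 = 0.5, Ws = 0
        nll += -np.log(1.0 / (1.0 + np.exp(0.5)))
        # update safe: qrs = 0.25, qps = 0.25
        # trial 3 (conflict): Wc = 0.5, Ws = 0.25 - 0.25 = 0
        nll += -np.log(np.exp(0.5) / (1.0 + np.exp(0.5)))
        assert negative_log_likelihood(s, ModelSpec("sym"), p) == \
            pytest.approx(nll, abs=1e-10)

    def test_missed_trials_skip_learning(self):
        # identical outcome histories; the missed trial must not update Q
        p = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.5, beta=2.0)
        with_missed = _session([1, -1, 1], [1, -1, 1], [0, -1, 0])
        without = _session([1, 1], [1, 1], [0, 0])
        assert negative_log_likelihood(with_missed, ModelSpec("sym"), p) == \
            pytest.approx(negative_log_likelihood(without, ModelSpec("sym"), p))

    def test_single_outcome_models_ignore_irrelevant_stream(self, schedule):
        spec = ModelSpec("reward_only")
        p = ParamVector.from_transformed(spec, alpha_r=0.4, beta_r=2.0)
        s = simulate_agent(schedule, ModelSpec("sym"),
                           ParamVector.from_transformed(ModelSpec("sym"),
                                                        alpha=0.4, beta=2.0),
                           seed=3)
        base = negative_log_likelihood(s, spec, p)
        rng = np.random.default_rng(0)
        shuffled = SessionData("t", 1, s.choices, s.rewards,
                               rng.permutation(s.punishments))
        # repair missed-trial coding after the shuffle
        shuffled.punishments[s.choices == -1] = -1
        shuffled.punishments[(s.choices != -1) & (shuffled.punishments == -1)] = 0
        assert negative_log_likelihood(shuffled, spec, p) == pytest.approx(base)

    def test_symmetric_model_nested_in_asymmetric(self, sym_session):
        sym = ParamVector.from_transformed(ModelSpec("sym"), alpha=0.4, beta=3.0)
        tied = ParamVector.from_transformed(
            ModelSpec("asym_lr_asym_sens"), alpha_r=0.4, alpha_p=0.4,
            beta_r=3.0, beta_p=3.0)
        a = negative_log_likelihood(sym_session, ModelSpec("sym"), sym)
        b = negative_log_likelihood(sym_session, ModelSpec("asym_lr_asym_sens"), tied)
        assert a == pytest.approx(b, abs=1e-10)


class TestSimulateAgent:
    def test_reproducible_from_seed(self, schedule, winning_spec):
        pv = ParamVector.from_transformed(winning_spec, alpha_r=0.4,
                                          alpha_p=0.2, beta_r=4, beta_p=2)
        a = simulate_agent(schedule, winning_spec, pv, seed=9)
        b = simulate_agent(schedule, winning_spec, pv, seed=9)
        np.testing.assert_array_equal(a.choices, b.choices)
        np.testing.assert_array_equal(a.rewards, b.rewards)

    def test_zero_sensitivity_agents_choose_at_chance(self, schedule):
        spec = ModelSpec("sym")
        pv = ParamVector.from_transformed(spec, alpha=0.3, beta=1e-8)
        props = [np.mean(simulate_agent(schedule, spec, pv, seed=s).choices == 1)
                 for s in range(20)]
        assert abs(np.mean(props) - 0.5) < 0.02

    def test_punishment_dominated_agents_avoid_conflict(self, schedule,
                                                        winning_spec):
        pv = ParamVector.from_transformed(winning_spec, alpha_r=0.3,
                                          alpha_p=0.3, beta_r=0.1, beta_p=20)
        prop = np.mean(simulate_agent(schedule, winning_spec, pv,
                                      seed=4).choices == 1)
        assert prop < 0.35

    def test_likelihood_self_consistency(self, schedule, winning_spec):
        """Generating parameters beat perturbed ones on average."""
        pv = ParamVector.from_transformed(winning_spec, alpha_r=0.45,
                                          alpha_p=0.25, beta_r=5, beta_p=2)
        rng = np.random.default_rng(0)
        wins = 0
        for s in range(20):
            sess = simulate_agent(schedule, winning_spec, pv, seed=s)
            base = negative_log_likelihood(sess, winning_spec, pv)
            pert = ParamVector(winning_spec,
                               pv.untransformed + rng.normal(0, 1.0, 4))
            wins += base < negative_log_likelihood(sess, winning_spec, pert)
        assert wins >= 15

    def test_missed_rate_emits_flagged_trials(self, schedule, winning_spec):
        pv = ParamVector.from_transformed(winning_spec, alpha_r=0.4,
                                          alpha_p=0.2, beta_r=4, beta_p=2)
        s = simulate_agent(schedule, winning_spec, pv, seed=1, missed_rate=0.2)
        missed = s.choices == -1
        assert 0.1 < missed.mean() < 0.3
        assert np.all(s.rewards[missed] == -1)
        assert np.all(s.keys[missed] == -1)

    def test_keys_encode_randomised_sides(self, schedule, winning_spec):
        pv = ParamVector.from_transformed(winning_spec, alpha_r=0.4,
                                          alpha_p=0.2, beta_r=4, beta_p=2)
        s = simulate_agent(schedule, winning_spec, pv, seed=1)
        chose_conflict = s.choices == 1
        np.testing.assert_array_equal(s.keys[chose_conflict],
                                      s.conflict_side[chose_conflict])
        chose_safe = s.choices == 0
        np.testing.assert_array_equal(s.keys[chose_safe],
                                      1 - s.conflict_side[chose_safe])
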