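"""Cleaning rules, choice regressions, correlations, composite indices."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import aarl
from aarl.models import SessionData
from aarl.stats import (choice_proportion, clean_cohort, glmm_choice,
                        kendall_perm_test, learning_rate_ratio,
                        sensitivity_index, welch_t)
from aarl.synthetic import CohortConfig, generate_cohort


def _keyed_session(pid, keys, missed=0, n=200):
    keys = np.asarray(keys, dtype=np.int8)
    choices = np.where(keys < 0, -1, 1).astype(np.int8)
    rewards = np.where(choices < 0, -1, 0).astype(np.int8)
    if missed:
        choices[:missed] = -1
        rewards[:missed] = -1
        keys[:missed] = -1
    pun = rewards.copy()
    return SessionData(pid, 1, choices, rewards, pun, keys=keys,
                       conflict_side=np.zeros(len(keys), dtype=np.int8))


class TestCleanCohort:
    def test_nineteen_consecutive_keys_retained_twenty_excluded(self):
        runs19 = np.array(([1] * 19 + [0]) * 10)          # max run exactly 19
        runs20 = np.array(([1] * 20 + [0, 1, 0]) * 10)[:200]  # max run 20
        rep = clean_cohort([_keyed_session("ok", runs19),
                            _keyed_session("bad", runs20)])
        assert rep.excluded_keys == {"bad"}
        assert [s.participant_id for s in rep.retained] == ["ok"]

    def test_twenty_missed_trials_excluded(self):
        base = np.tile([0, 1], 100)
        rep = clean_cohort([_keyed_session("m19", base, missed=19),
                            _keyed_session("m20", base, missed=20)])
        assert rep.excluded_missed == {"m20"}

    def test_attention_rule_allows_one_miss(self):
        base = np.tile([0, 1], 100)
        sessions = [_keyed_session(p, base) for p in ("a", "b")]
        rep = clean_cohort(sessions, {"a": 1, "b": 2})
        assert rep.excluded_attention == {"b"}

    def test_planted_violators_recovered_exactly(self):
        cohort = generate_cohort(CohortConfig(
            n_participants=30, n_trials=120, seed=4,
            n_violators_attention=1, n_violators_keys=1, n_violators_missed=1))
        rep = clean_cohort(cohort.sessions, cohort.attention_results)
        planted = set(cohort.ground_truth.loc[
            cohort.ground_truth["violator"] != "", "participant_id"])
        assert rep.excluded == planted

    def test_cleaning_is_idempotent(self):
        cohort = generate_cohort(CohortConfig(
            n_participants=20, n_trials=120, seed=4, n_violators_keys=2))
        rep = clean_cohort(cohort.sessions, cohort.attention_results)
        rep2 = clean_cohort(rep.retained, cohort.attention_results)
        assert rep2.excluded == set()

    def test_missing_key_stream_is_an_error(self):
        s = SessionData("x", 1, np.array([1, 0]), np.array([1, 0]),
                        np.array([0, 0]))
        with pytest.raises(ValueError):
            clean_cohort([s])


class TestChoiceProportion:
    def test_all_conflict(self):
        s = SessionData("x", 1, np.ones(10, dtype=np.int8),
                        np.zeros(10, dtype=np.int8), np.zeros(10, dtype=np.int8))
        assert choice_proportion(s) == 1.0

    def test_half_conflict_excludes_missed(self):
        choices = np.array([1] * 100 + [0] * 100 + [-1] * 10, dtype=np.int8)
        out = np.where(choices < 0, -1, 0).astype(np.int8)
        s = SessionData("x", 1, choices, out, out)
        assert choice_proportion(s) == 0.5

    def test_all_missed_is_an_error(self):
        s = SessionData("x", 1, np.full(5, -1, np.int8),
                        np.full(5, -1, np.int8), np.full(5, -1, np.int8))
        with pytest.raises(ValueError):
            choice_proportion(s)


class TestGlmmChoice:
    def test_signs_match_generative_construction(self, small_cohort):
        """Reward-seeking, punishment-averse agents: + reward, - punishment."""
        res = glmm_choice(small_cohort.sessions, small_cohort.schedules)
        assert res.coef("dp_reward") > 0
        assert res.coef("p_punish") < 0
        p = res.coefficients.set_index("term")["p"]
        assert p["dp_reward"] < 0.001 and p["p_punish"] < 0.001

    def test_shuffled_choices_null_coefficients(self, small_cohort):
        rng = np.random.default_rng(0)
        shuffled = []
        for s in small_cohort.sessions:
            idx = rng.permutation(s.n_trials)
            shuffled.append(SessionData(
                s.participant_id, s.session, s.choices[idx], s.rewards[idx],
                s.punishments[idx], covariates=s.covariates))
        res = glmm_choice(shuffled, small_cohort.schedules)
        coefs = res.coefficients.set_index("term")
        for term in ("dp_reward", "p_punish"):
            assert abs(coefs.loc[term, "estimate"]) < \
                4 * coefs.loc[term, "se"]

    def test_single_participant_reduces_to_plain_logistic(self, small_cohort):
        import statsmodels.formula.api as smf
        from aarl.stats import _build_choice_frame
        one = [small_cohort.sessions[0]]
        res = glmm_choice(one, small_cohort.schedules, random_intercepts=False)
        df = _build_choice_frame(one, small_cohort.schedules, True, False, ())
        oracle = smf.logit("choice ~ dp_reward + p_punish", df).fit(disp=0)
        got = res.coefficients.set_index("term")["estimate"]
        np.testing.assert_allclose(got["dp_reward"],
                                   oracle.params["dp_reward"], atol=1e-6)
        np.testing.assert_allclose(got["p_punish"],
                                   oracle.params["p_punish"], atol=1e-6)

    def test_anxiety_interaction_terms_present(self, small_cohort):
        res = glmm_choice(small_cohort.sessions, small_cohort.schedules,
                          include_anxiety=True)
        terms = set(res.coefficients["term"])
        assert {"anxiety", "anxiety_x_dp_reward",
                "anxiety_x_p_punish"} <= terms


class TestKendallPermTest:
    def test_perfect_concordance(self):
        x = np.arange(10.0)
        tau, p = kendall_perm_test(x, 2 * x + 1, n_perm=200, seed=0)
        assert tau == pytest.approx(1.0)
        assert p < 0.05

    def test_matches_exhaustive_enumeration_oracle(self):
        """n=5: all 120 pairings enumerated give the exact permutation p."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        obs = sps.kendalltau(x, y).statistic
        taus = np.array([sps.kendalltau(x, perm).statistic
                         for perm in itertools.permutations(y)])
        p_ge = (np.sum(taus >= obs) + 1) / (len(taus) + 1)
        p_le = (np.sum(taus <= obs) + 1) / (len(taus) + 1)
        exact = min(1.0, 2 * min(p_ge, p_le))
        _, p = kendall_perm_test(x, y, n_perm=20_000, seed=1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_detects_planted_negative_association(self):
        rng = np.random.default_rng(3)
        rho = np.sin(-0.1 * np.pi / 2)
        z = rng.standard_normal((500, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
        tau, p = kendall_perm_test(x, y, n_perm=2000, seed=0)
        assert tau < 0 and p < 0.05

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError):
            kendall_perm_test(np.ones(10), np.arange(10.0))


class TestIndices:
    def test_equal_sensitivities_give_unit_index(self):
        assert sensitivity_index({"beta_r": 2.0, "beta_p": 2.0}).iloc[0] == 1.0

    def test_avoidance_biased_ratio(self):
        assert sensitivity_index({"beta_r": 2.0, "beta_p": 4.0}).iloc[0] == 0.5

    def test_requires_split_sensitivities(self):
        with pytest.raises(ValueError):
            sensitivity_index({"beta": 3.0})

    def test_learning_rate_analogue(self):
        df = pd.DataFrame({"alpha_r": [0.4, 0.2], "alpha_p": [0.2, 0.4]})
        np.testing.assert_allclose(learning_rate_ratio(df), [2.0, 0.5])

    def test_fitted_index_tracks_generating_index(self, small_cohort,
                                                  fitted_small):
        fitted = sensitivity_index(fitted_small.params)
        truth = small_cohort.ground_truth.set_index("participant_id")
        truth = truth.loc[fitted.index, "sensitivity_index"]
        r = np.corrcoef(np.log(fitted), np.log(truth))[0, 1]
        assert r > 0.8


class TestWelchT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(a, a.copy())
        assert res["t"] == pytest.approx(0.0)
        assert res["cohen_d"] == pytest.approx(0.0)

    def test_matches_hand_computed_formula(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8])
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        t_hand = (ma - mb) / np.sqrt(va / na + vb / nb)
        df_hand = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        res = welch_t(a, b)
        assert res["t"] == pytest.approx(t_hand)
        assert res["df"] == pytest.approx(df_hand)

    def test_equal_variance_equal_n_df_limit(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(400)
        b = rng.standard_normal(400) + 0.1
        res = welch_t(a, b)
        assert res["df"] == pytest.approx(2 * 400 - 2, rel=0.02)

    def test_degenerate_variance_is_an_error(self):
        with pytest.raises(ValueError):
            welch_t(np.ones(5), np.ones(5))
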