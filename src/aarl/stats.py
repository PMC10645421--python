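"""Model-agnostic behavioural analyses: cleaning, regressions, correlations.

Covers the data-quality exclusion rules, per-participant choice proportions,
mixed-effects logistic regressions of trial-by-trial choice on the latent
outcome probabilities, permutation-based Kendall correlations, Welch t-tests,
and the reward-punishment sensitivity index (beta_r / beta_p, the model-based
measure of approach-avoidance bias; values below 1 mark avoidance bias) with
its learning-rate analogue (alpha_r / alpha_p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import MISSED, SessionData

__all__ = [
    "CleaningReport",
    "RegressionResult",
    "clean_cohort",
    "choice_proportion",
    "glmm_choice",
    "kendall_perm_test",
    "sensitivity_index",
    "learning_rate_ratio",
    "welch_t",
]


@dataclass
class CleaningReport:
    """Outcome of the three data-quality exclusion rules.

    Rules are applied independently and their exclusions unioned:
    (1) more than one missed attention check; (2) the same physical response
    key on 20+ consecutive trials (options switch sides randomly, so runs of
    the same *option* do not trigger this); (3) 20+ missed trials.
    """

    excluded_attention: set
    excluded_keys: set
    excluded_missed: set
    retained: list

    @property
    def excluded(self) -> set:
        return self.excluded_attention | self.excluded_keys | self.excluded_missed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": "attention_checks", "n_excluded": len(self.excluded_attention),
             "ids": sorted(self.excluded_attention)},
            {"rule": "consecutive_keys", "n_excluded": len(self.excluded_keys),
             "ids": sorted(self.excluded_keys)},
            {"rule": "missed_trials", "n_excluded": len(self.excluded_missed),
             "ids": sorted(self.excluded_missed)},
        ]
        return pd.DataFrame(rows)


def _max_key_run(keys: np.ndarray) -> int:
    """Longest run of identical non-missed response keys."""
    best = run = 0
    prev = None
    for k in keys:
        if k < 0:
            prev, run = None, 0
            continue
        run = run + 1 if k == prev else 1
        prev = k
        best = max(best, run)
    return best


def clean_cohort(
    sessions: list[SessionData],
    attention_results: dict[str, int] | None = None,
    max_attention_misses: int = 1,
    key_run_threshold: int = 20,
    missed_threshold: int = 20,
) -> CleaningReport:
    """Apply the three exclusion rules to a cohort of sessions.

    ``attention_results`` maps participant id to the number of missed
    auditory attention checks; participants absent from the map are treated
    as having missed none.
    """
    excl_att, excl_key, excl_miss = set(), set(), set()
    attention_results = attention_results or {}
    for s in sessions:
        pid = s.participant_id
        if attention_results.get(pid, 0) > max_attention_misses:
            excl_att.add(pid)
        if s.keys is None:
            if key_run_threshold is not None:
                raise ValueError(f"session {pid} has no response-key stream")
        elif _max_key_run(np.asarray(s.keys)) >= key_run_threshold:
            excl_key.add(pid)
        if int(np.sum(s.choices == MISSED)) >= missed_threshold:
            excl_miss.add(pid)
    excluded = excl_att | excl_key | excl_miss
    retained = [s for s in sessions if s.participant_id not in excluded]
    return CleaningReport(excl_att, excl_key, excl_miss, retained)


def choice_proportion(session: SessionData) -> float:
    """Proportion of conflict-option choices among non-missed trials."""
    valid = session.choices != MISSED
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all trials missed: choice proportion undefined")
    return float(np.mean(session.choices[valid] == 1))


@dataclass
class RegressionResult:
    """Coefficient table and diagnostics from a choice regression."""

    coefficients: pd.DataFrame   # term, estimate, se, z, p
    method: str
    converged: bool
    n_obs: int
    n_groups: int
    random_intercept_sd: float | None = None

    def coef(self, term: str) -> float:
        row = self.coefficients.set_index("term")
        return float(row.loc[term, "estimate"])


def _build_choice_frame(sessions, schedules, standardize, include_anxiety,
                        covariates):
    rows = []
    for s in sessions:
        sched = schedules[s.participant_id] if isinstance(schedules, dict) else schedules
        for t in range(s.n_trials):
            if s.choices[t] == MISSED:
                continue
            row = {
                "participant": s.participant_id,
                "choice": int(s.choices[t] == 1),
                "dp_reward": sched.p_reward_conflict[t] - sched.p_reward_safe[t],
                "p_punish": sched.p_punish_conflict[t],
            }
            if include_anxiety:
                row["anxiety"] = s.covariates["anxiety"]
            for c in covariates:
                row[c] = s.covariates[c]
            rows.append(row)
    df = pd.DataFrame(rows)
    if standardize:
        for col in ["dp_reward", "p_punish"] + (["anxiety"] if include_anxiety else []):
            sd = df[col].std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {col!r} is constant")
            df[col] = (df[col] - df[col].mean()) / sd
    return df


def glmm_choice(
    sessions: list[SessionData],
    schedules,
    include_anxiety: bool = False,
    covariates: tuple[str, ...] = (),
    standardize: bool = True,
    random_intercepts: bool = True,
) -> RegressionResult:
    """Mixed-effects logistic regression of trial-by-trial choice.

    Regresses choice (conflict = 1) on the latent reward-probability
    difference between options and the conflict option's punishment
    probability, optionally adding task-induced anxiety and its interactions
    with both probability terms, plus any extra covariates.  Participant
    random intercepts are estimated by Laplace approximation
    (statsmodels ``BinomialBayesMixedGLM.fit_map``); if that fails the model
    falls back to a fixed-effects logistic fit with cluster-robust standard
    errors and is flagged accordingly.

    ``schedules`` is a single schedule or a dict participant_id -> schedule.
    """
    df = _build_choice_frame(sessions, schedules, standardize,
                             include_anxiety, covariates)
    terms = ["dp_reward", "p_punish"]
    if include_anxiety:
        df["anxiety_x_dp_reward"] = df["anxiety"] * df["dp_reward"]
        df["anxiety_x_p_punish"] = df["anxiety"] * df["p_punish"]
        terms += ["anxiety", "anxiety_x_dp_reward", "anxiety_x_p_punish"]
    for c in covariates:
        if df[c].dtype == object:
            df[c] = pd.factorize(df[c])[0].astype(float)
        terms.append(c)
    formula = "choice ~ " + " + ".join(terms)
    n_groups = df["participant"].nunique()

    if random_intercepts and n_groups >= 2:
        try:
            from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glmm = BinomialBayesMixedGLM.from_formula(
                    formula, {"participant": "0 + C(participant)"}, df)
                fit = glmm.fit_map()
            names = glmm.exog_names
            est = fit.fe_mean
            se = fit.fe_sd
            z = est / se
            p = 2 * sps.norm.sf(np.abs(z))
            coefs = pd.DataFrame({"term": names, "estimate": est, "se": se,
                                  "z": z, "p": p})
            ri_sd = float(np.exp(fit.vcp_mean[0]))
            return RegressionResult(coefs, "laplace_glmm", True, len(df),
                                    n_groups, ri_sd)
        except Exception:
            pass  # fall through to robust fixed-effects fit

    import statsmodels.formula.api as smf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.logit(formula, df)
        if random_intercepts and n_groups >= 2:
            res = model.fit(disp=0, cov_type="cluster",
                            cov_kwds={"groups": df["participant"]})
            method = "logit_cluster_robust_fallback"
        else:
            res = model.fit(disp=0)
            method = "logit"
    coefs = pd.DataFrame({
        "term": res.params.index, "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(), "z": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    return RegressionResult(coefs, method, bool(res.mle_retvals.get("converged", True)),
                            len(df), n_groups, None)


def kendall_perm_test(
    x, y, n_perm: int = 10_000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Kendall tau-b with a permutation p-value.

    The null distribution is built by shuffling the pairing of ``y`` against
    ``x``; the two-sided p doubles the smaller one-tailed
    ``(count + 1) / (n_perm + 1)`` estimate (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: tau undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tau = float(sps.kendalltau(x, y).statistic)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = sps.kendalltau(x, rng.permutation(y)).statistic
    p_ge = (np.sum(perm >= tau) + 1) / (n_perm + 1)
    p_le = (np.sum(perm <= tau) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    return tau, float(p)


def _as_param_frame(params) -> pd.DataFrame:
    if isinstance(params, pd.DataFrame):
        return params
    if isinstance(params, dict):
        return pd.DataFrame({k: [v] for k, v in params.items()})
    raise TypeError("params must be a DataFrame or a dict of parameter values")


def sensitivity_index(params) -> pd.Series:
    """Reward-punishment sensitivity index beta_r / beta_p per subject.

    Values > 1 indicate approach bias, < 1 avoidance bias.  Requires a model
    with split sensitivities.
    """
    df = _as_param_frame(params)
    if "beta_r" not in df or "beta_p" not in df:
        raise ValueError("sensitivity index needs split beta_r / beta_p")
    if np.any(df["beta_p"] <= 0):
        raise ValueError("beta_p must be positive")
    return df["beta_r"] / df["beta_p"]


def learning_rate_ratio(params) -> pd.Series:
    """Learning-rate analogue of the sensitivity index: alpha_r / alpha_p."""
    df = _as_param_frame(params)
    if "alpha_r" not in df or "alpha_p" not in df:
        raise ValueError("learning-rate ratio needs split alpha_r / alpha_p")
    if np.any(df["alpha_p"] <= 0):
        raise ValueError("alpha_p must be positive")
    return df["alpha_r"] / df["alpha_p"]


def welch_t(group_a, group_b) -> dict:
    """Welch's unequal-variance t-test with Cohen's d (pooled SD)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled_sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (np.mean(a) - np.mean(b)) / pooled_sd if pooled_sd > 0 else 0.0
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue), "cohen_d": float(d)}
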