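"""Synthetic cohorts with the statistical structure the analyses assume.

Each participant is a softmax Q-learning agent whose parameters are drawn
from a Gaussian population distribution on the untransformed scale.
Task-induced anxiety is planted as a linear function of the (negated,
standardised) reward-punishment sensitivity index and punishment learning
rate plus Gaussian noise, so that the cohort-level Kendall correlations
between anxiety and those quantities hit configurable targets
(defaults tau = -0.099 and -0.088).  Because anxiety's latent scale is
Gaussian and Kendall's tau is invariant to monotone transforms of the
parameters, the mixing weights follow in closed form from
``rho = sin(pi * tau / 2)``; no calibration search is needed.

The generator also emits everything the cleaning rules need (physical
response keys under randomised side placement, attention-check outcomes)
and can plant rule violators, so the full pipeline is testable end to end
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import MISSED, ModelSpec, ParamVector, SessionData, simulate_agent
from .fitting import PopulationPrior
from .task import LatentSchedule, TaskConfig, generate_accepted_schedule

__all__ = [
    "CohortConfig",
    "Cohort",
    "default_generating_prior",
    "generate_cohort",
    "generate_retest_cohort",
]

_WINNING_MODEL = "asym_lr_asym_sens"


def default_generating_prior(spec: ModelSpec | str = _WINNING_MODEL) -> PopulationPrior:
    """Population distribution the cohorts are simulated from.

    Centred on moderate reward learning (alpha_r ~ 0.45), slower punishment
    learning (alpha_p ~ 0.25), reward sensitivity ~5.5 and punishment
    sensitivity ~1.7, with untransformed SDs of 1.0 (rates) / 0.7
    (sensitivities).  The sensitivity balance is calibrated so simulated
    cohorts jointly approximate two observed cohort properties: a mean
    conflict-choice proportion near 0.5 (the punishment walk spends much of
    the task near 0.4-0.5, so equal sensitivities would make agents
    strongly avoidant) and parameter identifiability adequate for
    simulate-and-refit recovery.  Diagonal covariance.
    """
    spec = ModelSpec(spec) if isinstance(spec, str) else spec
    loc = {"alpha": -0.2, "alpha_r": -0.2, "alpha_p": -1.1,
           "beta": 1.0, "beta_r": 1.7, "beta_p": 0.55, "xi": -2.2}
    sd = {"alpha": 1.0, "alpha_r": 1.0, "alpha_p": 1.0,
          "beta": 0.7, "beta_r": 0.7, "beta_p": 0.7, "xi": 0.5}
    mean = np.array([loc[p] for p in spec.param_names])
    cov = np.diag([sd[p] ** 2 for p in spec.param_names])
    return PopulationPrior(mean, cov)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults follow the reference study design (200 trials,
    anxiety slider 0-50 with cohort mean 21 / SD 14, four latent schedule
    sets, planted anxiety effect sizes tau = -0.099 on the sensitivity index
    and -0.088 on the punishment learning rate).
    """

    n_participants: int = 500
    n_trials: int = 200
    model: str = _WINNING_MODEL
    tau_index: float = -0.099
    tau_alpha_p: float = -0.088
    anxiety_mean: float = 21.0
    anxiety_sd: float = 14.0
    missed_rate: float = 0.01
    n_schedules: int = 4
    sex_effect_beta_r: float = -0.2   # untransformed shift for females
    n_violators_attention: int = 0
    n_violators_keys: int = 0
    n_violators_missed: int = 0
    retest_correlation: float | None = None
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not (-1 < self.tau_index < 1 and -1 < self.tau_alpha_p < 1):
            raise ValueError("effect-size targets must lie in (-1, 1)")
        w1 = np.sin(np.pi * self.tau_index / 2)
        w2 = np.sin(np.pi * self.tau_alpha_p / 2)
        if w1 ** 2 + w2 ** 2 >= 1:
            raise ValueError("infeasible effect-size combination: no noise "
                             "variance left for the anxiety plant")
        if self.retest_correlation is not None and not (-1 <= self.retest_correlation <= 1):
            # the closed endpoints are valid degenerate cases (identical /
            # sign-flipped parameters across sessions)
            raise ValueError("retest correlation must lie in [-1, 1]")
        object.__setattr__(self, "task", replace(self.task, n_trials=self.n_trials))


@dataclass
class Cohort:
    """Everything one synthetic study produces."""

    sessions: list[SessionData]
    covariates: pd.DataFrame          # one row per participant
    schedules: dict[str, LatentSchedule]
    ground_truth: pd.DataFrame        # true parameters + planted violations
    attention_results: dict[str, int]  # participant -> missed attention checks
    config: CohortConfig


def _planted_anxiety(h: np.ndarray, spec: ModelSpec, config: CohortConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent anxiety from negated index / punishment-LR signals + noise."""
    names = list(spec.param_names)
    h_index = h[:, names.index("beta_r")] - h[:, names.index("beta_p")]
    h_ap = h[:, names.index("alpha_p")]

    def z(v):
        return (v - v.mean()) / v.std(ddof=0)

    # Greiner's relation: rho = sin(pi * tau / 2); the target tau's sign
    # rides along, so a negative tau yields a negative weight on z(h).
    w1 = np.sin(np.pi * config.tau_index / 2)
    w2 = np.sin(np.pi * config.tau_alpha_p / 2)
    sigma = np.sqrt(1.0 - w1 ** 2 - w2 ** 2)
    latent = w1 * z(h_index) + w2 * z(h_ap) + sigma * rng.standard_normal(len(h))
    anxiety = np.clip(np.round(config.anxiety_mean + config.anxiety_sd * latent), 0, 50)
    return anxiety.astype(int), latent


def _plant_key_run(session: SessionData, rng: np.random.Generator,
                   run_length: int = 25) -> None:
    """Overwrite a block of trials with one repeated response key."""
    start = int(rng.integers(0, session.n_trials - run_length))
    key = int(rng.integers(0, 2))
    sl = slice(start, start + run_length)
    session.keys[sl] = key
    # the chosen option on those trials is whichever sat on that side
    forced = np.where(session.conflict_side[sl] == key, 1, 0).astype(np.int8)
    session.choices[sl] = forced
    # outcomes for forced trials: redraw at the scheduled probabilities is
    # unnecessary for the cleaning tests; keep existing outcomes but repair
    # missed codes
    miss = session.rewards[sl] < 0
    session.rewards[sl] = np.where(miss, 0, session.rewards[sl])
    session.punishments[sl] = np.where(miss, 0, session.punishments[sl])


def _plant_missed(session: SessionData, rng: np.random.Generator,
                  n_missed: int = 25) -> None:
    idx = rng.choice(session.n_trials, size=n_missed, replace=False)
    session.choices[idx] = MISSED
    session.rewards[idx] = -1
    session.punishments[idx] = -1
    session.keys[idx] = -1


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate a full cohort: parameters, anxiety, behaviour, violations.

    Fully deterministic given ``config.seed``; the ground-truth table is for
    validation only and is never read by the analysis pipeline.
    """
    config = config or CohortConfig()
    spec = ModelSpec(config.model)
    rng = np.random.default_rng(config.seed)
    prior = default_generating_prior(spec)
    n = config.n_participants

    h = prior.sample(n, rng)
    names = list(spec.param_names)
    sex = np.where(rng.random(n) < 0.55, "female", "male")
    if "beta_r" in names and config.sex_effect_beta_r:
        h[sex == "female", names.index("beta_r")] += config.sex_effect_beta_r
    anxiety, anx_latent = _planted_anxiety(h, spec, config, rng)

    # additional covariates, mildly coupled to the anxiety latent
    def slider(mean, sd, couple=0.3):
        raw = mean + sd * (couple * anx_latent
                           + np.sqrt(1 - couple ** 2) * rng.standard_normal(n))
        return np.clip(np.round(raw), 0, 50).astype(int)

    unpleasantness = slider(31.7, 12.8)
    gad7 = np.clip(np.round(5 + 4 * (0.35 * anx_latent
                   + np.sqrt(1 - 0.35 ** 2) * rng.standard_normal(n))), 0, 21).astype(int)
    phq8 = np.clip(np.round(6 + 5 * (0.3 * anx_latent
                   + np.sqrt(1 - 0.3 ** 2) * rng.standard_normal(n))), 0, 24).astype(int)
    beaq = np.clip(np.round(34 + 9 * (0.3 * anx_latent
                   + np.sqrt(1 - 0.3 ** 2) * rng.standard_normal(n))), 15, 90).astype(int)
    age = rng.integers(18, 61, size=n)

    schedule_pool = [generate_accepted_schedule(config.task, rng)
                     for _ in range(config.n_schedules)]
    sched_idx = rng.integers(0, config.n_schedules, size=n)

    ids = [f"p{i:04d}" for i in range(n)]
    sessions, schedules = [], {}
    for i, pid in enumerate(ids):
        sched = schedule_pool[sched_idx[i]]
        schedules[pid] = sched
        s = simulate_agent(sched, spec, ParamVector(spec, h[i]), seed=rng,
                           missed_rate=config.missed_rate, participant_id=pid)
        s.covariates = {
            "anxiety": int(anxiety[i]), "unpleasantness": int(unpleasantness[i]),
            "gad7": int(gad7[i]), "phq8": int(phq8[i]), "beaq": int(beaq[i]),
            "age": int(age[i]), "sex": str(sex[i]),
        }
        sessions.append(s)

    # planted rule violators, disjoint sets from the end of the id list
    n_att, n_key, n_miss = (config.n_violators_attention,
                            config.n_violators_keys, config.n_violators_missed)
    if n_att + n_key + n_miss > n:
        raise ValueError("more planted violators than participants")
    viol_att = set(ids[n - n_att:]) if n_att else set()
    viol_key = set(ids[n - n_att - n_key:n - n_att]) if n_key else set()
    viol_miss = set(ids[n - n_att - n_key - n_miss:n - n_att - n_key]) if n_miss else set()
    attention_results = {pid: 0 for pid in ids}
    for pid in viol_att:
        attention_results[pid] = 2
    by_id = {s.participant_id: s for s in sessions}
    for pid in viol_key:
        _plant_key_run(by_id[pid], rng)
    for pid in viol_miss:
        _plant_missed(by_id[pid], rng)

    truth = pd.DataFrame(h, columns=[f"h_{p}" for p in names])
    truth.insert(0, "participant_id", ids)
    for j, p in enumerate(names):
        col = h[:, j]
        truth[p] = np.exp(col) if p.startswith("beta") else 1 / (1 + np.exp(-col))
    if "beta_r" in names:
        truth["sensitivity_index"] = truth["beta_r"] / truth["beta_p"]
    truth["anxiety"] = anxiety
    truth["schedule"] = sched_idx
    truth["violator"] = [
        "attention" if pid in viol_att else
        "keys" if pid in viol_key else
        "missed" if pid in viol_miss else "" for pid in ids
    ]

    covariates = pd.DataFrame({
        "participant_id": ids, "anxiety": anxiety,
        "unpleasantness": unpleasantness, "gad7": gad7, "phq8": phq8,
        "beaq": beaq, "age": age, "sex": sex,
    })
    return Cohort(sessions, covariates, schedules, truth, attention_results, config)


def generate_retest_cohort(config: CohortConfig) -> tuple[Cohort, Cohort]:
    """Two-session dataset with correlated parameters and fresh schedules.

    Session-2 untransformed parameters are drawn with the configured
    cross-session correlation per parameter
    (``h2 = mu + rho (h1 - mu) + sqrt(1 - rho^2) * sd * eps``); session 2
    uses newly generated accepted schedules, as in the retest study arm.
    """
    if config.retest_correlation is None:
        raise ValueError("config.retest_correlation must be set")
    rho = config.retest_correlation
    cohort1 = generate_cohort(config)
    spec = ModelSpec(config.model)
    prior = default_generating_prior(spec)
    names = list(spec.param_names)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    h1 = cohort1.ground_truth[[f"h_{p}" for p in names]].to_numpy()
    sd = np.sqrt(np.diag(prior.cov))
    eps = rng.standard_normal(h1.shape)
    h2 = prior.mean + rho * (h1 - prior.mean) + np.sqrt(1 - rho ** 2) * sd * eps

    schedule_pool = [generate_accepted_schedule(config.task, rng)
                     for _ in range(config.n_schedules)]
    sched_idx = rng.integers(0, config.n_schedules, size=len(h2))
    sessions2, schedules2 = [], {}
    ids = list(cohort1.ground_truth["participant_id"])
    for i, pid in enumerate(ids):
        sched = schedule_pool[sched_idx[i]]
        schedules2[pid] = sched
        s = simulate_agent(sched, spec, ParamVector(spec, h2[i]), seed=rng,
                           missed_rate=config.missed_rate, participant_id=pid,
                           session=2)
        s.covariates = dict(cohort1.sessions[i].covariates)
        sessions2.append(s)

    truth2 = pd.DataFrame(h2, columns=[f"h_{p}" for p in names])
    truth2.insert(0, "participant_id", ids)
    for j, p in enumerate(names):
        col = h2[:, j]
        truth2[p] = np.exp(col) if p.startswith("beta") else 1 / (1 + np.exp(-col))
    if "beta_r" in names:
        truth2["sensitivity_index"] = truth2["beta_r"] / truth2["beta_p"]
    cohort2 = Cohort(sessions2, cohort1.covariates.copy(), schedules2, truth2,
                     dict(cohort1.attention_results), config)
    return cohort1, cohort2
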