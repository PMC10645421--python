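"""Reinforcement-learning model family for the approach-avoidance bandit.

Participants are modelled as tracking four outcome-probability estimates
(Q-values): reward and punishment probabilities for each option.  After each
non-missed trial the chosen option's estimates are updated by the
Rescorla-Wagner delta rule

    Q <- Q + alpha * (outcome - Q)

and choices follow a softmax over action weights that trade estimated reward
probability against estimated punishment probability,

    W = beta_r * Q_r - beta_p * Q_p        (asymmetric sensitivities)
    W = beta  * (Q_r - Q_p)                (single sensitivity)

optionally mixed with a uniform lapse:  P = (1 - xi) * softmax(W) + xi / 2.

Six model variants factorially share or split the learning rates
(alpha / alpha_r, alpha_p) and outcome sensitivities (beta / beta_r, beta_p);
single-outcome variants drop the irrelevant outcome stream entirely.  Each
variant also exists with a lapse term.  Parameters are estimated on an
unbounded (untransformed) scale and mapped to their natural ranges by a
sigmoid (rates, lapse) or an exponential (sensitivities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ModelSpec",
    "ParamVector",
    "SessionData",
    "MODEL_NAMES",
    "update_q",
    "action_weights",
    "choice_probs",
    "negative_log_likelihood",
    "simulate_agent",
    "sigmoid",
    "logit",
]

# choice codes used throughout
CONFLICT, SAFE, MISSED = 1, 0, -1

_BASE_PARAMS = {
    "reward_only": ("alpha_r", "beta_r"),
    "punish_only": ("alpha_p", "beta_p"),
    "sym": ("alpha", "beta"),
    "asym_lr": ("alpha_r", "alpha_p", "beta"),
    "asym_sens": ("alpha", "beta_r", "beta_p"),
    "asym_lr_asym_sens": ("alpha_r", "alpha_p", "beta_r", "beta_p"),
}

MODEL_NAMES = tuple(_BASE_PARAMS) + tuple(f"{n}_lapse" for n in _BASE_PARAMS)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass(frozen=True)
class ModelSpec:
    """One row of the model family: which parameters the model uses."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {MODEL_NAMES}"
            )

    @property
    def has_lapse(self) -> bool:
        return self.name.endswith("_lapse")

    @property
    def base_name(self) -> str:
        return self.name[:-6] if self.has_lapse else self.name

    @property
    def param_names(self) -> tuple[str, ...]:
        base = _BASE_PARAMS[self.base_name]
        return base + (("xi",) if self.has_lapse else ())

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def transform(self, untransformed: np.ndarray) -> dict[str, float]:
        """Map unbounded values to natural scale (sigmoid / exp)."""
        h = np.asarray(untransformed, dtype=float)
        if h.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} values, got {h.shape}")
        out = {}
        for name, val in zip(self.param_names, h):
            out[name] = float(np.exp(val)) if name.startswith("beta") else float(sigmoid(val))
        return out

    def untransform(self, transformed: dict[str, float]) -> np.ndarray:
        """Inverse of :meth:`transform` (log / logit)."""
        vals = []
        for name in self.param_names:
            v = transformed[name]
            vals.append(np.log(v) if name.startswith("beta") else logit(v))
        return np.array(vals, dtype=float)

    def kernel_params(self, transformed: dict[str, float]) -> tuple[float, ...]:
        """Map model parameters onto the shared (ar, ap, br, bp, xi) kernel.

        Single-outcome models zero out the irrelevant stream; symmetric
        models tie the split parameters.
        """
        p = transformed
        base = self.base_name
        if base == "reward_only":
            ar, ap, br, bp = p["alpha_r"], 0.0, p["beta_r"], 0.0
        elif base == "punish_only":
            ar, ap, br, bp = 0.0, p["alpha_p"], 0.0, p["beta_p"]
        elif base == "sym":
            ar = ap = p["alpha"]
            br = bp = p["beta"]
        elif base == "asym_lr":
            ar, ap = p["alpha_r"], p["alpha_p"]
            br = bp = p["beta"]
        elif base == "asym_sens":
            ar = ap = p["alpha"]
            br, bp = p["beta_r"], p["beta_p"]
        else:  # asym_lr_asym_sens
            ar, ap, br, bp = p["alpha_r"], p["alpha_p"], p["beta_r"], p["beta_p"]
        xi = p.get("xi", 0.0)
        return ar, ap, br, bp, xi

    @property
    def kernel_slots(self) -> tuple[tuple[int, ...], ...]:
        """Which (ar, ap, br, bp, xi) kernel slots each parameter feeds.

        Shared parameters feed several slots (e.g. a single learning rate
        drives both the reward and punishment updates); used to chain
        kernel-space gradients back to the model's parameter vector.
        """
        slots = {"alpha_r": (0,), "alpha_p": (1,), "alpha": (0, 1),
                 "beta_r": (2,), "beta_p": (3,), "beta": (2, 3), "xi": (4,)}
        return tuple(slots[p] for p in self.param_names)


@dataclass(frozen=True)
class ParamVector:
    """Parameter values for one model, stored on the untransformed scale."""

    spec: ModelSpec
    untransformed: np.ndarray

    def __post_init__(self) -> None:
        h = np.atleast_1d(np.asarray(self.untransformed, dtype=float))
        if h.shape != (self.spec.n_params,):
            raise ValueError(
                f"{self.spec.name} needs {self.spec.n_params} values, got {h.shape}"
            )
        object.__setattr__(self, "untransformed", h)

    @classmethod
    def from_transformed(cls, spec: ModelSpec, **values: float) -> "ParamVector":
        return cls(spec, spec.untransform(values))

    @property
    def transformed(self) -> dict[str, float]:
        return self.spec.transform(self.untransformed)

    def kernel_params(self) -> tuple[float, ...]:
        return self.spec.kernel_params(self.transformed)


@dataclass
class SessionData:
    """One participant-session: trial-wise choices, outcomes, covariates.

    ``choices`` uses codes 1 = conflict, 0 = safe, -1 = missed.  Missed
    trials carry no outcomes (coded -1) and never update Q-values.
    ``keys`` (0 = left, 1 = right) and ``conflict_side`` record the physical
    response and the randomised screen side of the conflict option; they are
    only needed by the data-cleaning rules.
    """

    participant_id: str
    session: int
    choices: np.ndarray
    rewards: np.ndarray
    punishments: np.ndarray
    keys: np.ndarray | None = None
    conflict_side: np.ndarray | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int8)
        self.rewards = np.asarray(self.rewards, dtype=np.int8)
        self.punishments = np.asarray(self.punishments, dtype=np.int8)
        n = len(self.choices)
        if len(self.rewards) != n or len(self.punishments) != n:
            raise ValueError("choices/rewards/punishments lengths differ")
        missed = self.choices == MISSED
        if np.any(self.rewards[missed] != -1) or np.any(self.punishments[missed] != -1):
            raise ValueError("missed trials must carry no outcomes (-1)")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.choices != MISSED))


# ---------------------------------------------------------------------------
# numba kernels — shared 5-parameter core (ar, ap, br, bp, xi)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _nll_kernel(choices, rewards, punishments, ar, ap, br, bp, xi, q_init):
    qrc = q_init
    qrs = q_init
    qpc = q_init
    qps = q_init
    nll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        wc = br * qrc - bp * qpc
        ws = br * qrs - bp * qps
        m = wc if wc > ws else ws
        ec = np.exp(wc - m)
        es = np.exp(ws - m)
        pc = ec / (ec + es)
        if xi > 0.0:
            pc = (1.0 - xi) * pc + 0.5 * xi
        p = pc if c == 1 else 1.0 - pc
        if p < 1e-300:
            p = 1e-300
        nll -= np.log(p)
        if c == 1:
            qrc += ar * (rewards[t] - qrc)
            qpc += ap * (punishments[t] - qpc)
        else:
            qrs += ar * (rewards[t] - qrs)
            qps += ap * (punishments[t] - qps)
    return nll


@njit(cache=False)
def _nll_grad_kernel(choices, rewards, punishments, ar, ap, br, bp, xi, q_init):
    """NLL and its gradient w.r.t. (ar, ap, br, bp, xi), forward-mode.

    Q-values depend only on their own learning rate, so four sensitivity
    scalars suffice.
    """
    qrc = q_init; qrs = q_init; qpc = q_init; qps = q_init
    d_qrc = 0.0; d_qrs = 0.0   # d q_r / d ar
    d_qpc = 0.0; d_qps = 0.0   # d q_p / d ap
    nll = 0.0
    g = np.zeros(5)
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        diff = br * (qrc - qrs) - bp * (qpc - qps)
        sm = 1.0 / (1.0 + np.exp(-diff))
        dsm = sm * (1.0 - sm)
        # d diff / d (ar, ap, br, bp)
        dd_ar = br * (d_qrc - d_qrs)
        dd_ap = -bp * (d_qpc - d_qps)
        dd_br = qrc - qrs
        dd_bp = -(qpc - qps)
        pc = (1.0 - xi) * sm + 0.5 * xi
        scale = (1.0 - xi) * dsm
        dp_ar = scale * dd_ar
        dp_ap = scale * dd_ap
        dp_br = scale * dd_br
        dp_bp = scale * dd_bp
        dp_xi = 0.5 - sm
        if c == 1:
            p = pc
            sgn = 1.0
        else:
            p = 1.0 - pc
            sgn = -1.0
        if p < 1e-300:
            p = 1e-300
        nll -= np.log(p)
        inv = sgn / p
        g[0] -= inv * dp_ar
        g[1] -= inv * dp_ap
        g[2] -= inv * dp_br
        g[3] -= inv * dp_bp
        g[4] -= inv * dp_xi
        if c == 1:
            d_qrc = d_qrc * (1.0 - ar) + (rewards[t] - qrc)
            d_qpc = d_qpc * (1.0 - ap) + (punishments[t] - qpc)
            qrc += ar * (rewards[t] - qrc)
            qpc += ap * (punishments[t] - qpc)
        else:
            d_qrs = d_qrs * (1.0 - ar) + (rewards[t] - qrs)
            d_qps = d_qps * (1.0 - ap) + (0.0 - qps)
            qrs += ar * (rewards[t] - qrs)
            qps += ap * (0.0 - qps)
    return nll, g


@njit(cache=False)
def _nll_many(choices, rewards, punishments, params, q_init):
    """NLL for many (ar, ap, br, bp, xi) rows on one session."""
    out = np.empty(params.shape[0])
    for i in range(params.shape[0]):
        out[i] = _nll_kernel(
            choices, rewards, punishments,
            params[i, 0], params[i, 1], params[i, 2], params[i, 3], params[i, 4],
            q_init,
        )
    return out


@njit(cache=False)
def _simulate_kernel(prc, prs, ppc, ar, ap, br, bp, xi, q_init,
                     u_choice, u_rew, u_pun, missed_mask):
    n = prc.shape[0]
    choices = np.empty(n, dtype=np.int8)
    rewards = np.empty(n, dtype=np.int8)
    punishments = np.empty(n, dtype=np.int8)
    qrc = q_init
    qrs = q_init
    qpc = q_init
    qps = q_init
    for t in range(n):
        if missed_mask[t]:
            choices[t] = -1
            rewards[t] = -1
            punishments[t] = -1
            continue
        wc = br * qrc - bp * qpc
        ws = br * qrs - bp * qps
        m = wc if wc > ws else ws
        ec = np.exp(wc - m)
        es = np.exp(ws - m)
        pc = ec / (ec + es)
        if xi > 0.0:
            pc = (1.0 - xi) * pc + 0.5 * xi
        if u_choice[t] < pc:
            choices[t] = 1
            r = 1 if u_rew[t] < prc[t] else 0
            p = 1 if u_pun[t] < ppc[t] else 0
            rewards[t] = r
            punishments[t] = p
            qrc += ar * (r - qrc)
            qpc += ap * (p - qpc)
        else:
            choices[t] = 0
            r = 1 if u_rew[t] < prs[t] else 0
            rewards[t] = r
            punishments[t] = 0
            qrs += ar * (r - qrs)
            qps += ap * (0 - qps)
    return choices, rewards, punishments


# ---------------------------------------------------------------------------
# reference-scale operations (also the readable spec of the kernels)
# ---------------------------------------------------------------------------

def update_q(q: float, outcome: int, alpha: float) -> float:
    """Rescorla-Wagner delta-rule update of a probability estimate."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome}")
    return q + alpha * (outcome - q)


def action_weights(qstate, spec: ModelSpec, params: ParamVector) -> np.ndarray:
    """Action weights (conflict, safe) from Q-values.

    ``qstate`` is (Q_r_conflict, Q_r_safe, Q_p_conflict, Q_p_safe).
    """
    qrc, qrs, qpc, qps = qstate
    ar, ap, br, bp, xi = params.kernel_params()
    return np.array([br * qrc - bp * qpc, br * qrs - bp * qps])


def choice_probs(weights, lapse: float | None = None) -> np.ndarray:
    """Softmax choice probabilities over two options, with optional lapse."""
    w = np.asarray(weights, dtype=float)
    w = w - w.max()
    e = np.exp(w)
    p = e / e.sum()
    if lapse:
        p = (1.0 - lapse) * p + lapse / len(w)
    return p


def negative_log_likelihood(
    session: SessionData,
    spec: ModelSpec,
    params: ParamVector | np.ndarray,
    q_init: float = 0.5,
) -> float:
    """Summed -ln P(choice) over non-missed trials, in nats.

    Missed trials contribute zero likelihood and trigger no Q-update.
    """
    if session.n_trials == 0:
        raise ValueError("empty session")
    if not isinstance(params, ParamVector):
        params = ParamVector(spec, params)
    ar, ap, br, bp, xi = params.kernel_params()
    return float(
        _nll_kernel(
            session.choices, session.rewards, session.punishments,
            ar, ap, br, bp, xi, q_init,
        )
    )


def simulate_agent(
    schedule,
    spec: ModelSpec,
    params: ParamVector | np.ndarray,
    seed: int | np.random.Generator = 0,
    q_init: float = 0.5,
    missed_rate: float = 0.0,
    participant_id: str = "sim",
    session: int = 1,
) -> SessionData:
    """Generative run of one agent on a latent schedule.

    Each trial: softmax choice from current Q-values, independent Bernoulli
    outcomes at the scheduled probabilities, delta-rule update of the chosen
    option's estimates.  A configurable fraction of trials is emitted as
    missed ('too slow') with no outcome.  Also emits the randomised screen
    side of the conflict option and the physical response key, which the
    data-cleaning rules operate on.
    """
    if not isinstance(params, ParamVector):
        params = ParamVector(spec, params)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = schedule.n_trials
    u_choice = rng.random(n)
    u_rew = rng.random(n)
    u_pun = rng.random(n)
    missed_mask = rng.random(n) < missed_rate
    conflict_side = rng.integers(0, 2, size=n).astype(np.int8)  # 0 left, 1 right
    ar, ap, br, bp, xi = params.kernel_params()
    choices, rewards, punishments = _simulate_kernel(
        schedule.p_reward_conflict, schedule.p_reward_safe,
        schedule.p_punish_conflict,
        ar, ap, br, bp, xi, q_init,
        u_choice, u_rew, u_pun, missed_mask,
    )
    keys = np.where(
        choices == MISSED,
        np.int8(-1),
        np.where(choices == CONFLICT, conflict_side, 1 - conflict_side),
    ).astype(np.int8)
    return SessionData(
        participant_id=participant_id,
        session=session,
        choices=choices,
        rewards=rewards,
        punishments=punishments,
        keys=keys,
        conflict_side=conflict_side,
    )
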