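"""Restless two-armed approach-avoidance bandit environment.

The task presents a *conflict* option (probabilistic reward and probabilistic
punishment) against a *safe* option (probabilistic reward only, punishment
probability fixed at zero).  Latent outcome probabilities follow decaying
Gaussian random walks

    p(t+1) = lambda * p(t) + (1 - lambda) * theta + e,   e ~ N(0, sd^2)

with decay ``lambda`` pulling each walk towards the centre ``theta``.  The
safe option's reward series is scaled down by a constant factor so that the
conflict option is more rewarding on average.  Candidate schedules are
accepted only if all pairwise cross-correlations among the three varying
series stay below a threshold, so that reward and punishment signals are
statistically dissociable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ScheduleError(ValueError):
    """Raised for invalid task configurations or failed schedule generation."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the latent outcome-probability walks.

    Defaults: 200 trials, decay 0.97 towards
    centre 0.5, per-trial Gaussian noise SD 0.04, safe-option reward series
    scaled by 0.7, walks initialised at 0.7 (conflict reward), 0.5
    (safe reward, pre-scaling -> 0.35 printed), 0.2 (conflict punishment),
    and a 0.3 cross-correlation screen.
    """

    n_trials: int = 200
    decay: float = 0.97
    centre: float = 0.5
    noise_sd: float = 0.04
    safe_reward_scale: float = 0.7
    init_reward_conflict: float = 0.7
    init_reward_safe_prescale: float = 0.5
    init_punish_conflict: float = 0.2
    cross_corr_threshold: float = 0.3
    clip_bounds: tuple[float, float] = (0.01, 0.99)
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.clip_bounds
        if not (0 < self.decay <= 1):
            raise ScheduleError(f"decay must be in (0, 1], got {self.decay}")
        if not (0 <= self.centre <= 1):
            raise ScheduleError(f"centre must be in [0, 1], got {self.centre}")
        if self.noise_sd < 0:
            raise ScheduleError("noise_sd must be non-negative")
        if not (0 < self.safe_reward_scale <= 1):
            raise ScheduleError("safe_reward_scale must be in (0, 1]")
        if not (0 <= lo < hi <= 1):
            raise ScheduleError(f"invalid clip_bounds {self.clip_bounds}")
        if self.n_trials < 1:
            raise ScheduleError("n_trials must be >= 1")


@dataclass(frozen=True)
class LatentSchedule:
    """Per-trial latent outcome probabilities for the two options.

    ``p_punish_safe`` is identically zero: the safe option never punishes.
    """

    p_reward_conflict: np.ndarray
    p_reward_safe: np.ndarray
    p_punish_conflict: np.ndarray
    p_punish_safe: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_rejections: int = 0

    def __post_init__(self) -> None:
        if self.p_punish_safe is None:
            object.__setattr__(
                self, "p_punish_safe", np.zeros_like(self.p_reward_conflict)
            )
        series = (
            self.p_reward_conflict,
            self.p_reward_safe,
            self.p_punish_conflict,
            self.p_punish_safe,
        )
        n = len(series[0])
        if any(len(s) != n for s in series):
            raise ScheduleError("all probability series must share one length")
        for s in series:
            if np.any((np.asarray(s) < 0) | (np.asarray(s) > 1)):
                raise ScheduleError("schedule probabilities must lie in [0, 1]")
        if np.any(self.p_punish_safe != 0):
            raise ScheduleError("safe-option punishment probability must be 0")

    @property
    def n_trials(self) -> int:
        return len(self.p_reward_conflict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "p_reward_conflict": self.p_reward_conflict,
                "p_reward_safe": self.p_reward_safe,
                "p_punish_conflict": self.p_punish_conflict,
                "p_punish_safe": self.p_punish_safe,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LatentSchedule":
        df = df.sort_values("trial")
        return cls(
            p_reward_conflict=df["p_reward_conflict"].to_numpy(float),
            p_reward_safe=df["p_reward_safe"].to_numpy(float),
            p_punish_conflict=df["p_punish_conflict"].to_numpy(float),
            p_punish_safe=df["p_punish_safe"].to_numpy(float),
        )


def _single_walk(
    p0: float, config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = config.clip_bounds
    p = np.empty(config.n_trials)
    p[0] = p0
    noise = rng.normal(0.0, config.noise_sd, size=config.n_trials - 1)
    for t in range(config.n_trials - 1):
        nxt = config.decay * p[t] + (1 - config.decay) * config.centre + noise[t]
        p[t + 1] = min(max(nxt, lo), hi)
    return p


def generate_walk(
    config: TaskConfig | None = None, seed: int | np.random.Generator = 0
) -> LatentSchedule:
    """Generate one (unscreened) latent schedule.

    The safe-reward walk is generated from its pre-scale initial value and
    the whole series is then multiplied by ``safe_reward_scale``, so the
    series starts at 0.35 under defaults.  Values are clipped each step.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    prc = _single_walk(config.init_reward_conflict, config, rng)
    prs = _single_walk(config.init_reward_safe_prescale, config, rng)
    ppc = _single_walk(config.init_punish_conflict, config, rng)
    return LatentSchedule(
        p_reward_conflict=prc,
        p_reward_safe=prs * config.safe_reward_scale,
        p_punish_conflict=ppc,
    )


def schedule_correlations(schedule: LatentSchedule) -> dict[str, float]:
    """Pairwise Pearson correlations among the three varying series.

    The identically-zero safe-punishment series is excluded (its correlation
    is undefined).  Returned keys name the pairs; diagnostics also report the
    signed and absolute means across pairs.
    """
    series = {
        "reward_conflict": schedule.p_reward_conflict,
        "reward_safe": schedule.p_reward_safe,
        "punish_conflict": schedule.p_punish_conflict,
    }
    names = list(series)
    out: dict[str, float] = {}
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = series[names[i]], series[names[j]]
            if np.std(a) == 0 or np.std(b) == 0:
                raise ScheduleError("constant series: correlation undefined")
            out[f"{names[i]}:{names[j]}"] = float(np.corrcoef(a, b)[0, 1])
    vals = np.array(list(out.values()))
    out["mean_signed"] = float(vals.mean())
    out["mean_abs"] = float(np.abs(vals).mean())
    return out


def screen_schedule(schedule: LatentSchedule, threshold: float = 0.3) -> bool:
    """Accept a schedule iff max pairwise |r| among varying series < threshold."""
    corrs = schedule_correlations(schedule)
    pair_vals = [v for k, v in corrs.items() if ":" in k]
    return max(abs(v) for v in pair_vals) < threshold


def generate_accepted_schedule(
    config: TaskConfig | None = None, seed: int | np.random.Generator = 0
) -> LatentSchedule:
    """Rejection-sample walks until one passes the cross-correlation screen."""
    config = config or TaskConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for attempt in range(config.max_attempts):
        sched = generate_walk(config, rng)
        if screen_schedule(sched, config.cross_corr_threshold):
            return replace(sched, n_rejections=attempt)
    raise ScheduleError(
        f"no accepted schedule within {config.max_attempts} attempts"
    )


def sample_outcomes(
    schedule: LatentSchedule,
    option: str,
    t: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw (reward, punishment) for choosing ``option`` on trial ``t``.

    Outcome dimensions are independent Bernoulli draws at the scheduled
    probabilities; the safe option never yields punishment.
    """
    if not 0 <= t < schedule.n_trials:
        raise IndexError(f"trial {t} out of range for {schedule.n_trials}-trial schedule")
    if option == "conflict":
        pr, pp = schedule.p_reward_conflict[t], schedule.p_punish_conflict[t]
    elif option == "safe":
        pr, pp = schedule.p_reward_safe[t], schedule.p_punish_safe[t]
    else:
        raise ValueError(f"option must be 'conflict' or 'safe', got {option!r}")
    reward = int(rng.random() < pr)
    punishment = int(rng.random() < pp)
    return reward, punishment
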