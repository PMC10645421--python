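"""Split-half and test-retest reliability of task measures and parameters.

Model-agnostic measures use ICC(3,1) (two-way mixed, consistency, single
measures) or Pearson correlations with Spearman-Brown correction for split
halves.  Model parameters use the joint-model approach: one hierarchical fit
whose per-subject parameter vector stacks both sessions, with a full
population covariance; each parameter's cross-session covariance converts
directly to a Pearson r.  Fitting both sessions jointly avoids the
attenuation that separate fits suffer from estimation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import HierarchicalRLModel, HierarchicalRLResults
from .models import SessionData

__all__ = [
    "ReliabilityReport",
    "reliability_band",
    "split_sessions",
    "icc31",
    "spearman_brown",
    "joint_model_reliability",
    "practice_effects",
]


def reliability_band(r: float) -> str:
    """Conventional qualitative bands for reliability coefficients."""
    if r < 0.40:
        return "poor"
    if r < 0.60:
        return "fair"
    if r <= 0.75:
        return "good"
    return "excellent"


@dataclass
class ReliabilityReport:
    measure: str
    method: str                 # pearson | icc31 | model_derived_r
    estimate: float
    corrected: float | None = None  # Spearman-Brown, where applicable

    @property
    def band(self) -> str:
        return reliability_band(self.estimate)

    def to_row(self) -> dict:
        return {"measure": self.measure, "method": self.method,
                "estimate": self.estimate, "corrected": self.corrected,
                "band": self.band}


def split_sessions(session: SessionData) -> tuple[SessionData, SessionData]:
    """Split one session into first/second-half pseudo-sessions.

    Odd trial counts put the extra trial in the second half (floor split).
    """
    n = session.n_trials
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    half = n // 2

    def _slice(lo, hi, label):
        return SessionData(
            participant_id=session.participant_id,
            session=label,
            choices=session.choices[lo:hi],
            rewards=session.rewards[lo:hi],
            punishments=session.punishments[lo:hi],
            keys=None if session.keys is None else session.keys[lo:hi],
            conflict_side=None if session.conflict_side is None else session.conflict_side[lo:hi],
            covariates=dict(session.covariates),
        )

    return _slice(0, half, 1), _slice(half, n, 2)


def icc31(x_session1, x_session2) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single measures.

    ``(MS_rows - MS_error) / (MS_rows + (k - 1) MS_error)`` with k = 2
    raters/sessions.  Consistency ICC ignores additive session shifts.
    """
    a = np.asarray(x_session1, dtype=float)
    b = np.asarray(x_session2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("paired 1-D data with n >= 3 required")
    X = np.column_stack([a, b])
    n, k = X.shape
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    grand = X.mean()
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows + (k - 1) * ms_err <= 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def spearman_brown(r: float) -> float:
    """Project a half-length reliability to full length: 2r / (1 + r)."""
    if not -1 < r < 1:
        if r == 1.0:
            return 1.0
        raise ValueError(f"r must be in (-1, 1), got {r}")
    return 2.0 * r / (1.0 + r)


def joint_model_reliability(
    cohort_s1: list[SessionData],
    cohort_s2: list[SessionData],
    spec,
    fit_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, HierarchicalRLResults]:
    """Cross-session parameter reliability from one joint hierarchical fit.

    Stacks each participant's two sessions into a single 2k-dimensional
    parameter vector with a full 2k x 2k population covariance; reliability
    of parameter j is ``cov(j, j') / sqrt(var(j) var(j'))`` between the two
    session blocks.  Participants missing either session are excluded (their
    ids are recorded in ``table.attrs['excluded']``).  Applies equally to
    split halves or genuine retest sessions.
    """
    by_id_1 = {s.participant_id: s for s in cohort_s1}
    by_id_2 = {s.participant_id: s for s in cohort_s2}
    common = [pid for pid in by_id_1 if pid in by_id_2]
    excluded = sorted(set(by_id_1) ^ set(by_id_2))
    if len(common) < 2:
        raise ValueError("need >= 2 participants with both sessions")
    subjects = [[by_id_1[pid], by_id_2[pid]] for pid in common]
    model = HierarchicalRLModel(subjects, spec)
    res = model.fit(**(fit_kwargs or {}))
    table = res.cross_session_reliability()
    table["band"] = [reliability_band(r) for r in table["reliability_r"]]
    table.attrs["excluded"] = excluded
    return table, res


def practice_effects(x_s1, x_s2) -> dict:
    """Paired t-test for session differences (session 2 minus session 1)."""
    a = np.asarray(x_s1, dtype=float)
    b = np.asarray(x_s2, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("paired data with n >= 3 required")
    diff = b - a
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    if se == 0:  # constant difference: t is 0 (no shift) or unbounded
        t = 0.0 if diff.mean() == 0 else float(np.sign(diff.mean()) * np.inf)
        p = 1.0 if diff.mean() == 0 else 0.0
        ci = (diff.mean(), diff.mean())
    else:
        res = sps.ttest_rel(b, a)
        t, p = float(res.statistic), float(res.pvalue)
        ci = sps.t.interval(0.95, len(diff) - 1, loc=diff.mean(), scale=se)
    return {"t": t, "df": len(diff) - 1, "p": p,
            "mean_diff": float(diff.mean()),
            "ci_low": float(ci[0]), "ci_high": float(ci[1])}
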