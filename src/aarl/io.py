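"""Readers/writers for the tidy interchange formats, and the pipeline runner.

Canonical formats (all plain CSV, JSON for nested results):

* trials: ``participant_id, session, trial, choice, reward, punishment,
  key, conflict_side`` — ``choice`` in {conflict, safe, missed}; outcomes
  are 0/1 and empty (NA) on missed trials; ``trial`` is 0-based (1-based
  input is auto-detected and normalised with a note).
* covariates: ``participant_id, anxiety, unpleasantness, gad7, phq8, beaq,
  age, sex``.
* schedule: ``trial, p_reward_conflict, p_reward_safe, p_punish_conflict,
  p_punish_safe``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import CONFLICT, MISSED, SAFE, SessionData
from .task import LatentSchedule

logger = logging.getLogger("aarl")

_CHOICE_TO_CODE = {"conflict": CONFLICT, "safe": SAFE, "missed": MISSED}
_CODE_TO_CHOICE = {v: k for k, v in _CHOICE_TO_CODE.items()}

TRIAL_COLUMNS = ["participant_id", "session", "trial", "choice",
                 "reward", "punishment"]
COVARIATE_COLUMNS = ["participant_id", "anxiety", "unpleasantness", "gad7",
                     "phq8", "beaq", "age", "sex"]
SCHEDULE_COLUMNS = ["trial", "p_reward_conflict", "p_reward_safe",
                    "p_punish_conflict", "p_punish_safe"]


class SchemaError(ValueError):
    """A table does not match the expected schema."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in range(s.n_trials):
            c = int(s.choices[t])
            rows.append({
                "participant_id": s.participant_id,
                "session": s.session,
                "trial": t,
                "choice": _CODE_TO_CHOICE[c],
                "reward": np.nan if c == MISSED else int(s.rewards[t]),
                "punishment": np.nan if c == MISSED else int(s.punishments[t]),
                "key": np.nan if s.keys is None or s.keys[t] < 0 else int(s.keys[t]),
                "conflict_side": np.nan if s.conflict_side is None
                else int(s.conflict_side[t]),
            })
    return pd.DataFrame(rows)


def sessions_from_frame(df: pd.DataFrame) -> list[SessionData]:
    """Parse a tidy trial table into per-(participant, session) objects."""
    _require_columns(df, TRIAL_COLUMNS, "trial table")
    bad = set(df["choice"].unique()) - set(_CHOICE_TO_CODE)
    if bad:
        raise SchemaError(f"invalid choice value(s): {sorted(bad)}; "
                          "expected conflict/safe/missed")
    valid = df["choice"] != "missed"
    for col in ("reward", "punishment"):
        vals = df.loc[valid, col]
        if vals.isna().any() or not vals.isin([0, 1]).all():
            raise SchemaError(f"{col} must be 0/1 on non-missed trials")
    sessions = []
    for (pid, sess), g in df.groupby(["participant_id", "session"], sort=True):
        g = g.sort_values("trial")
        trials = g["trial"].to_numpy()
        if trials.min() == 1 and np.array_equal(trials, np.arange(1, len(g) + 1)):
            logger.info("trial index for %s/%s looks 1-based; normalising to 0-based",
                        pid, sess)
        elif not np.array_equal(trials, np.arange(len(g))):
            raise SchemaError(f"non-contiguous trial index for {pid}/{sess}")
        codes = g["choice"].map(_CHOICE_TO_CODE).to_numpy(np.int8)
        rew = g["reward"].fillna(-1).to_numpy(np.int8)
        pun = g["punishment"].fillna(-1).to_numpy(np.int8)
        keys = (g["key"].fillna(-1).to_numpy(np.int8)
                if "key" in g and not g["key"].isna().all() else None)
        side = (g["conflict_side"].to_numpy(np.int8)
                if "conflict_side" in g and not g["conflict_side"].isna().any()
                else None)
        sessions.append(SessionData(str(pid), int(sess), codes, rew, pun,
                                    keys=keys, conflict_side=side))
    return sessions


def write_trials(sessions: list[SessionData], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_trials(path) -> list[SessionData]:
    return sessions_from_frame(pd.read_csv(path))


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "anxiety"], "covariate table")
    anx = df["anxiety"]
    if ((anx < 0) | (anx > 50)).any():
        raise SchemaError("anxiety must lie in [0, 50]")
    return df


def attach_covariates(sessions: list[SessionData], covariates: pd.DataFrame) -> None:
    by_id = covariates.set_index("participant_id")
    for s in sessions:
        if s.participant_id in by_id.index:
            s.covariates.update(by_id.loc[s.participant_id].to_dict())


def read_schedule(path) -> LatentSchedule:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SCHEDULE_COLUMNS, "schedule table")
    return LatentSchedule.from_frame(df)


def write_schedule(schedule: LatentSchedule, path) -> None:
    with open(path, "w") as fh:
        fh.write("# trial index is 0-based\n")
        schedule.to_frame().to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Toggles, seeds and sizes for an end-to-end synthetic run."""

    out_dir: str = "aarl_run"
    seed: int = 0
    n_participants: int = 60
    n_trials: int = 200
    model: str = "asym_lr_asym_sens"
    run_compare: bool = False
    run_mediation: bool = True
    run_reliability: bool = True
    n_boot: int = 2000
    n_perm: int = 2000
    n_mc_samples: int = 1000
    overwrite: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Generate a cohort, clean it, fit, and run every toggled analysis.

    Writes all tables, a human-readable summary and a manifest (seeds and
    SHA-256 hashes of every output) into ``config.out_dir``.  A failing
    stage aborts with the stage named; earlier outputs are preserved.
    """
    from . import __version__
    from .fitting import compare_models, em_fit
    from .mediation import parallel_mediation
    from .reliability import joint_model_reliability, spearman_brown, split_sessions
    from .stats import (choice_proportion, clean_cohort, kendall_perm_test,
                        sensitivity_index)
    from .synthetic import CohortConfig, generate_cohort

    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    summary: list[str] = [f"aarl pipeline (seed={config.seed})"]
    try:
        cohort = generate_cohort(CohortConfig(
            n_participants=config.n_participants, n_trials=config.n_trials,
            model=config.model, seed=config.seed))
        write_trials(cohort.sessions, out / "trials.csv")
        cohort.covariates.to_csv(out / "covariates.csv", index=False)
        cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        logger.info("simulate: %d participants", config.n_participants)

        stage = "clean"
        report = clean_cohort(cohort.sessions, cohort.attention_results)
        (out / "cleaning.json").write_text(json.dumps({
            "excluded_attention": sorted(report.excluded_attention),
            "excluded_keys": sorted(report.excluded_keys),
            "excluded_missed": sorted(report.excluded_missed),
            "n_retained": len(report.retained)}, indent=2))
        sessions = report.retained
        summary.append(f"cleaning: retained {len(sessions)}/{len(cohort.sessions)}")

        stage = "fit"
        if config.run_compare:
            table = compare_models(sessions, seed=config.seed,
                                   n_mc_samples=config.n_mc_samples)
            table.to_csv(out / "model_comparison.csv", index=False)
            summary.append("model comparison winner: "
                           + table.loc[0, "model"])
        res = em_fit(sessions, config.model, seed=config.seed)
        res.to_json(out / "fit.json")
        summary.append(res.summary())

        stage = "analyse"
        params = res.params
        index = sensitivity_index(params)
        anx = np.array([s.covariates["anxiety"] for s in sessions])
        tau, p = kendall_perm_test(anx, index.to_numpy(),
                                   n_perm=config.n_perm, seed=config.seed)
        analysis = {"tau_anxiety_index": tau, "p_anxiety_index": p,
                    "mean_choice_proportion": float(np.mean(
                        [choice_proportion(s) for s in sessions]))}
        summary.append(f"tau(anxiety, beta_r/beta_p) = {tau:.3f} (p = {p:.4f})")

        if config.run_mediation:
            stage = "mediate"
            med = parallel_mediation(
                anx, params[["alpha_p"]].assign(index=index)[["index", "alpha_p"]],
                np.array([choice_proportion(s) for s in sessions]),
                n_boot=config.n_boot, seed=config.seed,
                mediator_names=["index", "alpha_p"])
            med.paths.to_csv(out / "mediation.csv", index=False)
            summary.append(med.summary())
        (out / "analysis.json").write_text(json.dumps(analysis, indent=2))

        if config.run_reliability:
            stage = "reliability"
            halves = [split_sessions(s) for s in sessions]
            first = [h[0] for h in halves]
            second = [h[1] for h in halves]
            r_choice = float(np.corrcoef(
                [choice_proportion(s) for s in first],
                [choice_proportion(s) for s in second])[0, 1])
            rel_table, _ = joint_model_reliability(first, second, config.model)
            rel_table["corrected"] = [spearman_brown(r) if -1 < r < 1 else np.nan
                                      for r in rel_table["reliability_r"]]
            rel_table = pd.concat([rel_table, pd.DataFrame([{
                "parameter": "choice_proportion", "reliability_r": r_choice,
                "band": "", "corrected": spearman_brown(r_choice)}])],
                ignore_index=True)
            rel_table.to_csv(out / "reliability.csv", index=False)
            summary.append(f"split-half r (choice proportion) = {r_choice:.3f}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.txt").write_text("\n\n".join(summary) + "\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
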