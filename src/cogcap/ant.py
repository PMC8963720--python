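"""Cleaning and attention-network effect scoring for ANT-I trials.

Per subject, three subtraction scores are computed from condition-mean RTs
of correct trials:

* Alerting  = RT(no alerting signal) - RT(alerting signal)
* Orienting = RT(invalid cue) - RT(valid cue)
* Conflict  = RT(incongruent flankers) - RT(congruent flankers)

A larger effect indicates a worse function of the corresponding network.
No-response trials count as errors for accuracy but are excluded from RT;
within each of the 18 design cells, correct-trial RTs beyond three standard
deviations of the cell mean are discarded as outliers (single pass; cells
with fewer than two correct trials are left unfiltered and logged).
Accuracy effects use the same subtraction directions on per-condition
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cogcap.trials import AntTrial, ant_trials_to_frame

CELL_KEYS = ["alerting", "orienting", "congruency"]
OUTLIER_SD = 3.0


@dataclass(frozen=True)
class AttentionEffects:
    subject_id: str
    alerting_rt: float
    orienting_rt: float
    conflict_rt: float
    alerting_acc: float
    orienting_acc: float
    conflict_acc: float
    overall_rt: float
    n_trials_rt_used: int
    n_outliers_removed: int
    notes: tuple[str, ...] = ()


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials.copy()
    if len(trials) and isinstance(trials[0], AntTrial):
        return ant_trials_to_frame(trials)
    raise ValueError("expected a DataFrame or a list of AntTrial")


def clean_trials(trials) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Split one subject's trials into RT and accuracy pools.

    Returns ``(rt_pool, acc_pool, removal_log)``: the accuracy pool is all
    trials with no-response trials marked incorrect; the RT pool keeps
    correct responded trials within mean +- 3 SD of their own design cell.
    """
    df = _as_frame(trials)
    if len(df) == 0:
        raise ValueError("no trials supplied")
    df["correct"] = df["correct"].astype(bool) & df["responded"].astype(bool)
    acc_pool = df

    candidates = df[df["correct"] & df["responded"].astype(bool)].copy()
    keep = pd.Series(True, index=candidates.index)
    log: list[dict] = []
    for cell, sub in candidates.groupby(CELL_KEYS, observed=True):
        rts = sub["rt_ms"].to_numpy(dtype=float)
        if len(rts) < 2:
            log.append({"cell": cell, "n": len(rts), "removed": 0,
                        "note": "cell too small, outlier filter skipped"})
            continue
        mean = rts.mean()
        sd = rts.std(ddof=1)
        bad = np.abs(rts - mean) > OUTLIER_SD * sd
        if bad.any():
            keep.loc[sub.index[bad]] = False
        log.append({"cell": cell, "n": len(rts), "removed": int(bad.sum()),
                    "mean": float(mean), "sd": float(sd)})
    rt_pool = candidates[keep]
    return rt_pool, acc_pool, log


def _set_mean(df: pd.DataFrame, col: str, mask: pd.Series, what: str,
              notes: list[str]) -> float:
    if not mask.any():
        notes.append(f"no retained trials for {what}")
        return np.nan
    return float(df.loc[mask, col].mean())


def compute_effects(rt_pool: pd.DataFrame, acc_pool: pd.DataFrame,
                    subject_id: str | None = None,
                    include_neutral_in_overall: bool = True,
                    n_outliers_removed: int = 0) -> AttentionEffects:
    """Attention-network subtraction scores from cleaned pools."""
    notes: list[str] = []
    if subject_id is None:
        subject_id = (str(acc_pool["subject_id"].iloc[0])
                      if "subject_id" in acc_pool.columns and len(acc_pool) else "")

    def rt_effect(first: pd.Series, second: pd.Series, name: str) -> float:
        a = _set_mean(rt_pool, "rt_ms", first, f"{name} (first set)", notes)
        b = _set_mean(rt_pool, "rt_ms", second, f"{name} (second set)", notes)
        return a - b

    def acc_effect(first: pd.Series, second: pd.Series) -> float:
        a = float(acc_pool.loc[first, "correct"].astype(float).mean())
        b = float(acc_pool.loc[second, "correct"].astype(float).mean())
        return a - b

    alert_rt = rt_pool["alerting"].astype(int)
    alert_acc = acc_pool["alerting"].astype(int)
    alerting_rt = rt_effect(alert_rt == 0, alert_rt == 1, "alerting")
    orienting_rt = rt_effect(rt_pool["orienting"] == "invalid",
                             rt_pool["orienting"] == "valid", "orienting")
    conflict_rt = rt_effect(rt_pool["congruency"] == "incongruent",
                            rt_pool["congruency"] == "congruent", "conflict")
    alerting_acc = acc_effect(alert_acc == 0, alert_acc == 1)
    orienting_acc = acc_effect(acc_pool["orienting"] == "invalid",
                               acc_pool["orienting"] == "valid")
    conflict_acc = acc_effect(acc_pool["congruency"] == "incongruent",
                              acc_pool["congruency"] == "congruent")

    if include_neutral_in_overall:
        overall_pool = rt_pool
    else:
        overall_pool = rt_pool[rt_pool["congruency"] != "neutral"]
    overall_rt = float(overall_pool["rt_ms"].mean()) if len(overall_pool) else np.nan
    if not len(overall_pool):
        notes.append("no retained trials for overall RT")

    return AttentionEffects(
        subject_id=subject_id,
        alerting_rt=alerting_rt, orienting_rt=orienting_rt, conflict_rt=conflict_rt,
        alerting_acc=alerting_acc, orienting_acc=orienting_acc, conflict_acc=conflict_acc,
        overall_rt=overall_rt, n_trials_rt_used=len(rt_pool),
        n_outliers_removed=n_outliers_removed, notes=tuple(notes))


def score_subject(trials, include_neutral_in_overall: bool = True) -> AttentionEffects:
    """Clean one subject's trials and compute the attention effects."""
    rt_pool, acc_pool, log = clean_trials(trials)
    removed = sum(entry["removed"] for entry in log)
    return compute_effects(rt_pool, acc_pool,
                           include_neutral_in_overall=include_neutral_in_overall,
                           n_outliers_removed=removed)


def score_cohort(trials: pd.DataFrame,
                 include_neutral_in_overall: bool = True) -> pd.DataFrame:
    """Per-subject effects table for a multi-subject ANT-I trial table."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        eff = score_subject(sub, include_neutral_in_overall)
        rows.append({"subject_id": str(sid), "alerting_rt": eff.alerting_rt,
                     "orienting_rt": eff.orienting_rt, "conflict_rt": eff.conflict_rt,
                     "alerting_acc": eff.alerting_acc, "orienting_acc": eff.orienting_acc,
                     "conflict_acc": eff.conflict_acc, "overall_rt": eff.overall_rt,
                     "n_trials_rt_used": eff.n_trials_rt_used,
                     "n_outliers_removed": eff.n_outliers_removed})
    return pd.DataFrame(rows)
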