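"""Performance and learning metrics over race, decision and feature logs.

BCI command accuracy is the percentage of pads of each action color on which
the matching command was delivered while the avatar was on the pad; the
overall accuracy is the arithmetic mean of the three per-command rates. For
white pads the equivalent metric is the true-negative rate: the percentage
of white pads crossed without delivering any command (start and end whites
included). Longitudinal trends are quantified with Pearson correlations
(two-sided p from the Student-t transform with n-2 degrees of freedom), and
first-versus-last-four-session contrasts with unpaired two-sided Wilcoxon
rank-sum tests (exact p for small tie-free samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .race import COMMAND_FOR_PAD, RaceResult

#: Column dictionary of the per-run session log.
SESSION_COLUMNS = {
    "run_index": "strictly increasing run counter",
    "session": "session (recording day) label, groups runs",
    "paradigm": "control paradigm id (1-4)",
    "effect_size": "programmed SMR effect size of the run",
    "race_time": "race completion time, s",
    "mean_pad_time": "mean crossing time over all pads, s",
    "accuracy_overall": "mean of the three per-command accuracies, %",
    "accuracy_spin": "spin (cyan pad) true positive rate, %",
    "accuracy_jump": "jump (magenta pad) true positive rate, %",
    "accuracy_slide": "slide (yellow pad) true positive rate, %",
    "white_tnr": "white-pad true negative rate, %",
    "train_accuracy": "classifier training-set accuracy, fraction",
    "disc_medial_mu": "mean Fisher score, medial channels, mu band",
    "disc_medial_beta": "mean Fisher score, medial channels, beta band",
    "disc_lateral_mu": "mean Fisher score, lateral channels, mu band",
    "disc_lateral_beta": "mean Fisher score, lateral channels, beta band",
    "disc_smr_beta": "mean of the medial and lateral beta discriminancies",
}


@dataclass
class AccuracyReport:
    """Per-command true-positive rates and white-pad true-negative rate."""

    per_command: dict[str, float | None]  # % or None when no such pad
    white_tnr: float | None
    pad_counts: dict[str, int]

    @property
    def overall(self) -> float | None:
        vals = [v for v in self.per_command.values() if v is not None]
        return float(np.mean(vals)) if vals else None


def command_accuracy(result: RaceResult) -> AccuracyReport:
    """Score a race log.

    An action pad counts as correct if the matching command was delivered at
    any point while on it (accuracy measures delivery, not net speed); a
    white pad is a true negative iff zero commands were delivered on it.
    """
    correct = {k: 0 for k in COMMAND_FOR_PAD.values()}
    totals = {k: 0 for k in COMMAND_FOR_PAD.values()}
    white_total = white_clean = 0
    counts: dict[str, int] = {}
    for rec in result.records:
        counts[rec.pad_type] = counts.get(rec.pad_type, 0) + 1
        if rec.pad_type in COMMAND_FOR_PAD:
            cmd = COMMAND_FOR_PAD[rec.pad_type]
            totals[cmd] += 1
            if any(ok for _, _, ok in rec.commands):
                correct[cmd] += 1
        else:
            white_total += 1
            if not rec.commands:
                white_clean += 1
    per_command = {
        k: (100.0 * correct[k] / totals[k]) if totals[k] else None
        for k in totals
    }
    tnr = 100.0 * white_clean / white_total if white_total else None
    return AccuracyReport(per_command, tnr, counts)


def trend_correlation(values, index=None) -> tuple[float, float]:
    """Pearson r of a metric against run index, with two-sided p.

    p comes from the exact t transform t = r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom. Zero variance in either series yields (nan, nan)
    with a warning.
    """
    y = np.asarray(values, dtype=float)
    x = (np.arange(len(y), dtype=float) if index is None
         else np.asarray(index, dtype=float))
    if len(y) < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or y.std() == 0 or x.std() == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RankSumContrast:
    group1: np.ndarray
    group2: np.ndarray
    median1: float
    median2: float
    statistic: float
    p_value: float
    exact: bool


#: Above this pooled size the rank-sum test switches to the (tie-corrected)
#: normal approximation even without ties.
EXACT_RANKSUM_MAX_N = 25


def rank_sum_test(group1, group2) -> RankSumContrast:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample is small and
    tie-free, otherwise the normal approximation with tie correction
    (midranks).
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (not ties) and (len(pooled) <= EXACT_RANKSUM_MAX_N)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return RankSumContrast(
        a, b, float(np.median(a)), float(np.median(b)),
        float(res.statistic), float(res.pvalue), exact,
    )


def first_last_contrast(
    log: pd.DataFrame, metric: str, k_sessions: int = 4
) -> RankSumContrast:
    """Compare a metric between the first and last ``k_sessions`` sessions.

    Runs are pooled within each window; the windows must not overlap.
    """
    sessions = list(dict.fromkeys(log["session"]))
    if len(sessions) < 2 * k_sessions:
        raise ValueError(
            f"need >= {2 * k_sessions} sessions, got {len(sessions)}"
        )
    first = log[log["session"].isin(sessions[:k_sessions])][metric]
    last = log[log["session"].isin(sessions[-k_sessions:])][metric]
    return rank_sum_test(first, last)


TREND_METRICS = (
    "race_time", "mean_pad_time", "accuracy_overall", "disc_medial_beta",
    "disc_lateral_beta", "disc_smr_beta",
)
CROSS_PAIRS = (
    ("disc_smr_beta", "accuracy_overall"),
    ("disc_smr_beta", "mean_pad_time"),
    ("disc_smr_beta", "race_time"),
)


def learning_report(
    log: pd.DataFrame, k_sessions: int = 4
) -> dict:
    """All longitudinal statistics for a training campaign.

    Returns a JSON-serializable dict with per-metric trends against run
    index, cross-correlations of discriminancy with the performance metrics,
    first/last session contrasts (when enough sessions exist) and
    per-paradigm aggregates.
    """
    report: dict = {"n_runs": int(len(log)), "trends": {}, "cross": {},
                    "contrasts": {}, "paradigms": {}}
    idx = log["run_index"].to_numpy(dtype=float)
    if len(log) >= 3:  # trends are undefined on shorter campaigns
        for metric in TREND_METRICS:
            if metric not in log or log[metric].isna().all():
                continue
            r, p = trend_correlation(log[metric].to_numpy(), idx)
            report["trends"][metric] = {"r": r, "p": p}
        for m1, m2 in CROSS_PAIRS:
            if m1 not in log or m2 not in log:
                continue
            r, p = trend_correlation(log[m2].to_numpy(),
                                     log[m1].to_numpy())
            report["cross"][f"{m1}_vs_{m2}"] = {"r": r, "p": p}
    sessions = list(dict.fromkeys(log["session"]))
    if len(sessions) >= 2 * k_sessions:
        for metric in TREND_METRICS:
            if metric not in log:
                continue
            c = first_last_contrast(log, metric, k_sessions)
            report["contrasts"][metric] = {
                "median_first": c.median1, "median_last": c.median2,
                "p": c.p_value, "exact": c.exact,
            }
    for pid, grp in log.groupby("paradigm"):
        report["paradigms"][str(int(pid))] = {
            "n_runs": int(len(grp)),
            "mean_race_time": float(grp["race_time"].mean()),
            "mean_accuracy": float(grp["accuracy_overall"].mean()),
        }
    return report


def save_session_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False)


def load_session_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
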