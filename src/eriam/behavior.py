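"""Trial filtering and behavioral statistics.

Covers flanker performance by congruency, post-error measures, color-report
offset errors, the error-related impairment ratio (offset error after motor
errors relative to after motor-correct responses, incongruent trials only),
and change-detection capacity (K = set size x (hit - false alarm), averaged
over set sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_EXCLUSION_REASONS = ("flanker_miss", "anticipatory", "wm_miss")


def angular_offset(reported, true_color):
    """Minimal absolute circular difference in degrees, in [0, 180]."""
    a = np.asarray(reported, dtype=float)
    b = np.asarray(true_color, dtype=float)
    d = np.abs(a - b) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def filter_valid_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep trials with responses on both tasks and flanker RT >= 150 ms.

    Returns the kept trials and an exclusion tally by reason. A trial missing
    both responses is tallied once, under the flanker miss.
    """
    if len(trials) == 0:
        return trials.copy(), {k: 0 for k in VALID_EXCLUSION_REASONS}
    flanker_rt = trials["flanker_rt"].to_numpy(dtype=float)
    responded_flanker = np.isfinite(flanker_rt)
    anticipatory = responded_flanker & (flanker_rt < 150.0)
    responded_wm = np.isfinite(trials["wm_report"].to_numpy(dtype=float))
    keep = responded_flanker & ~anticipatory & responded_wm
    tally = {
        "flanker_miss": int((~responded_flanker).sum()),
        "anticipatory": int(anticipatory.sum()),
        "wm_miss": int((responded_flanker & ~anticipatory & ~responded_wm).sum()),
    }
    return trials.loc[keep].copy(), tally


def _mean_or_nan(x: np.ndarray) -> float:
    return float(np.mean(x)) if len(x) else float("nan")


def flanker_summary(trials: pd.DataFrame) -> pd.Series:
    """Flanker accuracy and RT by congruency for one subject's valid trials.

    RT cells are restricted to correct trials; the error-RT cell uses
    incongruent trials only (congruent errors are rare). Empty cells are NaN,
    never zero.
    """
    correct = trials["flanker_correct"].to_numpy() == 1.0
    incong = (trials["congruency"] == "incongruent").to_numpy()
    rt = trials["flanker_rt"].to_numpy(dtype=float)

    def acc(mask):
        return 100.0 * _mean_or_nan(correct[mask]) if mask.sum() else float("nan")

    return pd.Series({
        "acc_congruent": acc(~incong),
        "acc_incongruent": acc(incong),
        "rt_congruent_correct": _mean_or_nan(rt[~incong & correct]),
        "rt_incongruent_correct": _mean_or_nan(rt[incong & correct]),
        "rt_incongruent_error": _mean_or_nan(rt[incong & ~correct]),
        "error_rate": 100.0 * (1.0 - _mean_or_nan(correct)),
        "n_valid_trials": int(len(trials)),
        "n_incongruent_errors": int((incong & ~correct).sum()),
    })


def post_error_summary(trials: pd.DataFrame) -> pd.Series:
    """Post-error vs post-correct accuracy, RT, and interference contrasts.

    Trial n is classified by the accuracy of trial n-1 within the same block;
    the first trial of each block (and any trial whose immediate predecessor
    was excluded) stays unclassified. RT cells average the *correct* trials
    following errors / following correct responses.
    """
    t = trials.sort_values(["block", "trial"])
    block = t["block"].to_numpy()
    trial = t["trial"].to_numpy()
    correct = t["flanker_correct"].to_numpy() == 1.0
    incong = (t["congruency"] == "incongruent").to_numpy()
    rt = t["flanker_rt"].to_numpy(dtype=float)

    prev_same_block = np.zeros(len(t), dtype=bool)
    prev_correct = np.zeros(len(t), dtype=bool)
    if len(t) > 1:
        contiguous = (block[1:] == block[:-1]) & (trial[1:] == trial[:-1] + 1)
        prev_same_block[1:] = contiguous
        prev_correct[1:] = correct[:-1]
    post_corr = prev_same_block & prev_correct
    post_err = prev_same_block & ~prev_correct

    def acc(mask):
        return 100.0 * _mean_or_nan(correct[mask]) if mask.sum() else float("nan")

    def rt_interference(mask):
        a = rt[mask & correct & incong]
        b = rt[mask & correct & ~incong]
        return _mean_or_nan(a) - _mean_or_nan(b)

    def acc_interference(mask):
        return acc(mask & incong) - acc(mask & ~incong)

    return pd.Series({
        "acc_post_correct": acc(post_corr),
        "acc_post_error": acc(post_err),
        "rt_post_correct": _mean_or_nan(rt[post_corr & correct]),
        "rt_post_error": _mean_or_nan(rt[post_err & correct]),
        "rt_interference_post_correct": rt_interference(post_corr),
        "rt_interference_post_error": rt_interference(post_err),
        "acc_interference_post_correct": acc_interference(post_corr),
        "acc_interference_post_error": acc_interference(post_err),
        "n_post_error": int(post_err.sum()),
        "n_post_correct": int(post_corr.sum()),
    })


@dataclass(frozen=True)
class ERIAMResult:
    """Per-subject impairment ratio of the color report after motor errors."""

    subject_id: int
    offset_error_motor_error: float
    offset_error_motor_correct: float
    eriam: float
    n_motor_error: int
    n_motor_correct: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.eriam)


def wm_offsets(trials: pd.DataFrame) -> np.ndarray:
    return angular_offset(trials["wm_report"].to_numpy(dtype=float),
                          trials["true_color"].to_numpy(dtype=float))


def eriam_effect(trials: pd.DataFrame, min_trials: int = 5) -> ERIAMResult:
    """Normalized post-error impairment of the color report, one subject.

    Computed on incongruent valid trials only: mean absolute offsets per
    motor condition, then (error - correct) / correct. Undefined (NaN, with
    counts preserved) when either condition has fewer than ``min_trials``
    trials or the motor-correct mean is not positive.
    """
    sid = int(trials["subject_id"].iloc[0]) if len(trials) else -1
    t = trials[trials["congruency"] == "incongruent"]
    off = wm_offsets(t)
    is_err = t["flanker_correct"].to_numpy() == 0.0
    off_err = off[is_err]
    off_corr = off[~is_err]
    m_err = _mean_or_nan(off_err)
    m_corr = _mean_or_nan(off_corr)
    if (len(off_err) < min_trials or len(off_corr) < min_trials
            or not np.isfinite(m_corr) or m_corr <= 0.0):
        ratio = float("nan")
    else:
        ratio = (m_err - m_corr) / m_corr
    return ERIAMResult(
        subject_id=sid,
        offset_error_motor_error=m_err,
        offset_error_motor_correct=m_corr,
        eriam=ratio,
        n_motor_error=int(len(off_err)),
        n_motor_correct=int(len(off_corr)),
    )


def wm_summary(trials: pd.DataFrame) -> pd.Series:
    """Mean offsets by congruency (correct trials) and report RTs."""
    off = wm_offsets(trials)
    correct = trials["flanker_correct"].to_numpy() == 1.0
    incong = (trials["congruency"] == "incongruent").to_numpy()
    wm_rt = trials["wm_rt"].to_numpy(dtype=float)
    return pd.Series({
        "offset_congruent_correct": _mean_or_nan(off[~incong & correct]),
        "offset_incongruent_correct": _mean_or_nan(off[incong & correct]),
        "offset_incongruent_error": _mean_or_nan(off[incong & ~correct]),
        "wm_rt_congruent_correct": _mean_or_nan(wm_rt[~incong & correct]),
        "wm_rt_incongruent_correct": _mean_or_nan(wm_rt[incong & correct]),
        "wm_rt_incongruent_error": _mean_or_nan(wm_rt[incong & ~correct]),
        "wm_accuracy_60": wm_accuracy_60(trials),
    })


def wm_accuracy_60(trials: pd.DataFrame) -> float:
    """Percentage of reports within 60 degrees of the target (inclusive)."""
    off = wm_offsets(trials)
    if len(off) == 0:
        return float("nan")
    return float(100.0 * np.mean(off <= 60.0))


def cowan_k(records: pd.DataFrame) -> pd.Series:
    """Change-detection capacity per set size and averaged, one subject.

    K_N = N * (hit - false alarm); the subject estimate is the unweighted
    mean over set sizes. A set size missing either trial type is dropped from
    the average with a warning.
    """
    out: dict[str, float] = {}
    ks = []
    for set_size, grp in records.groupby("set_size"):
        change = grp[grp["is_change_trial"]]
        nochange = grp[~grp["is_change_trial"]]
        if len(change) == 0 or len(nochange) == 0:
            warnings.warn(
                f"set size {set_size}: missing change or no-change trials; "
                "dropped from the K average", stacklevel=2)
            out[f"k_{set_size}"] = float("nan")
            continue
        hit = float(change["response_change"].mean())
        fa = float(nochange["response_change"].mean())
        k = set_size * (hit - fa)
        out[f"k_{set_size}"] = k
        ks.append(k)
    out["k_mean"] = float(np.mean(ks)) if ks else float("nan")
    return pd.Series(out)


def behavior_summary(trials_valid: pd.DataFrame, min_trials: int = 5) -> pd.Series:
    """All per-subject behavioral statistics on the filtered trials."""
    parts = [flanker_summary(trials_valid), post_error_summary(trials_valid),
             wm_summary(trials_valid)]
    er = eriam_effect(trials_valid, min_trials=min_trials)
    parts.append(pd.Series({
        "eriam": er.eriam,
        "offset_motor_error": er.offset_error_motor_error,
        "offset_motor_correct": er.offset_error_motor_correct,
        "n_motor_error": er.n_motor_error,
        "n_motor_correct": er.n_motor_correct,
    }))
    return pd.concat(parts)
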