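"""Contralateral-minus-ipsilateral difference-wave extraction.

Implements the three hypothesis-specific measurement schemes on epoched data:

* H1 - fixed 500-900 ms window after memory-array onset, baselined at
  -200..0 ms pre-array (array-locked epochs);
* H2 - trial-specific window from flanker onset back-traced from the flanker
  response, same pre-array baseline;
* H3 - fixed 200-396 ms window after the flanker response, on response-locked
  epochs baselined at -150..-50 ms pre-response.

All windows are half-open [start, end) on the sampled time axis. Negative
values mean the contralateral electrode is more negative (active lateralized
maintenance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EpochSet


@dataclass(frozen=True)
class EpochWindow:
    """Half-open [start, end) measurement window, ms, tied to a reference event."""

    start: float
    end: float
    reference_event: str  # "array_onset" | "response_onset"
    per_trial: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")


H1_WINDOW = EpochWindow(500.0, 900.0, "array_onset")
H3_WINDOW = EpochWindow(200.0, 396.0, "response_onset")
ARRAY_BASELINE = EpochWindow(-200.0, 0.0, "array_onset")
RESPONSE_BASELINE = EpochWindow(-150.0, -50.0, "response_onset")
T2_START, T2_END = -1700.0, 800.0


def _window_mask(times: np.ndarray, window: EpochWindow) -> np.ndarray:
    return (times >= window.start) & (times < window.end)


def relock_to_response(epochs: EpochSet, t2_start: float = T2_START,
                       t2_end: float = T2_END) -> tuple[EpochSet, dict[str, int]]:
    """Re-window array-locked epochs so sample 0 is the flanker response.

    The response onset maps to the nearest sample of the source epoch. Trials
    without a response, and trials whose requested window does not fit inside
    the source epoch, are dropped with separate tallies.
    """
    if epochs.time_zero != "array_onset":
        raise ValueError("relock_to_response expects array-locked epochs")
    dt = epochs.sample_interval
    n_out = int(round((t2_end - t2_start) / dt))
    offset = int(round(t2_start / dt))

    lat = epochs.response_latency
    responded = np.isfinite(lat)
    r_idx = np.full(len(lat), -1, dtype=int)
    r_idx[responded] = np.rint((lat[responded] - epochs.tmin) / dt).astype(int)
    lo = r_idx + offset
    hi = lo + n_out
    fits = responded & (lo >= 0) & (hi <= epochs.n_samples)
    tally = {
        "no_response": int((~responded).sum()),
        "epoch_bounds": int((responded & ~fits).sum()),
    }
    keep = np.flatnonzero(fits)
    data = np.empty((len(keep), epochs.data.shape[1], n_out))
    for row, k in enumerate(keep):
        data[row] = epochs.data[k, :, lo[k]:hi[k]]
    out = EpochSet(
        data=data,
        channel_labels=epochs.channel_labels,
        sampling_rate=epochs.sampling_rate,
        tmin=offset * dt,
        time_zero="response_onset",
        response_latency=np.zeros(len(keep)),
        trial_index=epochs.trial_index[keep],
        channel_hemispheres=epochs.channel_hemispheres,
    )
    return out, tally


def apply_baseline(epochs: EpochSet, window: EpochWindow) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    if window.reference_event != epochs.time_zero:
        raise ValueError(
            f"baseline references {window.reference_event!r} but epochs are "
            f"locked to {epochs.time_zero!r}")
    mask = _window_mask(epochs.times, window)
    if not mask.any():
        raise ValueError("baseline window lies outside the epoch")
    if window.start < epochs.tmin or window.end > epochs.tmax:
        raise ValueError("baseline window lies outside the epoch")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def contra_ipsi_wave(epochs: EpochSet, cue_side: Sequence[str],
                     pair: tuple[str, str] = ("PO7", "PO8"),
                     ) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Per-trial contralateral-minus-ipsilateral difference wave.

    ``cue_side`` gives the to-be-remembered hemifield per trial; the
    contralateral channel is the pair member in the opposite hemisphere.
    Returns (waves, kept_row_indices, tally); trials with an unknown cue side
    are dropped with a tally.
    """
    labels = list(epochs.channel_labels)
    for ch in pair:
        if ch not in labels:
            raise ValueError(f"channel {ch!r} not present")
    hemi_of = {epochs.channel_hemispheres[labels.index(ch)]: labels.index(ch) for ch in pair}
    if set(hemi_of) != {"left", "right"}:
        raise ValueError("channel pair must span both hemispheres")

    cue = np.asarray(cue_side, dtype=object)
    if len(cue) != epochs.n_trials:
        raise ValueError("cue_side length must match trials")
    known = np.isin(cue, ("left", "right"))
    tally = {"unknown_cue": int((~known).sum())}
    keep = np.flatnonzero(known)

    left_ch, right_ch = hemi_of["left"], hemi_of["right"]
    cue_is_left = cue[keep] == "left"
    contra = np.where(cue_is_left[:, None],
                      epochs.data[keep, right_ch, :],
                      epochs.data[keep, left_ch, :])
    ipsi = np.where(cue_is_left[:, None],
                    epochs.data[keep, left_ch, :],
                    epochs.data[keep, right_ch, :])
    return contra - ipsi, keep, tally


def window_mean_fixed(waves: np.ndarray, times: np.ndarray,
                      window: EpochWindow) -> np.ndarray:
    """Mean over samples with start <= t < end, per trial (or per wave)."""
    mask = _window_mask(times, window)
    if not mask.any():
        raise ValueError("window contains no samples")
    return np.asarray(waves)[..., mask].mean(axis=-1)


def window_mean_trialwise(waves: np.ndarray, times: np.ndarray,
                          flanker_onset: float,
                          response_ms: np.ndarray,
                          ) -> tuple[np.ndarray, dict[str, int]]:
    """Per-trial mean over [flanker onset, response) on a shared time axis.

    Returns per-trial means (NaN for dropped trials) and a tally of trials
    dropped because the response precedes the flanker onset or is missing.
    """
    waves = np.asarray(waves)
    response_ms = np.asarray(response_ms, dtype=float)
    out = np.full(waves.shape[0], np.nan)
    bad_order = np.isfinite(response_ms) & (response_ms <= flanker_onset)
    missing = ~np.isfinite(response_ms)
    for i in range(waves.shape[0]):
        if missing[i] or bad_order[i]:
            continue
        mask = (times >= flanker_onset) & (times < response_ms[i])
        if not mask.any():
            # degenerate sub-sample window: use the sample at flanker onset
            mask = np.isclose(times, flanker_onset)
        out[i] = waves[i, mask].mean()
    tally = {"response_before_onset": int(bad_order.sum()),
             "no_response": int(missing.sum())}
    return out, tally


def find_divergence_window(condition_a: np.ndarray, condition_b: np.ndarray,
                           times: np.ndarray, alpha: float = 0.05,
                           t_min: float = 0.0,
                           ) -> tuple[EpochWindow | None, pd.DataFrame]:
    """Longest run of consecutively significant paired differences.

    ``condition_a``/``condition_b`` are per-subject mean waves (subjects x
    samples) on a common response-locked axis. A sample-wise two-tailed
    paired t is computed across subjects; the longest run of consecutive
    samples at t >= t_min with p < alpha is returned (earliest onset wins
    ties). Returns (window or None, per-sample statistics).
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape or a.shape[1] != len(times):
        raise ValueError("condition wave sets must share one time axis")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    import warnings
    with warnings.catch_warnings():
        # identical inputs trigger a precision warning and 0/0 -> NaN;
        # those samples are simply non-significant
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pval = stats.ttest_rel(a, b, axis=0)
    pval = np.where(np.isnan(pval), 1.0, pval)
    table = pd.DataFrame({"time_ms": times, "t": tstat, "p": pval})

    eligible = (times >= t_min) & (pval < alpha)
    best_len, best_start = 0, -1
    run_len, run_start = 0, -1
    for i, flag in enumerate(eligible):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len == 0:
        return None, table
    dt = float(times[1] - times[0])
    start = float(times[best_start])
    end = float(times[best_start + best_len - 1]) + dt
    return EpochWindow(start, end, "response_onset"), table


def condition_cda_summary(trials: pd.DataFrame, epochs: EpochSet,
                          hypothesis: str,
                          flanker_onset: float = 900.0,
                          min_error_trials: int = 5,
                          ) -> tuple[pd.Series, dict[str, int]]:
    """One CDA value per motor condition for one subject.

    Restricted to incongruent trials with a flanker response, matching the
    behavioral condition split. Applies the hypothesis-appropriate relock,
    baseline, and window; returns condition means, their difference, trial
    counts, and the drop tallies. Values are NaN when the subject has fewer
    than ``min_error_trials`` motor-error trials.
    """
    if hypothesis not in ("H1", "H2", "H3"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if epochs.time_zero != "array_onset":
        raise ValueError("condition_cda_summary expects array-locked epochs")

    # epochs align to the original (unfiltered) trial table through
    # trial_index; filtered trial frames keep their original row labels
    row_of = {int(t): i for i, t in enumerate(epochs.trial_index)}
    incong = (trials["congruency"] == "incongruent").to_numpy()
    responded = np.isfinite(trials["flanker_rt"].to_numpy(dtype=float))
    sel = trials.loc[incong & responded]
    sel_rows = np.array([row_of[int(i)] for i in sel.index], dtype=int)

    tally: dict[str, int] = {}
    sub = EpochSet(
        data=epochs.data[sel_rows],
        channel_labels=epochs.channel_labels,
        sampling_rate=epochs.sampling_rate,
        tmin=epochs.tmin,
        time_zero=epochs.time_zero,
        response_latency=epochs.response_latency[sel_rows],
        trial_index=epochs.trial_index[sel_rows],
        channel_hemispheres=epochs.channel_hemispheres,
    )
    is_err = (sel["flanker_correct"].to_numpy() == 0.0)

    if hypothesis in ("H1", "H2"):
        base = apply_baseline(sub, ARRAY_BASELINE)
        waves, keep, t_ci = contra_ipsi_wave(base, sel["cue_side"].to_numpy())
        tally.update(t_ci)
        is_err = is_err[keep]
        if hypothesis == "H1":
            vals = window_mean_fixed(waves, base.times, H1_WINDOW)
        else:
            resp = base.response_latency[keep]
            vals, t_tw = window_mean_trialwise(waves, base.times,
                                               flanker_onset, resp)
            tally.update(t_tw)
    else:
        relocked, t_rl = relock_to_response(sub)
        tally.update(t_rl)
        relocked = apply_baseline(relocked, RESPONSE_BASELINE)
        pos = {int(t): j for j, t in enumerate(sub.trial_index)}
        kept_pos = np.array([pos[int(t)] for t in relocked.trial_index], dtype=int)
        cue = sel["cue_side"].to_numpy()[kept_pos]
        waves, keep, t_ci = contra_ipsi_wave(relocked, cue)
        tally.update(t_ci)
        is_err = is_err[kept_pos][keep]
        vals = window_mean_fixed(waves, relocked.times, H3_WINDOW)

    ok = np.isfinite(vals)
    err_vals = vals[ok & is_err]
    corr_vals = vals[ok & ~is_err]
    n_err, n_corr = len(err_vals), len(corr_vals)
    enough = n_err >= min_error_trials and n_corr >= min_error_trials
    m_err = float(err_vals.mean()) if enough and n_err else float("nan")
    m_corr = float(corr_vals.mean()) if enough and n_corr else float("nan")
    if not enough:
        tally["below_min_error_trials"] = 1
    return pd.Series({
        "cda_motor_error": m_err,
        "cda_motor_correct": m_corr,
        "cda_diff": m_err - m_corr,
        "n_motor_error": n_err,
        "n_motor_correct": n_corr,
    }), tally


def condition_mean_waves(trials: pd.DataFrame, epochs: EpochSet,
                         ) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Per-condition mean response-locked difference waves for one subject.

    Used by the divergence scan: incongruent responded trials, relocked to the
    response and baselined pre-response. Returns (error_wave, correct_wave,
    times); a condition with no trials yields None.
    """
    row_of = {int(t): i for i, t in enumerate(epochs.trial_index)}
    incong = (trials["congruency"] == "incongruent").to_numpy()
    responded = np.isfinite(trials["flanker_rt"].to_numpy(dtype=float))
    sel = trials.loc[incong & responded]
    sel_rows = np.array([row_of[int(i)] for i in sel.index], dtype=int)
    sub = EpochSet(
        data=epochs.data[sel_rows],
        channel_labels=epochs.channel_labels,
        sampling_rate=epochs.sampling_rate,
        tmin=epochs.tmin,
        time_zero=epochs.time_zero,
        response_latency=epochs.response_latency[sel_rows],
        trial_index=epochs.trial_index[sel_rows],
        channel_hemispheres=epochs.channel_hemispheres,
    )
    relocked, _ = relock_to_response(sub)
    relocked = apply_baseline(relocked, RESPONSE_BASELINE)
    pos = {int(t): j for j, t in enumerate(sub.trial_index)}
    kept_pos = np.array([pos[int(t)] for t in relocked.trial_index], dtype=int)
    cue = sel["cue_side"].to_numpy()[kept_pos]
    waves, keep, _ = contra_ipsi_wave(relocked, cue)
    is_err = (sel["flanker_correct"].to_numpy() == 0.0)[kept_pos][keep]
    err = waves[is_err].mean(axis=0) if is_err.any() else None
    corr = waves[~is_err].mean(axis=0) if (~is_err).any() else None
    return err, corr, relocked.times
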