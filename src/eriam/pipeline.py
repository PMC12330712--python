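"""End-to-end orchestration: generate -> analyze -> report.

Streams the cohort subject by subject (memory stays bounded by one subject's
epochs), computes per-subject behavioral and CDA summaries, then the group
statistics mirroring the study's contrasts: condition comparisons in the
three hypothesis windows with paired t / Cohen's d / JZS Bayes factors, the
post-response divergence scan, CDA-capacity Spearman correlations per window,
and the partial correlations linking the post-response CDA condition
difference, the behavioral impairment ratio, and capacity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_summary, cowan_k, filter_valid_trials
from .cda import (ARRAY_BASELINE, apply_baseline, condition_cda_summary,
                  condition_mean_waves, contra_ipsi_wave,
                  find_divergence_window)
from .cohort import EpochSet, SubjectData, draw_subject_profiles, simulate_subject
from .config import RunConfig, config_hash, write_toml
from .stats import jzs_bf, one_sample_t, paired_t, partial_spearman_rho, spearman_rho

log = logging.getLogger("eriam")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisReport:
    subjects: pd.DataFrame
    cda_table: pd.DataFrame
    waveforms: dict[str, pd.DataFrame]
    summary: dict
    exclusions: pd.DataFrame


def _nan_to_none(obj):
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _ttest_record(res) -> dict:
    return {"t": res.t, "df": res.df, "p": res.p, "d": res.d,
            "mean": res.mean, "se": res.se, "n": res.n}


def _paired_with_bf(x, y, alpha: float) -> dict:
    res = paired_t(x, y)
    bf = jzs_bf(res.t, res.n)
    rec = _ttest_record(res)
    rec["significant"] = bool(res.p < alpha)
    rec["bf"] = {"bf10": bf.bf10, "bf01": bf.bf01, "prior_scale": bf.prior_scale}
    return rec


def analyze_subject_data(data: SubjectData, cfg: RunConfig) -> dict:
    """Per-subject stage: filtering, behavior, capacity, CDA per hypothesis."""
    valid, tally = filter_valid_trials(data.trials)
    row = {"subject_id": data.profile.subject_id}
    row.update(behavior_summary(valid, min_trials=cfg.min_trials_per_condition).to_dict())
    row.update(cowan_k(data.change_detection).to_dict())

    cda_rows = []
    eeg_tallies: dict[str, int] = {}
    waves = None
    if data.epochs is not None:
        for hyp in cfg.hypotheses:
            s, t = condition_cda_summary(
                valid, data.epochs, hyp,
                flanker_onset=cfg.cohort.flanker_onset,
                min_error_trials=cfg.min_trials_per_condition)
            for cond in ("motor_error", "motor_correct"):
                cda_rows.append({
                    "subject_id": data.profile.subject_id,
                    "hypothesis": hyp,
                    "condition": cond,
                    "value_uv": s[f"cda_{cond}"],
                    "n_trials": s[f"n_{cond}"],
                })
            row[f"cda_{hyp}_motor_error"] = s["cda_motor_error"]
            row[f"cda_{hyp}_motor_correct"] = s["cda_motor_correct"]
            row[f"cda_{hyp}_diff"] = s["cda_diff"]
            row[f"cda_{hyp}_avg"] = 0.5 * (s["cda_motor_error"] + s["cda_motor_correct"])
            for k, v in t.items():
                eeg_tallies[f"{hyp}_{k}"] = eeg_tallies.get(f"{hyp}_{k}", 0) + v
        err_wave, corr_wave, t2_times = condition_mean_waves(valid, data.epochs)
        t1 = apply_baseline(data.epochs, ARRAY_BASELINE)
        incong = (valid["congruency"] == "incongruent").to_numpy()
        responded = np.isfinite(valid["flanker_rt"].to_numpy(dtype=float))
        sel = valid.loc[incong & responded]
        row_of = {int(ti): i for i, ti in enumerate(t1.trial_index)}
        rows_sel = np.array([row_of[int(i)] for i in sel.index], dtype=int)
        sub = EpochSet(data=t1.data[rows_sel], channel_labels=t1.channel_labels,
                       sampling_rate=t1.sampling_rate, tmin=t1.tmin,
                       time_zero=t1.time_zero,
                       response_latency=t1.response_latency[rows_sel],
                       trial_index=t1.trial_index[rows_sel])
        w, keep, _ = contra_ipsi_wave(sub, sel["cue_side"].to_numpy())
        is_err = (sel["flanker_correct"].to_numpy() == 0.0)[keep]
        t1_err = w[is_err].mean(axis=0) if is_err.any() else None
        t1_corr = w[~is_err].mean(axis=0) if (~is_err).any() else None
        waves = {
            "t2": (err_wave, corr_wave, t2_times),
            "t1": (t1_err, t1_corr, t1.times),
        }
    return {"row": row, "cda_rows": cda_rows, "tally": tally,
            "eeg_tallies": eeg_tallies, "waves": waves}


def _group_waveform_table(stacks: dict[str, list[np.ndarray]], times: np.ndarray,
                          ) -> pd.DataFrame:
    df = pd.DataFrame({"time_ms": times})
    for cond, waves in stacks.items():
        arr = np.vstack(waves)
        df[f"mean_{cond}"] = arr.mean(axis=0)
        df[f"sem_{cond}"] = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
    return df


def run_full_analysis(config: RunConfig, with_epochs: bool = True,
                      subject_stream: Iterable[SubjectData] | None = None,
                      ) -> AnalysisReport:
    """Run the complete pipeline on a (simulated or supplied) cohort."""
    config.validate()
    log.info("cohort: %d subjects x %d trials, seed %d",
             config.cohort.n_subjects, config.cohort.n_trials, config.seed)

    if subject_stream is None:
        try:
            profiles = draw_subject_profiles(config.cohort, config.seed, config.traits)
        except Exception as exc:
            raise StageError(f"synthetic_cohort: {exc}") from exc
        subject_stream = (
            simulate_subject(p, config.cohort, config.seed, with_epochs=with_epochs)
            for p in profiles
        )

    rows, cda_rows, tallies, eeg_tallies = [], [], [], {}
    t1_stacks = {"motor_error": [], "motor_correct": []}
    t2_stacks = {"motor_error": [], "motor_correct": []}
    t1_times = t2_times = None
    for data in subject_stream:
        try:
            res = analyze_subject_data(data, config)
        except Exception as exc:
            raise StageError(
                f"subject {data.profile.subject_id}: {exc}") from exc
        rows.append(res["row"])
        cda_rows.extend(res["cda_rows"])
        tallies.append({"subject_id": data.profile.subject_id, **res["tally"]})
        for k, v in res["eeg_tallies"].items():
            eeg_tallies[k] = eeg_tallies.get(k, 0) + v
        if res["waves"] is not None:
            err, corr, t2t = res["waves"]["t2"]
            if err is not None and corr is not None:
                t2_stacks["motor_error"].append(err)
                t2_stacks["motor_correct"].append(corr)
                t2_times = t2t
            err, corr, t1t = res["waves"]["t1"]
            if err is not None and corr is not None:
                t1_stacks["motor_error"].append(err)
                t1_stacks["motor_correct"].append(corr)
                t1_times = t1t
        log.debug("subject %s analyzed", data.profile.subject_id)

    subjects = pd.DataFrame(rows)
    cda_table = pd.DataFrame(
        cda_rows, columns=["subject_id", "hypothesis", "condition",
                           "value_uv", "n_trials"])
    exclusions = pd.DataFrame(
        tallies, columns=["subject_id", "flanker_miss", "anticipatory", "wm_miss"])

    summary = _group_summary(subjects, t2_stacks, t2_times, config, eeg_tallies,
                             exclusions)
    waveforms = {}
    if t1_times is not None and t1_stacks["motor_error"]:
        waveforms["array_locked"] = _group_waveform_table(t1_stacks, t1_times)
    if t2_times is not None and t2_stacks["motor_error"]:
        waveforms["response_locked"] = _group_waveform_table(t2_stacks, t2_times)
    return AnalysisReport(subjects=subjects, cda_table=cda_table,
                          waveforms=waveforms, summary=summary,
                          exclusions=exclusions)


def _group_summary(subjects: pd.DataFrame, t2_stacks, t2_times,
                   config: RunConfig, eeg_tallies: dict, exclusions: pd.DataFrame,
                   ) -> dict:
    alpha = config.alpha

    def col(name):
        if name not in subjects:
            return np.array([])
        v = subjects[name].to_numpy(dtype=float)
        return v

    def paired(name_x, name_y):
        x, y = col(name_x), col(name_y)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 2:
            return None
        res = paired_t(x[ok], y[ok])
        rec = _ttest_record(res)
        rec["significant"] = bool(res.p < alpha)
        return rec

    def one_sample(name, mu0=0.0):
        x = col(name)
        x = x[np.isfinite(x)]
        if len(x) < 2:
            return None
        res = one_sample_t(x, mu0)
        rec = _ttest_record(res)
        rec["significant"] = bool(res.p < alpha)
        return rec

    summary: dict = {
        "provenance": {
            "package": "eriam",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
            "n_subjects": int(len(subjects)),
        },
    }

    k = col("k_mean")
    k = k[np.isfinite(k)]
    summary["capacity"] = {
        "k_mean": float(k.mean()) if len(k) else None,
        "k_se": float(k.std(ddof=1) / math.sqrt(len(k))) if len(k) > 1 else None,
        "k_min": float(k.min()) if len(k) else None,
        "k_max": float(k.max()) if len(k) else None,
    }

    er = col("eriam")
    er_ok = er[np.isfinite(er)]
    summary["eriam_mean"] = float(er_ok.mean()) if len(er_ok) else None
    summary["eriam_se"] = (float(er_ok.std(ddof=1) / math.sqrt(len(er_ok)))
                           if len(er_ok) > 1 else None)

    summary["behavior"] = {
        "error_rate_mean": float(np.nanmean(col("error_rate"))) if len(subjects) else None,
        "error_rate_se": (float(np.nanstd(col("error_rate"), ddof=1)
                                / math.sqrt(len(subjects)))
                          if len(subjects) > 1 else None),
        "mean_n_incongruent_errors": (float(np.nanmean(col("n_incongruent_errors")))
                                      if len(subjects) else None),
        "tests": {
            "acc_incongruent_vs_congruent": paired("acc_incongruent", "acc_congruent"),
            "rt_incongruent_vs_congruent": paired("rt_incongruent_correct",
                                                  "rt_congruent_correct"),
            "rt_error_vs_correct_incongruent": paired("rt_incongruent_error",
                                                      "rt_incongruent_correct"),
            "acc_post_error_vs_post_correct": paired("acc_post_error", "acc_post_correct"),
            "rt_post_error_vs_post_correct": paired("rt_post_error", "rt_post_correct"),
            "rt_interference_post": paired("rt_interference_post_error",
                                           "rt_interference_post_correct"),
            "acc_interference_post": paired("acc_interference_post_error",
                                            "acc_interference_post_correct"),
            "offset_incongruent_vs_congruent": paired("offset_incongruent_correct",
                                                      "offset_congruent_correct"),
            "offset_motor_error_vs_correct": paired("offset_motor_error",
                                                    "offset_motor_correct"),
            "wm_rt_incongruent_vs_congruent": paired("wm_rt_incongruent_correct",
                                                     "wm_rt_congruent_correct"),
            "wm_rt_error_vs_correct": paired("wm_rt_incongruent_error",
                                             "wm_rt_incongruent_correct"),
            "eriam_vs_zero": one_sample("eriam"),
        },
    }

    cda: dict = {}
    for hyp in config.hypotheses:
        err_col, corr_col = f"cda_{hyp}_motor_error", f"cda_{hyp}_motor_correct"
        if err_col not in subjects:
            continue
        x, y = col(err_col), col(corr_col)
        ok = np.isfinite(x) & np.isfinite(y)
        entry = {
            "motor_error_mean": float(x[ok].mean()) if ok.sum() else None,
            "motor_error_se": (float(x[ok].std(ddof=1) / math.sqrt(ok.sum()))
                               if ok.sum() > 1 else None),
            "motor_correct_mean": float(y[ok].mean()) if ok.sum() else None,
            "motor_correct_se": (float(y[ok].std(ddof=1) / math.sqrt(ok.sum()))
                                 if ok.sum() > 1 else None),
            "one_sample_motor_error": one_sample(err_col),
            "one_sample_motor_correct": one_sample(corr_col),
        }
        rec = _paired_with_bf(x[ok], y[ok], alpha) if ok.sum() >= 2 else None
        entry["paired"] = rec
        entry["bf"] = rec["bf"] if rec else None
        cda[hyp] = entry
    summary["cda"] = cda

    # divergence scan on the response-locked per-subject mean waves
    summary["divergence_window"] = None
    if (t2_times is not None and len(t2_stacks["motor_error"]) >= 2
            and len(t2_stacks["motor_error"]) == len(t2_stacks["motor_correct"])):
        win, _ = find_divergence_window(
            np.vstack(t2_stacks["motor_error"]),
            np.vstack(t2_stacks["motor_correct"]),
            t2_times, alpha=alpha, t_min=0.0)
        if win is not None:
            summary["divergence_window"] = {
                "start_ms": win.start, "end_ms": win.end,
                "reference_event": win.reference_event,
            }

    # brain-behavior correlations
    cda_k = []
    for hyp in config.hypotheses:
        name = f"cda_{hyp}_avg"
        x, y = col(name), col("k_mean")
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3:
            r = spearman_rho(x[ok], y[ok])
            cda_k.append({"window": hyp, "rho": r.rho, "p": r.p, "n": r.n,
                          "kind": r.kind})
    partial = []
    x, y, z = col("cda_H3_diff"), col("eriam"), col("k_mean")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    if ok.sum() >= 4:
        r1 = partial_spearman_rho(x[ok], y[ok], z[ok], control_name="capacity_K")
        partial.append({"x": "cda_H3_diff", "y": "eriam",
                        "control": r1.control_variable, "rho": r1.rho,
                        "p": r1.p, "n": r1.n, "kind": r1.kind})
        r2 = partial_spearman_rho(z[ok], y[ok], x[ok], control_name="cda_H3_diff")
        partial.append({"x": "capacity_K", "y": "eriam",
                        "control": r2.control_variable, "rho": r2.rho,
                        "p": r2.p, "n": r2.n, "kind": r2.kind})
    summary["correlations"] = {"cda_k": cda_k, "partial": partial}

    total_trials = int(len(subjects)) * config.cohort.n_trials
    excl_cols = [c for c in exclusions.columns if c != "subject_id"]
    excluded = int(exclusions[excl_cols].to_numpy().sum()) if len(exclusions) else 0
    summary["exclusions"] = {
        "by_reason": {c: int(exclusions[c].sum()) for c in excl_cols} if len(exclusions) else {},
        "eeg_drops": eeg_tallies,
        "total_trials": total_trials,
        "excluded_fraction": (excluded / total_trials) if total_trials else None,
    }
    return _nan_to_none(summary)


# ---------------------------------------------------------------------------
# disk interfaces


EVENTS_COLUMNS = [
    "subject_id", "block", "trial", "cue_side", "congruency",
    "col_l1", "col_l2", "col_l3", "col_r1", "col_r2", "col_r3",
    "probed_item", "true_color", "flanker_onset_in_epoch", "deadline",
    "flanker_rt", "flanker_correct", "wm_report", "wm_rt",
]


def write_events(trials: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated trial-events table, one row per trial, UTF-8, header."""
    trials.to_csv(path, sep="\t", index=False, columns=EVENTS_COLUMNS)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def generate_to_dir(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate the cohort and write events, change detection, and epochs."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = draw_subject_profiles(config.cohort, config.seed, config.traits)
    all_trials, all_cd = [], []
    for p in profiles:
        data = simulate_subject(p, config.cohort, config.seed)
        all_trials.append(data.trials)
        all_cd.append(data.change_detection)
        data.epochs.save(out / f"epochs_sub-{p.subject_id:03d}")
        log.info("wrote subject %03d", p.subject_id)
    write_events(pd.concat(all_trials, ignore_index=True), out / "events.tsv")
    pd.concat(all_cd, ignore_index=True).to_csv(
        out / "change_detection.tsv", sep="\t", index=False)
    write_toml(config, out / "config.toml")
    return out


def analyze_from_dir(config: RunConfig, data_dir: str | Path) -> AnalysisReport:
    """Run the analysis on a previously generated on-disk cohort."""
    data_dir = Path(data_dir)
    events = read_events(data_dir / "events.tsv")
    cd = pd.read_csv(data_dir / "change_detection.tsv", sep="\t")
    from .cohort import SubjectProfile

    def stream():
        for sid, trials in events.groupby("subject_id", sort=True):
            trials = trials.reset_index(drop=True)
            epochs = EpochSet.load(data_dir / f"epochs_sub-{sid:03d}")
            profile = SubjectProfile(
                subject_id=int(sid), capacity_K=float("nan"),
                cda_plateau=float("nan"), post_resp_level_correct=float("nan"),
                post_resp_level_error=float("nan"),
                impairment_propensity=float("nan"), rt_shift=float("nan"),
                error_rate_scale=float("nan"), offset_base=float("nan"),
                offset_congruent=float("nan"), wm_rt_base=float("nan"))
            yield SubjectData(profile, trials,
                              epochs, cd[cd["subject_id"] == sid])

    return run_full_analysis(config, subject_stream=stream())


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """CSV tables plus one JSON summary with stable column ordering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.subjects.to_csv(out / "subjects.csv", index=False)
    report.cda_table.to_csv(out / "cda.csv", index=False)
    report.exclusions.to_csv(out / "exclusions.csv", index=False)
    for name, df in report.waveforms.items():
        df.to_csv(out / f"waveform_{name}.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(_nan_to_none(report.summary), indent=1, sort_keys=True) + "\n")
    return out


def read_report(out_dir: str | Path) -> AnalysisReport:
    out = Path(out_dir)
    waveforms = {}
    for p in sorted(out.glob("waveform_*.csv")):
        waveforms[p.stem.removeprefix("waveform_")] = pd.read_csv(p)
    return AnalysisReport(
        subjects=pd.read_csv(out / "subjects.csv"),
        cda_table=pd.read_csv(out / "cda.csv"),
        waveforms=waveforms,
        summary=json.loads((out / "summary.json").read_text()),
        exclusions=pd.read_csv(out / "exclusions.csv"),
    )
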