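"""Synthetic cohort generator.

Produces everything the analysis consumes: latent subject traits, hybrid-task
trial schedules and behavior (flanker + continuous color report), a separate
change-detection session, and two-channel epoched EEG carrying a lateralized
component whose sustained amplitude and post-response disruption are tied to
the behavioral traits through a correlated latent model.

Subjects are reproducible independently of one another: one cohort seed spawns
per-subject substreams keyed by subject index, so regenerating subject *i*
never depends on how many subjects were simulated before it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal, special
from scipy import stats as sps

from .config import CohortConfig, ConfigError, TraitModel

CHANNEL_LABELS = ("PO7", "PO8")
CHANNEL_HEMISPHERES = ("left", "right")

# latent standard-normal axes of the trait model, in draw order
_LATENT_NAMES = (
    "capacity_K", "cda_plateau", "cda_diff", "impairment_propensity",
    "rt_shift", "error_rate_scale", "offset_base", "level_correct",
    "wm_rt_base",
)
# monotone direction of each observable trait in its latent coordinate;
# the plateau is minus a gamma quantile, hence decreasing
_LATENT_DIRECTION = {name: 1.0 for name in _LATENT_NAMES}
_LATENT_DIRECTION["cda_plateau"] = -1.0

# substream roles for SeedSequence spawn keys
_STREAM_PROFILES = 0
_STREAM_SCHEDULE = 1
_STREAM_FLANKER = 2
_STREAM_WM = 3
_STREAM_EEG = 4
_STREAM_CHANGEDET = 5


def _rng(seed, role: int, subject: int = 0) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("rng seed is required")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(role, subject)))


@dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject traits tying behavior and EEG together."""

    subject_id: int
    capacity_K: float
    cda_plateau: float
    post_resp_level_correct: float
    post_resp_level_error: float
    impairment_propensity: float
    rt_shift: float
    error_rate_scale: float
    offset_base: float
    offset_congruent: float
    wm_rt_base: float

    @property
    def cda_diff(self) -> float:
        """Post-response lateralized level difference, error minus correct."""
        return self.post_resp_level_error - self.post_resp_level_correct


@dataclass
class EpochSet:
    """Trials x channels x samples container, microvolts at a fixed rate.

    ``tmin`` is the time (ms) of sample 0 relative to ``time_zero``; the last
    sample sits one sample interval before ``tmin + n_samples/rate`` (the
    right edge is exclusive). ``response_latency`` is per trial, in ms on the
    same axis (NaN when the flanker response is missing).
    """

    data: np.ndarray
    channel_labels: tuple[str, str]
    sampling_rate: float
    tmin: float
    time_zero: str
    response_latency: np.ndarray
    trial_index: np.ndarray
    channel_hemispheres: tuple[str, str] = CHANNEL_HEMISPHERES

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels must match data")
        hemis = set(self.channel_hemispheres)
        if hemis != {"left", "right"}:
            raise ValueError("channel pair must contain one left and one right member")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sample_interval(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to the time-zero event."""
        return self.tmin + np.arange(self.n_samples) * self.sample_interval

    @property
    def tmax(self) -> float:
        """Exclusive right edge of the epoch, ms."""
        return self.tmin + self.n_samples * self.sample_interval

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(), channel_labels=self.channel_labels,
            sampling_rate=self.sampling_rate, tmin=self.tmin,
            time_zero=self.time_zero,
            response_latency=self.response_latency.copy(),
            trial_index=self.trial_index.copy(),
            channel_hemispheres=self.channel_hemispheres,
        )

    def save(self, stem: str | Path) -> tuple[Path, Path]:
        """Write raw little-endian float32 (trials x channels x samples) plus
        a JSON sidecar describing shape, axis, and per-trial latencies."""
        stem = Path(stem)
        raw = stem.with_suffix(".raw")
        meta = stem.with_suffix(".json")
        self.data.astype("<f4").tofile(raw)
        sidecar = {
            "shape": list(self.data.shape),
            "dtype": "<f4",
            "order": "trials_channels_samples",
            "channel_labels": list(self.channel_labels),
            "channel_hemispheres": list(self.channel_hemispheres),
            "sampling_rate": self.sampling_rate,
            "epoch_start_ms": self.tmin,
            "epoch_end_ms": self.tmax,
            "time_zero": self.time_zero,
            "response_latency_ms": [None if not np.isfinite(v) else float(v)
                                    for v in self.response_latency],
            "trial_index": [int(v) for v in self.trial_index],
        }
        meta.write_text(json.dumps(sidecar, indent=1))
        return raw, meta

    @classmethod
    def load(cls, stem: str | Path) -> "EpochSet":
        stem = Path(stem)
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        shape = tuple(sidecar["shape"])
        data = np.fromfile(stem.with_suffix(".raw"), dtype="<f4").reshape(shape)
        lat = np.array([np.nan if v is None else v
                        for v in sidecar["response_latency_ms"]], dtype=float)
        return cls(
            data=data.astype(float),
            channel_labels=tuple(sidecar["channel_labels"]),
            sampling_rate=float(sidecar["sampling_rate"]),
            tmin=float(sidecar["epoch_start_ms"]),
            time_zero=sidecar["time_zero"],
            response_latency=lat,
            trial_index=np.asarray(sidecar["trial_index"], dtype=int),
            channel_hemispheres=tuple(sidecar["channel_hemispheres"]),
        )

    def to_mne(self):
        """Optional export to an mne.EpochsArray (volts, seconds)."""
        import mne

        info = mne.create_info(list(self.channel_labels), self.sampling_rate, "eeg")
        return mne.EpochsArray(self.data * 1e-6, info, tmin=self.tmin / 1000.0,
                               verbose="error")


# ---------------------------------------------------------------------------
# subject traits


def _latent_correlation(trait_model: TraitModel) -> np.ndarray:
    """Latent Gaussian correlation matrix from injected Spearman targets."""
    names = list(_LATENT_NAMES)
    R = np.eye(len(names))
    for (a, b), rho_s in trait_model.correlation_dict().items():
        if a not in names or b not in names:
            raise ConfigError(f"unknown trait in correlation spec: {(a, b)}")
        if not -1.0 < rho_s < 1.0:
            raise ConfigError(f"correlation for {(a, b)} must be in (-1, 1)")
        # Spearman -> Gaussian copula Pearson, then flip into latent signs
        rho_g = 2.0 * math.sin(math.pi * rho_s / 6.0)
        rho_g *= _LATENT_DIRECTION[a] * _LATENT_DIRECTION[b]
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = rho_g
    return R


def draw_subject_profiles(
    config: CohortConfig,
    rng_seed=None,
    trait_model: TraitModel | None = None,
) -> list[SubjectProfile]:
    """Draw correlated subject traits for the cohort.

    Traits are correlated standard normals mapped through monotone transforms;
    injected correlations are therefore preserved on the Spearman scale. A
    non-positive-definite correlation specification is rejected.
    """
    if config.n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    if rng_seed is None:
        rng_seed = config.rng_seed
    tm = trait_model or TraitModel()
    R = _latent_correlation(tm)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(
            "trait correlation matrix is not positive definite"
        ) from exc
    rng = _rng(rng_seed, _STREAM_PROFILES)
    z = rng.standard_normal((config.n_subjects, len(_LATENT_NAMES))) @ chol.T
    cols = {name: z[:, i] for i, name in enumerate(_LATENT_NAMES)}

    capacity = np.clip(tm.capacity_mean + tm.capacity_sd * cols["capacity_K"],
                       *tm.capacity_bounds)
    # strictly negative plateau: minus a gamma marginal (Gaussian copula),
    # mean/sd as configured; gamma keeps the tail lighter than a lognormal
    # at this coefficient of variation
    m = abs(tm.cda_plateau_mean)
    shape_k = (m / tm.cda_plateau_sd) ** 2
    scale = tm.cda_plateau_sd ** 2 / m
    u = sps.norm.cdf(cols["cda_plateau"])
    plateau = -sps.gamma.ppf(u, a=shape_k, scale=scale)
    diff = tm.cda_diff_mean + tm.cda_diff_sd * cols["cda_diff"]
    level_correct = tm.level_correct_mean + tm.level_correct_sd * cols["level_correct"]
    level_error = level_correct + diff
    impairment = tm.impairment_mean + tm.impairment_sd * cols["impairment_propensity"]
    rt_shift = tm.rt_shift_sd * cols["rt_shift"]
    error_scale = np.clip(1.0 + tm.error_scale_sd * cols["error_rate_scale"],
                          *tm.error_scale_bounds)
    offset_base = np.clip(tm.offset_base_mean + tm.offset_base_sd * cols["offset_base"],
                          *tm.offset_base_bounds)
    wm_rt_base = config.wm_rt_mean + config.wm_rt_between_sd * cols["wm_rt_base"]

    return [
        SubjectProfile(
            subject_id=i,
            capacity_K=float(capacity[i]),
            cda_plateau=float(plateau[i]),
            post_resp_level_correct=float(level_correct[i]),
            post_resp_level_error=float(level_error[i]),
            impairment_propensity=float(impairment[i]),
            rt_shift=float(rt_shift[i]),
            error_rate_scale=float(error_scale[i]),
            offset_base=float(offset_base[i]),
            offset_congruent=float(offset_base[i] * tm.offset_congruent_ratio),
            wm_rt_base=float(wm_rt_base[i]),
        )
        for i in range(config.n_subjects)
    ]


# ---------------------------------------------------------------------------
# trial schedule


def min_circular_gap(colors: np.ndarray) -> np.ndarray:
    """Minimum pairwise circular distance (deg) within each row of hues."""
    srt = np.sort(np.asarray(colors, dtype=float) % 360.0, axis=-1)
    gaps = np.diff(srt, axis=-1)
    wrap = 360.0 - (srt[..., -1] - srt[..., 0])
    return np.minimum(gaps.min(axis=-1), wrap)


def _sample_display_colors(n: int, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n displays of six hues with pairwise separation >= min_sep."""
    out = np.empty((n, 6), dtype=int)
    filled = 0
    # joint acceptance for six uniform hues at 30 deg is ~1/32
    while filled < n:
        chunk = max(64, (n - filled) * 40)
        cand = rng.integers(0, 360, size=(chunk, 6))
        ok = cand[min_circular_gap(cand) >= min_sep]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate_trial_schedule(config: CohortConfig, rng_seed=None,
                            subject_id: int = 0) -> pd.DataFrame:
    """Schedule-only trial table: cue side, congruency, display colors, probe.

    Congruency and cue side are balanced within each block (counterbalanced
    cells, shuffled); display colors honor the joint 30-degree circular
    separation across all six hues; the probed item is uniform over 0-2.
    """
    config.validate()
    if rng_seed is None:
        rng_seed = config.rng_seed
    rng = _rng(rng_seed, _STREAM_SCHEDULE, subject_id)
    n = config.n_trials
    per_block = config.trials_per_block

    cue, cong = [], []
    cells = [(s, c) for s in ("left", "right") for c in ("congruent", "incongruent")]
    for _ in range(config.n_blocks):
        reps, rem = divmod(per_block, len(cells))
        block = cells * reps
        if rem:
            extra_idx = rng.choice(len(cells), size=rem, replace=False)
            block = block + [cells[i] for i in extra_idx]
        for k in rng.permutation(len(block)):
            cue.append(block[k][0])
            cong.append(block[k][1])

    colors = _sample_display_colors(n, config.color_min_separation, rng)
    probed = rng.integers(0, 3, size=n)
    df = pd.DataFrame({
        "subject_id": subject_id,
        "block": np.repeat(np.arange(1, config.n_blocks + 1), per_block),
        "trial": np.tile(np.arange(1, per_block + 1), config.n_blocks),
        "cue_side": cue,
        "congruency": cong,
        "col_l1": colors[:, 0], "col_l2": colors[:, 1], "col_l3": colors[:, 2],
        "col_r1": colors[:, 3], "col_r2": colors[:, 4], "col_r3": colors[:, 5],
        "probed_item": probed,
        "flanker_onset_in_epoch": config.flanker_onset,
    })
    left = df[["col_l1", "col_l2", "col_l3"]].to_numpy()
    right = df[["col_r1", "col_r2", "col_r3"]].to_numpy()
    cued = np.where((df["cue_side"] == "left").to_numpy()[:, None], left, right)
    df["true_color"] = cued[np.arange(n), probed]
    return df


def adapt_deadline(current_deadline: float, outcome: str, config: CohortConfig) -> float:
    """One staircase step of the flanker response deadline.

    Tighten after a timely correct response, relax after a miss, hold after a
    timely error; the result is clamped to [deadline_min, deadline_max].
    """
    if outcome == "in_time_correct":
        new = current_deadline - config.deadline_step_down
    elif outcome == "miss":
        new = current_deadline + config.deadline_step_up
    elif outcome == "in_time_error":
        new = current_deadline
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return min(max(new, config.deadline_min), config.deadline_max)


# ---------------------------------------------------------------------------
# flanker behavior


def simulate_flanker_behavior(profile: SubjectProfile, schedule: pd.DataFrame,
                              config: CohortConfig, rng_seed=None) -> pd.DataFrame:
    """Fill flanker RT/accuracy/deadline columns of a schedule.

    RTs follow a shifted lognormal per (congruency, accuracy) cell; responses
    slower than the running adaptive deadline become misses; a small
    anticipatory-response rate produces sub-150 ms responses that downstream
    filtering must exclude.
    """
    if rng_seed is None:
        rng_seed = config.rng_seed
    rng = _rng(rng_seed, _STREAM_FLANKER, profile.subject_id)
    n = len(schedule)
    incong = (schedule["congruency"] == "incongruent").to_numpy()

    p_err = np.where(incong, config.error_rate_incongruent, config.error_rate_congruent)
    p_err = np.clip(p_err * profile.error_rate_scale, 0.0, 1.0)
    is_err = rng.random(n) < p_err
    anticipatory = rng.random(n) < config.anticipatory_rate

    mean_cell = np.where(is_err, config.rt_mean_error,
                         np.where(incong, config.rt_mean_incongruent,
                                  config.rt_mean_congruent))
    comp_mean = mean_cell - config.rt_shift_base
    sigma = config.rt_log_sigma
    mu = np.log(comp_mean) - 0.5 * sigma * sigma
    shift = config.rt_shift_base + profile.rt_shift
    rt = shift + np.exp(mu + sigma * rng.standard_normal(n))
    rt = np.maximum(rt, config.rt_floor)
    # anticipatory responses violate the floor by construction and are a coin flip
    rt_ant = rng.uniform(80.0, config.rt_floor, size=n)
    correct = ~is_err
    ant_correct = rng.random(n) < 0.5
    rt = np.where(anticipatory, rt_ant, rt)
    correct = np.where(anticipatory, ant_correct, correct)

    deadline = np.empty(n)
    flanker_rt = np.full(n, np.nan)
    flanker_correct = np.full(n, np.nan)
    d = config.deadline_max
    for i in range(n):
        deadline[i] = d
        if rt[i] >= d:
            outcome = "miss"
        else:
            flanker_rt[i] = rt[i]
            flanker_correct[i] = 1.0 if correct[i] else 0.0
            outcome = "in_time_correct" if correct[i] else "in_time_error"
        d = adapt_deadline(d, outcome, config)

    out = schedule.copy()
    out["deadline"] = deadline
    out["flanker_rt"] = flanker_rt
    out["flanker_correct"] = flanker_correct
    return out


# ---------------------------------------------------------------------------
# working-memory reports

_KAPPA_GRID = None  # lazy (kappa, mean_abs_deg) table


def _von_mises_mean_abs_table() -> tuple[np.ndarray, np.ndarray]:
    global _KAPPA_GRID
    if _KAPPA_GRID is None:
        kappa = np.concatenate([[0.0], np.logspace(-3, 3, 600)])
        theta = np.linspace(0.0, np.pi, 4001)
        # E|theta| = int_0^pi theta e^{k cos t} dt / (pi I0(k)); use scaled
        # Bessel form for numerical stability at large kappa
        k = kappa[:, None]
        logw = k * (np.cos(theta)[None, :] - 1.0)
        w = np.exp(logw)
        num = np.trapezoid(theta[None, :] * w, theta, axis=1)
        den = np.pi * special.i0e(kappa)
        mean_abs = np.degrees(num / den)
        _KAPPA_GRID = (kappa, mean_abs)
    return _KAPPA_GRID


def kappa_for_mean_abs(target_deg: np.ndarray | float) -> np.ndarray:
    """Concentration of a centered von Mises with a given mean |error| (deg).

    Solved numerically from the analytic mean-absolute-deviation curve; the
    target must lie in (0, 90) -- 90 deg is the uniform limit.
    """
    kappa, mean_abs = _von_mises_mean_abs_table()
    t = np.atleast_1d(np.asarray(target_deg, dtype=float))
    if np.any((t <= 0) | (t >= 90.0)):
        raise ValueError("target mean absolute error must be in (0, 90) degrees")
    # mean_abs is decreasing in kappa; interpolate on the reversed axis
    return np.interp(t, mean_abs[::-1], kappa[::-1])


def simulate_wm_reports(profile: SubjectProfile, trials: pd.DataFrame,
                        config: CohortConfig, rng_seed=None) -> pd.DataFrame:
    """Fill the color-wheel report and its RT.

    The report error is a two-component mixture: a centered von Mises whose
    concentration is solved from the condition's target mean absolute offset,
    plus uniform guesses. Reports following motor errors are impaired by the
    subject's impairment propensity and are faster at the cohort level.
    """
    if rng_seed is None:
        rng_seed = config.rng_seed
    rng = _rng(rng_seed, _STREAM_WM, profile.subject_id)
    n = len(trials)
    incong = (trials["congruency"] == "incongruent").to_numpy()
    is_err = trials["flanker_correct"].to_numpy() == 0.0

    base = profile.offset_base
    target = np.where(incong, base, profile.offset_congruent)
    target = np.where(is_err, base * (1.0 + profile.impairment_propensity), target)
    target = np.clip(target, 5.0, 88.0)

    g = config.wm_guess_rate
    if g >= 1.0:
        err = rng.uniform(-180.0, 180.0, size=n)
    else:
        comp_target = np.clip((target - 90.0 * g) / (1.0 - g), 1.0, 89.9)
        kappa = kappa_for_mean_abs(comp_target)
        err = np.degrees(rng.vonmises(0.0, kappa))
        guess = rng.random(n) < g
        err = np.where(guess, rng.uniform(-180.0, 180.0, size=n), err)

    missing = rng.random(n) < config.wm_miss_rate
    report = (trials["true_color"].to_numpy() + err) % 360.0
    report[missing] = np.nan

    wm_rt = (profile.wm_rt_base
             + np.where(is_err, -config.wm_rt_error_speedup, 0.0)
             + np.where(incong, 0.0, config.wm_rt_congruent_offset)
             + config.wm_rt_sd * rng.standard_normal(n))
    wm_rt = np.maximum(wm_rt, config.wm_rt_floor)
    wm_rt[missing] = np.nan

    out = trials.copy()
    out["wm_report"] = report
    out["wm_rt"] = wm_rt
    return out


# ---------------------------------------------------------------------------
# EEG epochs


def lateralized_waveform(times_ms: np.ndarray, plateau: float,
                         level: float | None, response_ms: float | None,
                         config: CohortConfig) -> np.ndarray:
    """Deterministic lateralized component L(t) for one trial.

    Zero before the encoding ramp, linear ramp to the sustained plateau,
    hold until flanker onset, exponential relaxation toward zero until the
    response, then a logistic transition (over ~transition_width ms) to the
    post-response level. Without a response the relaxation simply continues.
    """
    t = np.asarray(times_ms, dtype=float)
    onset = config.flanker_onset
    L = np.zeros_like(t)
    ramp = (t >= config.ramp_start) & (t < config.ramp_end)
    L[ramp] = plateau * (t[ramp] - config.ramp_start) / (config.ramp_end - config.ramp_start)
    hold = (t >= config.ramp_end) & (t < onset)
    L[hold] = plateau
    relax = t >= onset
    L[relax] = plateau * np.exp(-(t[relax] - onset) / config.relax_tau)
    if response_ms is not None and np.isfinite(response_ms) and level is not None:
        post = t >= response_ms
        center = response_ms + config.transition_width / 2.0
        scale = config.transition_width / 6.6667
        s = special.expit((t[post] - center) / scale)
        L[post] = L[post] * (1.0 - s) + level * s
    return L


def _ar1_plus_white(shape: tuple[int, ...], config: CohortConfig,
                    rng: np.random.Generator) -> np.ndarray:
    sd = config.noise_sd
    if sd == 0.0:
        return np.zeros(shape)
    phi = config.ar1_coefficient
    var_ar = sd * sd * config.ar1_variance_fraction
    var_w = sd * sd - var_ar
    noise = np.zeros(shape)
    if var_ar > 0:
        innov = rng.standard_normal(shape) * math.sqrt(var_ar * (1.0 - phi * phi))
        x_prev = rng.standard_normal(shape[:-1] + (1,)) * math.sqrt(var_ar)
        zi = phi * x_prev
        ar, _ = signal.lfilter([1.0], [1.0, -phi], innov, axis=-1, zi=zi)
        noise += ar
    if var_w > 0:
        noise += rng.standard_normal(shape) * math.sqrt(var_w)
    return noise


def _shared_erp(times_ms: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Non-lateralized ERP C(t) common to both channels (cancels in the
    contra-ipsi subtraction; gives baselining something real to remove)."""
    t = times_ms
    onset = config.flanker_onset
    c = (1.5 * np.exp(-0.5 * ((t - 150.0) / 50.0) ** 2)
         - 1.2 * np.exp(-0.5 * ((t - 280.0) / 70.0) ** 2)
         + 1.0 * np.exp(-0.5 * ((t - onset - 170.0) / 60.0) ** 2))
    return c


def simulate_eeg_epochs(profile: SubjectProfile, trials: pd.DataFrame,
                        config: CohortConfig, rng_seed=None) -> EpochSet:
    """Array-locked two-channel epochs with the injected lateralized component.

    contralateral = C(t) + L(t)/2 and ipsilateral = C(t) - L(t)/2, with the
    left/right channel roles determined per trial by the cued side, plus
    independent AR(1)+white noise per channel.
    """
    if rng_seed is None:
        rng_seed = config.rng_seed
    rng = _rng(rng_seed, _STREAM_EEG, profile.subject_id)
    n = len(trials)
    times = config.epoch_start + np.arange(config.n_samples) * config.sample_interval

    flanker_rt = trials["flanker_rt"].to_numpy(dtype=float)
    responded = np.isfinite(flanker_rt)
    response_ms = np.where(responded, config.flanker_onset + flanker_rt, np.nan)
    is_err = trials["flanker_correct"].to_numpy() == 0.0
    level = np.where(is_err, profile.post_resp_level_error,
                     profile.post_resp_level_correct)

    L = np.empty((n, config.n_samples))
    for i in range(n):
        L[i] = lateralized_waveform(
            times, profile.cda_plateau,
            float(level[i]) if responded[i] else None,
            float(response_ms[i]) if responded[i] else None,
            config,
        )

    C = _shared_erp(times, config)
    cue_left = (trials["cue_side"] == "left").to_numpy()
    # contra is the hemisphere opposite the cued side: PO8 (right) when the
    # cue points left, PO7 (left) when it points right
    sign_po7 = np.where(cue_left, -1.0, 1.0)[:, None]
    data = np.empty((n, 2, config.n_samples))
    data[:, 0, :] = C[None, :] + sign_po7 * L / 2.0
    data[:, 1, :] = C[None, :] - sign_po7 * L / 2.0
    data += _ar1_plus_white((n, 2, config.n_samples), config, rng)

    return EpochSet(
        data=data,
        channel_labels=CHANNEL_LABELS,
        sampling_rate=config.sampling_rate,
        tmin=config.epoch_start,
        time_zero="array_onset",
        response_latency=response_ms,
        trial_index=np.arange(n),
    )


# ---------------------------------------------------------------------------
# change detection


def simulate_change_detection(profile: SubjectProfile, config: CohortConfig,
                              rng_seed=None) -> pd.DataFrame:
    """Change-detection session under the discrete-slot generative model.

    The probed item is stored with probability d = min(1, K/N); stored items
    yield correct responses, unstored items a 'change' guess with rate g, and
    an optional lapse flips the final response.
    """
    if rng_seed is None:
        rng_seed = config.rng_seed
    rng = _rng(rng_seed, _STREAM_CHANGEDET, profile.subject_id)
    rows = []
    per = config.change_detection_trials_per_set_size
    g = config.change_guess_rate
    for set_size in config.set_sizes:
        is_change = np.zeros(per, dtype=bool)
        is_change[: per // 2] = True
        rng.shuffle(is_change)
        d = min(1.0, profile.capacity_K / set_size)
        stored = rng.random(per) < d
        guess_change = rng.random(per) < g
        resp = np.where(stored, is_change, guess_change)
        if config.change_lapse_rate > 0:
            lapse = rng.random(per) < config.change_lapse_rate
            resp = np.where(lapse, ~resp, resp)
        rows.append(pd.DataFrame({
            "subject_id": profile.subject_id,
            "set_size": set_size,
            "is_change_trial": is_change,
            "response_change": resp,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort orchestration


@dataclass
class SubjectData:
    profile: SubjectProfile
    trials: pd.DataFrame
    epochs: EpochSet
    change_detection: pd.DataFrame


def simulate_subject(profile: SubjectProfile, config: CohortConfig,
                     rng_seed=None, with_epochs: bool = True) -> SubjectData:
    if rng_seed is None:
        rng_seed = config.rng_seed
    schedule = generate_trial_schedule(config, rng_seed, profile.subject_id)
    trials = simulate_flanker_behavior(profile, schedule, config, rng_seed)
    trials = simulate_wm_reports(profile, trials, config, rng_seed)
    epochs = (simulate_eeg_epochs(profile, trials, config, rng_seed)
              if with_epochs else None)
    cd = simulate_change_detection(profile, config, rng_seed)
    return SubjectData(profile, trials, epochs, cd)


def iter_cohort(config: CohortConfig, rng_seed=None,
                trait_model: TraitModel | None = None,
                with_epochs: bool = True) -> Iterator[SubjectData]:
    """Stream per-subject bundles; memory stays bounded by one subject."""
    if rng_seed is None:
        rng_seed = config.rng_seed
    profiles = draw_subject_profiles(config, rng_seed, trait_model)
    for profile in profiles:
        yield simulate_subject(profile, config, rng_seed, with_epochs=with_epochs)
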