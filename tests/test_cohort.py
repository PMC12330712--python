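"""Generator: schedules, traits, behavior, change detection, epochs."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from eriam import (CohortConfig, ConfigError, TraitModel, adapt_deadline,
                   draw_subject_profiles, generate_trial_schedule,
                   min_circular_gap, simulate_change_detection,
                   simulate_eeg_epochs, simulate_flanker_behavior,
                   simulate_subject, simulate_wm_reports)
from eriam.cohort import lateralized_waveform


class TestSchedule:
    def test_default_schedule_counts_and_balance(self):
        cfg = CohortConfig()
        sch = generate_trial_schedule(cfg, 0)
        assert len(sch) == 768
        assert (sch["congruency"] == "congruent").sum() == 384
        assert (sch["cue_side"] == "left").sum() == 384
        # balance holds within each block too
        per_block = sch.groupby("block")["congruency"].apply(
            lambda s: (s == "congruent").sum())
        assert set(per_block) == {16}
        assert set(sch["probed_item"]) <= {0, 1, 2}

    def test_color_separation_holds_across_all_six_hues(self):
        """>= 10^4 displays all satisfy the 30-degree joint constraint."""
        cfg = CohortConfig()
        mins = []
        for seed in range(14):  # 14 x 768 = 10752 displays
            sch = generate_trial_schedule(cfg, seed)
            cols = sch[["col_l1", "col_l2", "col_l3",
                        "col_r1", "col_r2", "col_r3"]].to_numpy()
            mins.append(min_circular_gap(cols).min())
        assert min(mins) >= 30.0

    def test_single_trial_schedule(self):
        cfg = dataclasses.replace(CohortConfig(), n_blocks=1, trials_per_block=1)
        sch = generate_trial_schedule(cfg, 0)
        assert len(sch) == 1
        cols = sch[["col_l1", "col_l2", "col_l3",
                    "col_r1", "col_r2", "col_r3"]].to_numpy()
        assert min_circular_gap(cols).min() >= 30.0

    def test_infeasible_color_constraint_rejected(self):
        cfg = dataclasses.replace(CohortConfig(), color_min_separation=61.0)
        with pytest.raises(ConfigError, match="infeasible"):
            generate_trial_schedule(cfg, 0)

    def test_array_to_probe_interval_fixed(self):
        cfg = CohortConfig()
        assert cfg.array_onset_to_probe == 2500.0
        assert cfg.flanker_onset == 900.0


class TestDeadlineStaircase:
    def test_steps_and_clamps(self):
        cfg = CohortConfig()
        down, up = cfg.deadline_step_down, cfg.deadline_step_up
        assert adapt_deadline(800.0, "in_time_correct", cfg) == 800.0 - down
        assert adapt_deadline(330.0, "in_time_correct", cfg) == 330.0
        assert adapt_deadline(800.0, "miss", cfg) == 800.0
        assert adapt_deadline(500.0, "miss", cfg) == 500.0 + up
        assert adapt_deadline(500.0, "in_time_error", cfg) == 500.0
        with pytest.raises(ValueError):
            adapt_deadline(500.0, "nonsense", cfg)


class TestSubjectProfiles:
    def test_identity_correlations_give_independent_traits(self):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=10_000)
        tm = dataclasses.replace(TraitModel(), correlations=())
        profs = draw_subject_profiles(cfg, 0, tm)
        df = pd.DataFrame([p.__dict__ for p in profs])
        cols = ["capacity_K", "cda_plateau", "impairment_propensity",
                "rt_shift", "error_rate_scale", "offset_base"]
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                assert abs(spearmanr(df[a], df[b]).statistic) < 0.03, (a, b)

    def test_default_correlations_recovered(self):
        """The generator's injected rank correlations are recovered at 10^4."""
        cfg = dataclasses.replace(CohortConfig(), n_subjects=10_000)
        profs = draw_subject_profiles(cfg, 1)
        df = pd.DataFrame([p.__dict__ for p in profs])
        df["cda_diff"] = df.post_resp_level_error - df.post_resp_level_correct
        injected = TraitModel().correlation_dict()
        got = {
            ("capacity_K", "cda_plateau"):
                spearmanr(df.capacity_K, df.cda_plateau).statistic,
            ("cda_diff", "impairment_propensity"):
                spearmanr(df.cda_diff, df.impairment_propensity).statistic,
            ("capacity_K", "impairment_propensity"):
                spearmanr(df.capacity_K, df.impairment_propensity).statistic,
        }
        for pair, rho in injected.items():
            assert got[pair] == pytest.approx(rho, abs=0.03), pair

    def test_cohort_capacity_calibration(self):
        """n=42 mean latent capacity within 3 SE of the reported 2.50."""
        profs = draw_subject_profiles(CohortConfig(), 0)
        k = np.array([p.capacity_K for p in profs])
        se = k.std(ddof=1) / math.sqrt(len(k))
        assert abs(k.mean() - 2.50) <= 3 * se

    def test_plateau_strictly_negative(self):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=5000)
        profs = draw_subject_profiles(cfg, 2)
        assert all(p.cda_plateau < 0 for p in profs)
        assert all(0.5 <= p.capacity_K <= 6.0 for p in profs)

    def test_non_positive_definite_matrix_rejected(self):
        tm = dataclasses.replace(TraitModel(), correlations=(
            (("capacity_K", "cda_plateau"), -0.99),
            (("capacity_K", "impairment_propensity"), 0.99),
            (("cda_plateau", "impairment_propensity"), -0.9),
        ))
        with pytest.raises(ConfigError, match="positive definite"):
            draw_subject_profiles(CohortConfig(), 0, tm)

    def test_deterministic_given_seed(self):
        a = draw_subject_profiles(CohortConfig(), 7)
        b = draw_subject_profiles(CohortConfig(), 7)
        assert a == b


class TestFlankerBehavior:
    def test_zero_error_scale_gives_no_errors(self, nominal_profile):
        cfg = CohortConfig()
        prof = dataclasses.replace(nominal_profile, error_rate_scale=0.0)
        sch = generate_trial_schedule(cfg, 0)
        tr = simulate_flanker_behavior(prof, sch, cfg, 0)
        responded = tr["flanker_correct"].dropna()
        # only anticipatory coin-flips can be wrong
        anticipatory = tr["flanker_rt"] < cfg.rt_floor
        assert (tr.loc[~anticipatory, "flanker_correct"].dropna() == 1.0).all()

    def test_responses_respect_deadline_and_floor(self, nominal_profile):
        cfg = CohortConfig()
        sch = generate_trial_schedule(cfg, 1)
        tr = simulate_flanker_behavior(nominal_profile, sch, cfg, 1)
        resp = tr.dropna(subset=["flanker_rt"])
        assert (resp["flanker_rt"] < resp["deadline"]).all()
        assert (resp["deadline"] >= cfg.deadline_min).all()
        assert (resp["deadline"] <= cfg.deadline_max).all()
        non_ant = resp[resp["flanker_rt"] >= 80.0 + 1e-9]
        # anticipatory rate ~1%: a handful of sub-150 ms responses exist
        assert (resp["flanker_rt"] < cfg.rt_floor).mean() < 0.05
        assert (resp["flanker_rt"] < cfg.rt_floor).sum() > 0

    def test_interference_direction(self, nominal_profile):
        cfg = CohortConfig()
        sch = generate_trial_schedule(cfg, 2)
        tr = simulate_flanker_behavior(nominal_profile, sch, cfg, 2)
        ok = tr["flanker_correct"] == 1.0
        inc = tr["congruency"] == "incongruent"
        assert (tr.loc[ok & inc, "flanker_rt"].mean()
                > tr.loc[ok & ~inc, "flanker_rt"].mean())
        assert (tr.loc[inc, "flanker_correct"].mean()
                < tr.loc[~inc, "flanker_correct"].mean())


class TestWMReports:
    def test_all_guesses_mean_offset_90(self, nominal_profile):
        cfg = dataclasses.replace(CohortConfig(), wm_guess_rate=1.0,
                                  wm_miss_rate=0.0)
        sch = generate_trial_schedule(cfg, 3)
        tr = simulate_flanker_behavior(nominal_profile, sch, cfg, 3)
        tr = simulate_wm_reports(nominal_profile, tr, cfg, 3)
        from eriam import wm_offsets
        off = wm_offsets(tr)
        assert off.mean() == pytest.approx(90.0, abs=2.5)

    def test_reports_faster_after_errors(self, nominal_profile):
        cfg = CohortConfig()
        sch = generate_trial_schedule(cfg, 4)
        tr = simulate_flanker_behavior(nominal_profile, sch, cfg, 4)
        tr = simulate_wm_reports(nominal_profile, tr, cfg, 4)
        err = tr["flanker_correct"] == 0.0
        ok = tr["flanker_correct"] == 1.0
        assert (tr.loc[ok, "wm_rt"].mean() - tr.loc[err, "wm_rt"].mean()
                == pytest.approx(97.1, abs=60.0))


class TestChangeDetection:
    def test_perfect_capacity_at_set_size(self, nominal_profile):
        cfg = CohortConfig()
        prof = dataclasses.replace(nominal_profile, capacity_K=4.0)
        cd = simulate_change_detection(prof, cfg, 0)
        four = cd[cd["set_size"] == 4]
        hits = four[four["is_change_trial"]]["response_change"]
        fas = four[~four["is_change_trial"]]["response_change"]
        assert hits.mean() == 1.0 and fas.mean() == 0.0

    def test_zero_guess_rate_no_false_alarms(self, nominal_profile):
        cfg = dataclasses.replace(CohortConfig(), change_guess_rate=0.0)
        cd = simulate_change_detection(nominal_profile, cfg, 1)
        fas = cd[~cd["is_change_trial"]]["response_change"]
        assert fas.sum() == 0

    def test_balanced_schedule(self, nominal_profile):
        cfg = CohortConfig()
        cd = simulate_change_detection(nominal_profile, cfg, 2)
        assert len(cd) == 192
        for n, grp in cd.groupby("set_size"):
            assert len(grp) == 64
            assert grp["is_change_trial"].sum() == 32

    def test_cowan_recovery_closed_form(self, nominal_profile):
        """E[N(hit-FA)] = min(K, N): Monte-Carlo at three set sizes."""
        cfg = dataclasses.replace(CohortConfig(),
                                  change_detection_trials_per_set_size=400_000)
        prof = dataclasses.replace(nominal_profile, capacity_K=2.5)
        cd = simulate_change_detection(prof, cfg, 3)
        for n, grp in cd.groupby("set_size"):
            hit = grp[grp["is_change_trial"]]["response_change"].mean()
            fa = grp[~grp["is_change_trial"]]["response_change"].mean()
            assert n * (hit - fa) == pytest.approx(min(2.5, n), abs=0.05)


class TestEEG:
    def test_noiseless_plateau_window(self, nominal_profile, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, n_blocks=1,
                                  trials_per_block=4)
        sch = generate_trial_schedule(cfg, 5)
        tr = simulate_flanker_behavior(nominal_profile, sch, cfg, 5)
        tr = simulate_wm_reports(nominal_profile, tr, cfg, 5)
        ep = simulate_eeg_epochs(nominal_profile, tr, cfg, 5)
        times = ep.times
        win = (times >= 500.0) & (times < 900.0)
        cue_left = (tr["cue_side"] == "left").to_numpy()
        contra = np.where(cue_left[:, None], ep.data[:, 1, :], ep.data[:, 0, :])
        ipsi = np.where(cue_left[:, None], ep.data[:, 0, :], ep.data[:, 1, :])
        diff = (contra - ipsi)[:, win]
        assert np.allclose(diff, nominal_profile.cda_plateau)

    def test_symmetric_profile_gives_zero_wave(self, noiseless_config):
        from eriam.cohort import SubjectProfile
        prof = SubjectProfile(0, 2.5, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
                              43.74, 41.46, 1777.0)
        cfg = dataclasses.replace(noiseless_config, n_blocks=1,
                                  trials_per_block=4)
        sch = generate_trial_schedule(cfg, 6)
        tr = simulate_flanker_behavior(prof, sch, cfg, 6)
        ep = simulate_eeg_epochs(prof, tr, cfg, 6)
        assert np.allclose(ep.data[:, 0, :] - ep.data[:, 1, :], 0.0)

    def test_noiseless_wave_equals_injected_component(self, nominal_profile,
                                                      noiseless_config):
        """contra - ipsi reproduces L(t) sample-for-sample without noise."""
        cfg = dataclasses.replace(noiseless_config, n_blocks=1,
                                  trials_per_block=8)
        sch = generate_trial_schedule(cfg, 7)
        tr = simulate_flanker_behavior(nominal_profile, sch, cfg, 7)
        ep = simulate_eeg_epochs(nominal_profile, tr, cfg, 7)
        times = ep.times
        for i in range(len(tr)):
            rt = tr["flanker_rt"].iloc[i]
            level = (nominal_profile.post_resp_level_error
                     if tr["flanker_correct"].iloc[i] == 0.0
                     else nominal_profile.post_resp_level_correct)
            L = lateralized_waveform(
                times, nominal_profile.cda_plateau,
                None if np.isnan(rt) else level,
                None if np.isnan(rt) else 900.0 + rt, cfg)
            sign = 1.0 if tr["cue_side"].iloc[i] == "left" else -1.0
            got = sign * (ep.data[i, 1, :] - ep.data[i, 0, :])
            np.testing.assert_allclose(got, L, atol=1e-12)

    def test_epoch_shape_and_axis(self, nominal_profile, small_config):
        data = simulate_subject(nominal_profile, small_config, 8)
        ep = data.epochs
        assert ep.data.shape == (small_config.n_trials, 2, 925)
        assert ep.times[0] == -1200.0
        assert ep.times[-1] == 2496.0
        assert ep.time_zero == "array_onset"
        assert set(ep.channel_hemispheres) == {"left", "right"}

    def test_bit_identical_under_same_seed(self, nominal_profile):
        cfg = dataclasses.replace(CohortConfig(), n_blocks=1, trials_per_block=8)
        a = simulate_subject(nominal_profile, cfg, 9)
        b = simulate_subject(nominal_profile, cfg, 9)
        assert np.array_equal(a.epochs.data, b.epochs.data)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.change_detection, b.change_detection)

    def test_epochs_roundtrip_to_disk(self, nominal_profile, tmp_path):
        cfg = dataclasses.replace(CohortConfig(), n_blocks=1, trials_per_block=4)
        data = simulate_subject(nominal_profile, cfg, 10)
        from eriam import EpochSet
        data.epochs.save(tmp_path / "ep")
        back = EpochSet.load(tmp_path / "ep")
        assert back.data.shape == data.epochs.data.shape
        np.testing.assert_allclose(back.data, data.epochs.data, atol=1e-3)
        assert back.time_zero == data.epochs.time_zero
        np.testing.assert_allclose(back.response_latency,
                                   data.epochs.response_latency, atol=1e-6)

    def test_optional_mne_export(self, nominal_profile):
        pytest.importorskip("mne")
        cfg = dataclasses.replace(CohortConfig(), n_blocks=1, trials_per_block=4)
        data = simulate_subject(nominal_profile, cfg, 11)
        epo = data.epochs.to_mne()
        assert epo.get_data(copy=True).shape[0] == 4
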