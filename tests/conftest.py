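import dataclasses

import pandas as pd
import pytest

from eriam import CohortConfig, TraitModel
from eriam.cohort import SubjectProfile


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Four blocks of 32 trials: enough error trials per subject to form
    conditions, small enough to keep epoch simulation cheap."""
    return dataclasses.replace(CohortConfig(), n_subjects=6, n_blocks=4,
                               trials_per_block=32, noise_sd=1.5)


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    return dataclasses.replace(CohortConfig(), noise_sd=0.0)


@pytest.fixture()
def nominal_profile() -> SubjectProfile:
    """A subject sitting at the calibrated trait means."""
    tm = TraitModel()
    return SubjectProfile(
        subject_id=0,
        capacity_K=tm.capacity_mean,
        cda_plateau=tm.cda_plateau_mean,
        post_resp_level_correct=tm.level_correct_mean,
        post_resp_level_error=tm.level_correct_mean + tm.cda_diff_mean,
        impairment_propensity=tm.impairment_mean,
        rt_shift=0.0,
        error_rate_scale=1.0,
        offset_base=tm.offset_base_mean,
        offset_congruent=tm.offset_base_mean * tm.offset_congruent_ratio,
        wm_rt_base=1777.0,
    )


def make_trials(offsets_error, offsets_correct, congruency="incongruent",
                subject_id=0):
    """Minimal trial table with prescribed report offsets (degrees)."""
    rows = []
    i = 0
    for off, is_err in ([(o, True) for o in offsets_error]
                        + [(o, False) for o in offsets_correct]):
        rows.append({
            "subject_id": subject_id, "block": 1, "trial": i + 1,
            "cue_side": "left", "congruency": congruency,
            "true_color": 100.0, "wm_report": (100.0 + off) % 360.0,
            "wm_rt": 1500.0, "flanker_rt": 400.0,
            "flanker_correct": 0.0 if is_err else 1.0,
            "deadline": 600.0, "probed_item": 0,
        })
        i += 1
    return pd.DataFrame(rows)
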