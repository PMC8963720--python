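import numpy as np
import pandas as pd
import pytest

from cogcap import ant, capacity, cohort, trials
from cogcap.cohort import ExGaussian, InformantReport, SubjectProfile

BLANK_REPORT = InformantReport("parent", (0,) * 9, (0,) * 9, (0,) * 8, 0)


def make_profile(subject_id="X", group="TD", true_ccc=3.26, ceiling_acc=0.985,
                 lapse_rate=0.02, mu_ms=450.0, sigma_ms=60.0, tau_ms=120.0,
                 alerting_ms=26.0, orienting_ms=37.0, conflict_ms=101.0,
                 ant_base_error=0.015, ant_conflict_error_extra=0.065):
    """Hand-built subject profile for targeted simulations."""
    return SubjectProfile(
        subject_id=subject_id, group=group, sex="M", age=11.0, school=0,
        parent_report=BLANK_REPORT, teacher_report=BLANK_REPORT,
        latent_rt=ExGaussian(mu_ms, sigma_ms, tau_ms),
        alerting_ms=alerting_ms, orienting_ms=orienting_ms, conflict_ms=conflict_ms,
        ant_base_error=ant_base_error,
        ant_conflict_error_extra=ant_conflict_error_extra,
        lapse_rate=lapse_rate, ceiling_acc=ceiling_acc, true_ccc=true_ccc)


def simulate_cohort_tables(seed, n_per_group=None):
    """Subjects + scored effects + capacity tables for one synthetic cohort."""
    cfg = cohort.CohortConfig(seed=seed, **(
        {"n_per_group": n_per_group} if n_per_group else {}))
    subs = cohort.generate_cohort(cfg)
    subj = cohort.subjects_to_frame(subs)
    ant_rows, mft_rows = [], []
    for i, s in enumerate(subs):
        ant_rows.append(trials.ant_trials_to_frame(
            trials.simulate_ant(s, seed=seed * 1009 + i)))
        mft_rows.append(trials.mft_trials_to_frame(
            trials.simulate_mft(s, seed=seed * 2003 + i)))
    eff = ant.score_cohort(pd.concat(ant_rows, ignore_index=True))
    cap = capacity.estimate_cohort(pd.concat(mft_rows, ignore_index=True))
    return subj, eff, cap


@pytest.fixture(scope="session")
def small_cohort_tables():
    """One small cohort shared by tests that only need realistic tables."""
    return simulate_cohort_tables(7, {"ADHD": 14, "subthreshold": 13, "TD": 14})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
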