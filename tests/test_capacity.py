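"""Information quantification and maximum-likelihood CCC estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogcap.capacity import (
    expected_samples, group_search_information, predict_accuracy,
    estimate_ccc, estimate_cohort, _loglik,
)
from cogcap.trials import make_mft_schedule, simulate_mft, mft_trials_to_frame
from conftest import make_profile


def monte_carlo_expected_samples(m, k, n_runs, rng):
    """Independent oracle: draw groups of g = (n+1)/2 arrows uniformly (with
    replacement of groups) until homogeneous; average the draw count."""
    n = m + k
    g = (n + 1) // 2
    arrows = np.array([1] * m + [0] * k)
    counts = np.zeros(n_runs, dtype=int)
    active = np.arange(n_runs)
    draws = 0
    while active.size:
        draws += 1
        pick = np.argpartition(rng.random((active.size, n)), g - 1, axis=1)[:, :g]
        vals = arrows[pick].sum(axis=1)
        homogeneous = (vals == g) | (vals == 0)
        counts[active] = draws
        active = active[~homogeneous]
    return counts.mean()


class TestInformation:
    def test_expected_samples_closed_form(self):
        assert expected_samples(1, 0) == 1.0
        assert expected_samples(3, 0) == 1.0
        assert expected_samples(2, 1) == 3.0
        assert expected_samples(5, 0) == 1.0
        assert expected_samples(4, 1) == 2.5
        assert expected_samples(3, 2) == 10.0

    def test_monte_carlo_oracle_agrees(self, rng):
        for m, k in ((2, 1), (4, 1), (3, 2)):
            mc = monte_carlo_expected_samples(m, k, 30_000, rng)
            assert mc == pytest.approx(expected_samples(m, k), rel=0.03)

    def test_zero_bits_for_single_arrow(self):
        assert group_search_information(1, 0) == 0.0

    @pytest.mark.parametrize("m,k", [(2, 2), (1, 1), (3, 4), (-1, 0), (2, -1)])
    def test_invalid_ratios_rejected(self, m, k):
        with pytest.raises(ValueError):
            group_search_information(m, k)


class TestPredictAccuracy:
    def test_zero_information_returns_ceiling(self):
        assert predict_accuracy(0.0, 0.25, 1.0, 0.97) == 0.97

    def test_continuity_at_the_knee(self):
        a0 = 0.99
        at = predict_accuracy(2.0, 1.0, 2.0, a0)
        just_above = predict_accuracy(2.0 + 1e-9, 1.0, 2.0, a0)
        assert at == a0
        assert just_above == pytest.approx(a0, abs=1e-6)

    def test_closed_form_example(self):
        assert predict_accuracy(4.91, 0.25, 3.0, 0.99) == pytest.approx(0.5749, abs=5e-4)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.floats(0.0, 6.0), st.floats(0.1, 2.0), st.floats(0.1, 8.0),
           st.floats(0.55, 1.0))
    def test_monotone_in_load_and_capacity(self, info, t, c, a0):
        p = predict_accuracy(info, t, c, a0)
        assert 0.5 <= p <= a0 + 1e-12
        assert predict_accuracy(info + 0.5, t, c, a0) <= p + 1e-12
        assert predict_accuracy(info, t, c + 0.5, a0) >= p - 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            predict_accuracy(-1.0, 0.25, 1.0, 0.9)
        with pytest.raises(ValueError):
            predict_accuracy(1.0, 0.0, 1.0, 0.9)
        with pytest.raises(ValueError):
            predict_accuracy(1.0, 0.25, 1.0, 0.4)


def simulate_subject_frame(true_ccc, a0, seed, reps=1, lapse=0.0):
    p = make_profile(true_ccc=true_ccc, ceiling_acc=a0, lapse_rate=lapse)
    frames = [mft_trials_to_frame(simulate_mft(p, make_mft_schedule(seed + r),
                                               seed=seed + r))
              for r in range(reps)]
    return pd.concat(frames, ignore_index=True)


class TestEstimateCcc:
    def test_parameter_recovery_at_high_trial_count(self):
        df = simulate_subject_frame(3.0, 0.99, seed=11, reps=10)
        est = estimate_ccc(df)
        assert est.ccc_bps == pytest.approx(3.0, abs=0.2)
        assert est.boundary_flag == "none"

    def test_all_correct_flags_upper_boundary(self):
        sched = make_mft_schedule(seed=1)
        df = mft_trials_to_frame(simulate_mft(
            make_profile(true_ccc=3.0), sched, seed=1))
        df["correct"] = 1
        df["responded"] = 1
        est = estimate_ccc(df)
        assert est.boundary_flag == "upper"

    def test_chance_performance_flags_lower_boundary(self):
        sched = make_mft_schedule(seed=2)
        df = mft_trials_to_frame(simulate_mft(
            make_profile(true_ccc=3.0), sched, seed=2))
        df["responded"] = 1
        # exactly half correct in every condition cell: guessing throughout
        pos = df.groupby(["majority_n", "minority_n", "exposure_s"]).cumcount()
        df["correct"] = (pos % 2).astype(int)
        est = estimate_ccc(df)
        assert est.boundary_flag == "lower"

    def test_grid_mle_matches_exhaustive_fine_grid(self):
        # oracle: exhaustive arithmetic grid at 0.001 resolution
        from cogcap.capacity import _cells_from_trials
        rng = np.random.default_rng(31)
        for i in range(20):
            true = float(rng.uniform(0.8, 5.0))
            df = simulate_subject_frame(true, 0.985, seed=100 + i)
            est = estimate_ccc(df)
            info, t, counts, n0, c0, _ = _cells_from_trials(df)
            a0 = float(np.clip(c0 / n0, 0.51, 0.999))
            grid = np.arange(0.05, 10.0 + 0.001, 0.001)
            ll = _loglik(grid, info, t, counts, a0)
            oracle = float(grid[np.argmax(ll)])
            assert est.ccc_bps == pytest.approx(oracle, abs=0.01)

    def test_scale_consistency(self):
        # multiplying all I and T by the same factor leaves C unchanged
        df = simulate_subject_frame(2.5, 0.98, seed=55)
        base = estimate_ccc(df).ccc_bps
        scaled = df.copy()
        scaled["exposure_s"] = scaled["exposure_s"] * 2.0
        # doubling T halves the information rate; the estimate must halve
        est2 = estimate_ccc(scaled).ccc_bps
        assert est2 == pytest.approx(base / 2.0, abs=0.05)

    def test_no_response_counts_as_error(self):
        df = simulate_subject_frame(3.0, 0.99, seed=77)
        lapsed = df.copy()
        hardest = (lapsed.majority_n == 3) & (lapsed.minority_n == 2) \
            & (lapsed.exposure_s == 0.25)
        lapsed.loc[hardest, "responded"] = 0
        lapsed.loc[hardest, "correct"] = 1  # must be ignored once responded=0
        est_full = estimate_ccc(df)
        est_lapsed = estimate_ccc(lapsed)
        assert est_lapsed.ccc_bps <= est_full.ccc_bps

    def test_too_few_cells_rejected(self):
        df = simulate_subject_frame(3.0, 0.99, seed=5)
        only_one = df[(df.majority_n == 1) & (df.exposure_s == 0.25)]
        with pytest.raises(ValueError, match="cells"):
            estimate_ccc(only_one)

    def test_monotone_recovery_of_group_means(self):
        means = []
        for true_mean, base in ((2.73, 300), (3.26, 600)):
            ests = []
            rng = np.random.default_rng(base)
            for i in range(12):
                true = max(0.3, float(rng.normal(true_mean, 0.61)))
                df = simulate_subject_frame(true, 0.985, seed=base + i)
                ests.append(estimate_ccc(df).ccc_bps)
            means.append(np.mean(ests))
        assert means[0] < means[1]

    def test_cohort_wrapper_covers_all_subjects(self, small_cohort_tables):
        subj, eff, cap = small_cohort_tables
        assert set(cap.subject_id) == set(subj.subject_id)
        assert (cap.ccc_bps > 0).all()
        assert (cap.log_likelihood <= 0).all()
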