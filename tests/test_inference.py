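"""Chi-square, covariate-adjusted ANOVA, partial correlations, Fisher z,
and BIC Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from cogcap.inference import (
    chisq_independence, ancova, partial_correlation, fisher_z_compare,
    bf_bic, bf_label,
)


class TestChisq:
    @pytest.mark.parametrize("table, printed, df", [
        ([[29, 10], [24, 10], [17, 19]], 6.87, 2),  # sex x group
        ([[29, 10], [17, 19]], 5.81, 1),            # TD vs ADHD sex
        ([[24, 10], [17, 19]], 3.93, 1),            # TD vs subthreshold sex
    ])
    def test_reported_sex_ratio_statistics(self, table, printed, df):
        res = chisq_independence(table)
        assert round(res.chi2, 2) == printed
        assert res.df == df

    def test_proportional_rows_zero(self):
        res = chisq_independence([[10, 20], [5, 10]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_undefined(self):
        res = chisq_independence([[0, 0], [5, 10]])
        assert np.isnan(res.chi2)
        assert "zero" in res.note

    def test_2x2_equals_squared_two_proportion_z(self, rng):
        for _ in range(20):
            k1, k2 = rng.integers(1, 25, 2)
            n1, n2 = k1 + rng.integers(1, 25), k2 + rng.integers(1, 25)
            res = chisq_independence([[k1, n1 - k1], [k2, n2 - k2]])
            p1, p2, p = k1 / n1, k2 / n2, (k1 + k2) / (n1 + n2)
            z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
            assert res.chi2 == pytest.approx(z ** 2)

    def test_rejects_tiny_or_negative_tables(self):
        with pytest.raises(ValueError):
            chisq_independence([[1, 2]])
        with pytest.raises(ValueError):
            chisq_independence([[1, -2], [3, 4]])


def two_model_f_oracle(y, groups, covariates):
    """Independent F via residual sums of squares of two nested OLS fits."""
    def design(with_group):
        cols = [np.ones(len(y))]
        if with_group:
            for g in sorted(set(groups))[1:]:
                cols.append((np.asarray(groups) == g).astype(float))
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or c in ("sex", "school"):
                for lev in sorted(col.astype(str).unique())[1:]:
                    cols.append((col.astype(str) == lev).astype(float).to_numpy())
            else:
                cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum()), X.shape[1]

    rss_full, k_full = rss(design(True))
    rss_red, k_red = rss(design(False))
    df_num = k_full - k_red
    df_den = len(y) - k_full
    return ((rss_red - rss_full) / df_num) / (rss_full / df_den)


class TestAncova:
    def make_data(self, seed=3, n=60, group_shift=40.0):
        rng = np.random.default_rng(seed)
        g = np.repeat(["A", "B", "C"], n // 3)
        cov = pd.DataFrame({"sex": rng.choice(["M", "F"], n),
                            "age": rng.normal(10, 1.5, n),
                            "school": rng.integers(0, 4, n)})
        y = rng.normal(600, 50, n) + (g == "A") * group_shift + 3 * cov["age"]
        return np.asarray(y), g, cov

    def test_matches_two_model_ols_oracle(self):
        y, g, cov = self.make_data()
        res = ancova(y, g, cov)
        assert res.F == pytest.approx(two_model_f_oracle(y, g, cov), rel=1e-9)

    def test_small_constructed_dataset_matches_oracle(self):
        y = np.array([5.0, 6, 7, 9, 11, 10, 4, 5, 6, 12, 13, 14])
        g = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        cov = pd.DataFrame({"age": [7, 8, 9, 10] * 3})
        res = ancova(y, g, cov)
        assert res.F == pytest.approx(two_model_f_oracle(y, g, cov), rel=1e-9)
        assert res.df_num == 2
        assert res.df_den == 12 - 2 - 1 - 1

    def test_no_covariates_equals_textbook_one_way_anova(self):
        rng = np.random.default_rng(10)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        g = np.array(["A"] * 8 + ["B"] * 8)
        res = ancova(y, g, pd.DataFrame(index=range(16)))
        means = [y[:8].mean(), y[8:].mean()]
        ssb = 8 * sum((m - y.mean()) ** 2 for m in means)
        ssw = sum(((y[:8] - means[0]) ** 2).sum() for _ in [0]) \
            + ((y[8:] - means[1]) ** 2).sum()
        f_textbook = (ssb / 1) / (ssw / 14)
        assert res.F == pytest.approx(f_textbook, rel=1e-9)

    def test_null_effect_large_n(self):
        rng = np.random.default_rng(11)
        n = 1200
        g = rng.choice(["A", "B", "C"], n)
        cov = pd.DataFrame({"age": rng.normal(10, 1, n)})
        y = rng.normal(0, 1, n)
        res = ancova(y, g, cov)
        assert res.F < 3.5
        assert res.eta_sq < 0.01

    def test_adjusted_means_and_posthoc_sign(self):
        y, g, cov = self.make_data(group_shift=60.0)
        res = ancova(y, g, cov)
        assert res.adjusted_group_means["A"] > res.adjusted_group_means["B"]
        ab = next(c for c in res.posthoc if {c.group_a, c.group_b} == {"A", "B"})
        assert ab.difference != 0
        assert 0 <= ab.p_bonferroni <= 1

    def test_rank_deficient_design_rejected(self):
        y = np.arange(12.0)
        g = np.array(["A"] * 6 + ["B"] * 6)
        cov = pd.DataFrame({"dup": (g == "A").astype(float)})
        with pytest.raises(ValueError, match="collinear|rank|Sum"):
            ancova(y, g, cov, categorical_covariates=())


def precision_matrix_partial_r(x, y, covs):
    """Oracle: r_xy.z = -P_xy / sqrt(P_xx P_yy), P the precision matrix."""
    m = np.column_stack([x, y] + [covs[c] for c in covs.columns])
    prec = np.linalg.inv(np.cov(m, rowvar=False))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_pearson(self, rng):
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        res = partial_correlation(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1])
        assert res.df == 28

    def test_regressing_out_a_duplicate_covariate_kills_r(self, rng):
        z = rng.normal(size=40)
        x = rng.normal(size=40)
        res = partial_correlation(x, z, pd.DataFrame({"z": z}),
                                  categorical_covariates=())
        assert res.note == "zero residual variance" or abs(res.r) < 1e-6

    def test_eight_point_dataset_matches_precision_matrix_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.0, 1, 4, 3, 7, 8, 6, 9])
        covs = pd.DataFrame({"z": [0.5, 1.2, 0.3, 2.2, 1.9, 0.7, 2.5, 1.1]})
        res = partial_correlation(x, y, covs, categorical_covariates=())
        assert res.r == pytest.approx(precision_matrix_partial_r(x, y, covs))
        assert res.df == 8 - 2 - 1

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.5 * x + 0.3 * z + rng.normal(size=40)
        mine = partial_correlation(x, y, pd.DataFrame({"z": z}),
                                   categorical_covariates=())
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                              "x", "y", covar="z")
        assert mine.r == pytest.approx(float(ref["r"].iloc[0]))
        assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_symmetry_and_covariate_rescaling_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        z = rng.normal(size=25)
        covs = pd.DataFrame({"z": z})
        scaled = pd.DataFrame({"z": 3.0 * z + 7.0})
        r_xy = partial_correlation(x, y, covs, categorical_covariates=()).r
        r_yx = partial_correlation(y, x, covs, categorical_covariates=()).r
        r_scaled = partial_correlation(x, y, scaled, categorical_covariates=()).r
        assert r_xy == pytest.approx(r_yx)
        assert r_xy == pytest.approx(r_scaled)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.4, 40, 0.4, 35)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        z, _ = fisher_z_compare(0.5, 50, 0.0, 50)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 47), rel=1e-12)
        assert round(z, 2) == 2.66

    def test_swapping_flips_sign(self):
        z1, p1 = fisher_z_compare(0.6, 30, 0.1, 45)
        z2, p2 = fisher_z_compare(0.1, 45, 0.6, 30)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 30, 0.2, 30)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.2, 30)


class TestBayesFactor:
    def test_identical_models_unit_bf(self):
        assert bf_bic(-100.0, 3, -100.0, 3, 50) == pytest.approx(1.0)

    def test_bic_difference_of_two(self):
        # choose fits so BIC_null - BIC_alt = 2 exactly
        n, k = 50, 3
        ll_null = -100.0
        ll_alt = ll_null + 1.0
        assert bf_bic(ll_null, k, ll_alt, k, n) == pytest.approx(np.e)

    def test_threshold_labels(self):
        assert bf_label(5.0) == "evidence for H1"
        assert bf_label(0.2) == "evidence for H0"
        assert bf_label(1.0) == "inconclusive"
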