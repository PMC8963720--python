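"""Group-level statistics: chi-square, covariate-adjusted ANOVA, partial
correlations, Fisher-z comparison of correlations, and BIC Bayes factors.

Conventions follow common clinical-neuropsychology practice: the Pearson
chi-square statistic carries no continuity correction; the group ANOVA
adjusts for child sex, age, and school (school as an unordered categorical)
with Type-III sums of squares and Bonferroni-corrected pairwise comparisons
of adjusted means; partial correlations are Pearson correlations of
covariate-residualized variables.  Bayes factors use the BIC approximation
BF10 = exp((BIC_null - BIC_alt)/2), which approximates — but does not
reproduce — default JZS Bayes factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    df: int
    p: float
    note: str = ""


def chisq_independence(table) -> ChisqResult:
    """Pearson chi-square test of independence (no continuity correction).

    A table with a zero row or column margin yields an undefined statistic
    (NaN) with an explanatory note rather than an exception.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return ChisqResult(chi2=float("nan"), df=df, p=float("nan"),
                           note="undefined: zero row or column margin")
    chi2, p, df_, _ = stats.chi2_contingency(t, correction=False)
    return ChisqResult(chi2=float(chi2), df=int(df_), p=float(p))


@dataclass(frozen=True)
class PosthocComparison:
    group_a: str
    group_b: str
    difference: float  # adjusted mean A - adjusted mean B
    t: float
    p_uncorrected: float
    p_bonferroni: float


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq: float
    adjusted_group_means: dict[str, float]
    posthoc: tuple[PosthocComparison, ...] = ()
    covariates: tuple[str, ...] = ()


def ancova(values, group_labels, covariates: pd.DataFrame | None = None,
           categorical_covariates: tuple[str, ...] = ("sex", "school")) -> AncovaResult:
    """One-way ANOVA of ``values`` over groups, adjusting for covariates.

    Covariate columns named in ``categorical_covariates`` are treated as
    unordered factors; the rest enter linearly.  The group F-test uses a
    Type-III decomposition (sum-coded factors).  Adjusted group means
    average model predictions over the observed covariate distribution,
    and pairwise contrasts of adjusted means carry Bonferroni-corrected
    p-values.
    """
    y = np.asarray(values, dtype=float)
    groups = pd.Series(group_labels, name="group").astype(str).reset_index(drop=True)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    data = pd.DataFrame({"y": y, "group": groups})
    terms = ["C(group, Sum)"]
    cov_names: tuple[str, ...] = ()
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        if len(cov) != len(data):
            raise ValueError("covariates must align with values")
        for c in cov.columns:
            data[c] = cov[c].to_numpy()
            if c in categorical_covariates or cov[c].dtype == object:
                terms.append(f"C({c}, Sum)")
            else:
                terms.append(c)
        cov_names = tuple(cov.columns)
    formula = "y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns among {terms}")
    table = anova_lm(model, typ=3)
    row = table.loc["C(group, Sum)"]
    ss_group = float(row["sum_sq"])
    ss_total = float(((y - y.mean()) ** 2).sum())
    F = float(row["F"])
    p = float(row["PR(>F)"])
    df_num = int(row["df"])
    df_den = int(model.df_resid)

    # adjusted means: average prediction over the whole sample with group
    # forced to each level in turn
    adjusted: dict[str, float] = {}
    design_rows: dict[str, np.ndarray] = {}
    from patsy import build_design_matrices
    design_info = model.model.data.design_info
    for g in levels:
        counterfactual = data.copy()
        counterfactual["group"] = g
        (X,) = build_design_matrices([design_info], counterfactual)
        xbar = np.asarray(X).mean(axis=0)
        design_rows[g] = xbar
        adjusted[g] = float(xbar @ model.params.to_numpy())

    n_pairs = len(levels) * (len(levels) - 1) // 2
    posthoc = []
    for a, b in combinations(levels, 2):
        contrast = design_rows[a] - design_rows[b]
        tt = model.t_test(contrast)
        p_unc = float(tt.pvalue)
        posthoc.append(PosthocComparison(
            group_a=a, group_b=b, difference=float(np.squeeze(tt.effect)),
            t=float(np.squeeze(tt.tvalue)), p_uncorrected=p_unc,
            p_bonferroni=min(1.0, p_unc * n_pairs)))

    return AncovaResult(F=F, df_num=df_num, df_den=df_den, p=p,
                        eta_sq=ss_group / ss_total if ss_total > 0 else float("nan"),
                        adjusted_group_means=adjusted, posthoc=tuple(posthoc),
                        covariates=cov_names)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    covariates: tuple[str, ...] = ()
    note: str = ""


def _covariate_matrix(covariates: pd.DataFrame | None,
                      categorical: tuple[str, ...]) -> tuple[np.ndarray, int, tuple[str, ...]]:
    """Design matrix (with intercept) and the number of covariate parameters."""
    if covariates is None or not len(covariates.columns):
        return np.ones((0, 1)), 0, ()
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for c in covariates.columns:
        col = covariates[c]
        if c in categorical or col.dtype == object:
            dummies = pd.get_dummies(col.astype("category"), prefix=c, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(col.astype(float))
    X = pd.concat(parts, axis=1).to_numpy(dtype=float)
    return X, X.shape[1] - 1, tuple(covariates.columns)


def partial_correlation(x, y, covariates: pd.DataFrame | None = None,
                        categorical_covariates: tuple[str, ...] = ("sex", "school"),
                        ) -> CorrelationResult:
    """Pearson correlation of x and y after linear removal of covariates.

    df = n - 2 - (number of covariate parameters); two-sided p from
    t = r sqrt(df / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    X, k, names = _covariate_matrix(covariates, categorical_covariates)
    if k:
        if X.shape[0] != n:
            raise ValueError("covariates must align with x and y")
        beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
        beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
        rx = x - X @ beta_x
        ry = y - X @ beta_y
    else:
        rx = x - x.mean()
        ry = y - y.mean()
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough observations for the covariate set")
    sx = float(np.sqrt((rx ** 2).sum()))
    sy = float(np.sqrt((ry ** 2).sum()))
    # residuals indistinguishable from numerical noise (e.g. a variable that
    # is itself a covariate) have no meaningful correlation
    tol_x = 1e-8 * float(np.sqrt(((x - x.mean()) ** 2).sum()) + 1e-300)
    tol_y = 1e-8 * float(np.sqrt(((y - y.mean()) ** 2).sum()) + 1e-300)
    if sx <= tol_x or sy <= tol_y:
        return CorrelationResult(r=float("nan"), df=df, p=float("nan"),
                                 covariates=names, note="zero residual variance")
    r = float((rx @ ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, df=df, p=p, covariates=names)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    normal p.  Swapping the argument pairs flips the sign of z.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def bf_bic(loglik_null: float, k_null: int, loglik_alt: float, k_alt: int,
           n: int) -> float:
    """BF10 from the BIC approximation on two nested fits of the same data.

    BF10 = exp((BIC_null - BIC_alt) / 2).  This is an approximation to a
    default Bayes factor, not a replacement for a full Bayesian analysis.
    """
    if n <= max(k_null, k_alt):
        raise ValueError("n must exceed the number of parameters")
    bic_null = k_null * np.log(n) - 2.0 * loglik_null
    bic_alt = k_alt * np.log(n) - 2.0 * loglik_alt
    return float(np.exp((bic_null - bic_alt) / 2.0))


def bf_label(bf10: float) -> str:
    """Conventional evidence label: >3 supports H1, <1/3 supports H0."""
    if bf10 > 3.0:
        return "evidence for H1"
    if bf10 < 1.0 / 3.0:
        return "evidence for H0"
    return "inconclusive"
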