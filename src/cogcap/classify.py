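"""SVM group prediction with repeated cross-validation and a shuffled-label
baseline.

Features are the three attention-network RT effects, overall ANT-I RT, and
the CCC, z-scored across all subjects entering the classification (the
historical whole-sample convention; fold-wise scaling is available and
avoids the train/test leakage that convention entails).  Each repeat draws
a random tenth of the sample as the test set, trains a linear soft-margin
SVM on the rest, and records test accuracy; the baseline accuracy scores
the same predictions against shuffled test labels.  Cross-classification
trains on one patient-vs-TD population and tests on random tenths of the
other, with per-population standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

FEATURE_SETS = {
    "attention": ("alerting_rt", "orienting_rt", "conflict_rt", "overall_rt"),
    "ccc": ("ccc_bps",),
    "combined": ("alerting_rt", "orienting_rt", "conflict_rt", "overall_rt", "ccc_bps"),
}


@dataclass(frozen=True)
class FeatureMatrix:
    X: pd.DataFrame  # z-scored, indexed by subject_id
    labels: pd.Series
    means: pd.Series
    sds: pd.Series
    dropped: tuple[str, ...] = ()

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


@dataclass(frozen=True)
class ClassificationResult:
    accuracies: np.ndarray
    baseline_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    chance: float | None
    t_stat: float
    p_value: float  # one-sided, accuracy > mean baseline
    n_resampled: int
    config: dict = field(default_factory=dict)


def chance_level(n_pos: int, n_neg: int) -> float:
    """Prevalence of the positive (more-affected) class: n_pos/(n_pos+n_neg)."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes need at least one subject")
    return n_pos / (n_pos + n_neg)


def build_features(effects: pd.DataFrame, capacity: pd.DataFrame,
                   subjects: pd.DataFrame, feature_set: str = "combined",
                   standardize: bool = True) -> FeatureMatrix:
    """Assemble and z-score the feature matrix for the selected subjects.

    Subjects missing from either task table are dropped (and recorded).
    Standardization uses the sample mean and SD (ddof=1) over all rows of
    the assembled matrix — the population entering this classification.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"choose from {sorted(FEATURE_SETS)}")
    cols = FEATURE_SETS[feature_set]
    eff = effects.set_index("subject_id")
    cap = capacity.set_index("subject_id")
    sub = subjects.set_index("subject_id")
    merged = eff.join(cap[["ccc_bps"]], how="inner").join(sub[["group"]], how="inner")
    dropped = tuple(sorted(set(sub.index) - set(merged.index)))
    merged = merged.dropna(subset=list(cols))
    X = merged[list(cols)].astype(float)
    means = X.mean()
    sds = X.std(ddof=1)
    if standardize:
        if (sds == 0).any():
            bad = list(sds.index[sds == 0])
            raise ValueError(f"zero-variance feature(s): {bad}")
        X = (X - means) / sds
    return FeatureMatrix(X=X, labels=merged["group"], means=means, sds=sds,
                         dropped=dropped)


def _accuracy_and_baseline(clf: SVC, X_test: np.ndarray, y_test: np.ndarray,
                           rng: np.random.Generator) -> tuple[float, float]:
    pred = clf.predict(X_test)
    acc = float((pred == y_test).mean())
    shuffled = rng.permutation(y_test)
    baseline = float((pred == shuffled).mean())
    return acc, baseline


def _draw_test_indices(n: int, n_test: int, y: np.ndarray,
                       rng: np.random.Generator, max_tries: int = 1000,
                       ) -> tuple[np.ndarray, int]:
    """A random test subset whose complement keeps both classes; test sets
    containing a single class are resampled."""
    resampled = 0
    for _ in range(max_tries):
        test_idx = rng.choice(n, size=n_test, replace=False)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if len(np.unique(y[test_idx])) == 2 and len(np.unique(y[train_mask])) == 2:
            return test_idx, resampled
        resampled += 1
    raise RuntimeError("could not draw a two-class test split")


def repeated_cv(features: pd.DataFrame | FeatureMatrix, labels=None,
                n_repeats: int = 1000, test_fraction: float = 0.1,
                seed: int = 0, mode: str = "subsample",
                svm_c: float = 1.0) -> ClassificationResult:
    """Repeated cross-validated linear-SVM accuracy with shuffled baseline.

    ``mode='subsample'`` draws one random test tenth per repeat (the
    default); ``mode='kfold'`` runs a classical shuffled 10-fold partition
    per repeat and averages the fold accuracies.
    """
    if isinstance(features, FeatureMatrix):
        X = features.X.to_numpy(dtype=float)
        y = features.labels.to_numpy()
    else:
        X = np.asarray(features, dtype=float)
        y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 subjects each")
    if mode not in ("subsample", "kfold"):
        raise ValueError("mode must be 'subsample' or 'kfold'")
    n = len(y)
    n_test = max(2, ceil(n * test_fraction))
    rng = np.random.default_rng(seed)

    accs = np.empty(n_repeats)
    bases = np.empty(n_repeats)
    n_resampled = 0
    for rep in range(n_repeats):
        if mode == "subsample":
            test_idx, extra = _draw_test_indices(n, n_test, y, rng)
            n_resampled += extra
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            clf = SVC(kernel="linear", C=svm_c)
            clf.fit(X[train_mask], y[train_mask])
            accs[rep], bases[rep] = _accuracy_and_baseline(
                clf, X[test_idx], y[test_idx], rng)
        else:
            order = rng.permutation(n)
            fold_accs, fold_bases = [], []
            for fold in np.array_split(order, 10):
                train_mask = np.ones(n, dtype=bool)
                train_mask[fold] = False
                if len(np.unique(y[train_mask])) < 2:
                    continue
                clf = SVC(kernel="linear", C=svm_c)
                clf.fit(X[train_mask], y[train_mask])
                a, b = _accuracy_and_baseline(clf, X[fold], y[fold], rng)
                fold_accs.append(a)
                fold_bases.append(b)
            accs[rep] = float(np.mean(fold_accs))
            bases[rep] = float(np.mean(fold_bases))

    t_stat, p_value = _vs_baseline(accs, bases)
    counts_sorted = {str(c): int(k) for c, k in zip(classes, counts)}
    return ClassificationResult(
        accuracies=accs, baseline_accuracies=bases,
        mean_accuracy=float(accs.mean()), sd_accuracy=float(accs.std(ddof=1)),
        chance=None, t_stat=t_stat, p_value=p_value, n_resampled=n_resampled,
        config={"mode": mode, "n_repeats": n_repeats, "test_fraction": test_fraction,
                "seed": seed, "svm_c": svm_c, "kernel": "linear",
                "class_counts": counts_sorted})


def _vs_baseline(accs: np.ndarray, bases: np.ndarray) -> tuple[float, float]:
    """One-sided one-sample t-test of accuracies against the mean baseline."""
    null = float(bases.mean())
    if np.allclose(accs, accs[0]):
        # degenerate: zero variance across repeats
        t = np.inf if accs[0] > null else (-np.inf if accs[0] < null else 0.0)
        p = 0.0 if accs[0] > null else 1.0
        return float(t), float(p)
    res = stats.ttest_1samp(accs, popmean=null, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def cross_classify(features_train: FeatureMatrix | pd.DataFrame, labels_train=None,
                   features_test: FeatureMatrix | pd.DataFrame = None, labels_test=None,
                   n_repeats: int = 1000, test_fraction: float = 0.1,
                   seed: int = 0, svm_c: float = 1.0) -> ClassificationResult:
    """Train on the full training population, test on random tenths of the
    other population (both standardized separately beforehand)."""
    if isinstance(features_train, FeatureMatrix):
        X_tr = features_train.X.to_numpy(dtype=float)
        y_tr = features_train.labels.to_numpy()
    else:
        X_tr = np.asarray(features_train, dtype=float)
        y_tr = np.asarray(labels_train)
    if isinstance(features_test, FeatureMatrix):
        X_te = features_test.X.to_numpy(dtype=float)
        y_te = features_test.labels.to_numpy()
    else:
        X_te = np.asarray(features_test, dtype=float)
        y_te = np.asarray(labels_test)
    if len(np.unique(y_tr)) != 2:
        raise ValueError("training population must contain two classes")

    n = len(y_te)
    n_test = max(2, ceil(n * test_fraction))
    rng = np.random.default_rng(seed)
    clf = SVC(kernel="linear", C=svm_c)
    clf.fit(X_tr, y_tr)

    accs = np.empty(n_repeats)
    bases = np.empty(n_repeats)
    n_resampled = 0
    for rep in range(n_repeats):
        test_idx, extra = _draw_test_indices(n, n_test, y_te, rng)
        n_resampled += extra
        accs[rep], bases[rep] = _accuracy_and_baseline(
            clf, X_te[test_idx], y_te[test_idx], rng)

    t_stat, p_value = _vs_baseline(accs, bases)
    return ClassificationResult(
        accuracies=accs, baseline_accuracies=bases,
        mean_accuracy=float(accs.mean()), sd_accuracy=float(accs.std(ddof=1)),
        chance=None, t_stat=t_stat, p_value=p_value, n_resampled=n_resampled,
        config={"mode": "cross", "n_repeats": n_repeats,
                "test_fraction": test_fraction, "seed": seed, "svm_c": svm_c,
                "kernel": "linear"})


def compare_feature_sets(result_a: ClassificationResult,
                         result_b: ClassificationResult) -> tuple[float, float]:
    """Two-sample t-test on the per-repeat accuracy vectors of two feature
    sets evaluated on the same classification target."""
    a = result_a.accuracies
    b = result_b.accuracies
    if len(a) != len(b):
        raise ValueError("accuracy vectors must have equal length")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)
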