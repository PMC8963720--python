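"""Information content of majority-judgment conditions and CCC estimation.

The backward-masked Majority Function Task presents 1, 3, or 5 arrows for a
fixed exposure time T; the child reports the majority direction.  Under the
grouping-search decision strategy the observer repeatedly samples a group of
g = (n+1)/2 arrows until the group is homogeneous, whose direction then
determines the majority.  With groups drawn uniformly (with replacement of
groups) from the n arrows, the probability that a sample is homogeneous is

    p_hom = [C(m, g) + C(k, g)] / C(n, g)

for a majority:minority split m:k (C(k, g) = 0 when k < g), so the expected
number of samples is E[S] = 1 / p_hom and the information conveyed by the
condition is

    I = log2(g * E[S])   bits.

The cognitive control capacity C (bits/s) is the highest information rate
I/T at which accuracy remains at its ceiling a0.  Beyond it, only the
fraction C*T/I of the information can be processed and accuracy descends
linearly toward the 0.5 guessing floor:

    P(correct) = a0                              if I <= C*T
                 0.5 + (a0 - 0.5) * C*T / I      otherwise.

C is estimated per subject by maximizing the Bernoulli likelihood of the
trial outcomes over a grid, with a0 fixed from the zero-information 1:0
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log2

import numpy as np
import pandas as pd

#: the six majority:minority splits used by the task
RATIOS = ((1, 0), (3, 0), (2, 1), (5, 0), (4, 1), (3, 2))
EXPOSURES_S = (0.25, 0.5, 1.0)

GUESS_FLOOR = 0.5


def _check_ratio(m: int, k: int) -> None:
    if m <= k or k < 0:
        raise ValueError(f"majority must exceed minority: got {m}:{k}")
    if (m + k) % 2 == 0:
        raise ValueError(f"set size must be odd: got {m + k}")


def expected_samples(m: int, k: int) -> float:
    """Expected number of group samples E[S] until a homogeneous group.

    Closed form from the hypergeometric probability of drawing a
    homogeneous group of size g = (n+1)/2 out of the n = m + k arrows.
    """
    _check_ratio(m, k)
    n = m + k
    g = (n + 1) // 2
    hom = comb(m, g) + (comb(k, g) if k >= g else 0)
    return comb(n, g) / hom


def group_search_information(m: int, k: int) -> float:
    """Information amount I = log2(g * E[S]) in bits for an m:k arrow set."""
    _check_ratio(m, k)
    g = (m + k + 1) // 2
    return log2(g * expected_samples(m, k))


def predict_accuracy(info_bits, exposure_s, ccc_bps, ceiling_acc):
    """Model accuracy for information load ``info_bits`` at exposure
    ``exposure_s`` given capacity ``ccc_bps`` and ceiling ``ceiling_acc``.

    Ceiling while the processable amount C*T covers I; otherwise a linear
    descent toward the guessing floor in the processed fraction C*T/I.
    Continuous at the knee I = C*T.  Accepts scalars or arrays.
    """
    info = np.asarray(info_bits, dtype=float)
    t = np.asarray(exposure_s, dtype=float)
    c = np.asarray(ccc_bps, dtype=float)
    a0 = np.asarray(ceiling_acc, dtype=float)
    if np.any(info < 0):
        raise ValueError("information amount must be >= 0")
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValueError("exposure time and capacity must be > 0")
    if np.any(a0 <= GUESS_FLOOR) or np.any(a0 > 1.0):
        raise ValueError("ceiling accuracy must lie in (0.5, 1]")
    load = c * t
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(info > 0, load / np.maximum(info, 1e-300), np.inf)
    p = np.where(info <= load, a0, GUESS_FLOOR + (a0 - GUESS_FLOOR) * np.minimum(frac, 1.0))
    if p.ndim == 0:
        return float(p)
    return p


@dataclass(frozen=True)
class InfoCondition:
    """One (ratio, exposure) cell with its information bookkeeping."""

    majority: int
    minority: int
    exposure_s: float

    @property
    def set_size(self) -> int:
        return self.majority + self.minority

    @property
    def group_size(self) -> int:
        return (self.set_size + 1) // 2

    @property
    def expected_samples(self) -> float:
        return expected_samples(self.majority, self.minority)

    @property
    def info_bits(self) -> float:
        return group_search_information(self.majority, self.minority)

    @property
    def info_rate(self) -> float:
        return self.info_bits / self.exposure_s


@dataclass(frozen=True)
class CapacityEstimate:
    subject_id: str
    ccc_bps: float
    ceiling_acc: float
    log_likelihood: float
    boundary_flag: str  # "none" / "lower" / "upper"
    n_trials: int
    grid: tuple[float, float, int]  # (min, max, coarse points)


def _cells_from_trials(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                                      int, int, int]:
    """Aggregate trials into (I, T, n, n_correct) cells.

    No-response trials count as errors.  Returns the 1:0-condition totals
    separately: that condition carries zero information and anchors a0.
    """
    df = trials.copy()
    df["correct_eff"] = df["correct"].astype(bool) & df["responded"].astype(bool)
    info = np.array([group_search_information(m, k)
                     for m, k in zip(df["majority_n"], df["minority_n"])])
    df["info_bits"] = info
    zero = df["info_bits"] == 0.0
    n0 = int(zero.sum())
    c0 = int(df.loc[zero, "correct_eff"].sum())
    loaded = df.loc[~zero]
    cells = loaded.groupby(["info_bits", "exposure_s"], as_index=False).agg(
        n=("correct_eff", "size"), n_correct=("correct_eff", "sum"))
    return (cells["info_bits"].to_numpy(), cells["exposure_s"].to_numpy(),
            np.stack([cells["n"].to_numpy(), cells["n_correct"].to_numpy()]),
            n0, c0, len(df))


def _loglik(grid: np.ndarray, info: np.ndarray, t: np.ndarray,
            counts: np.ndarray, a0: float) -> np.ndarray:
    n, n_correct = counts
    p = predict_accuracy(info[None, :], t[None, :], grid[:, None], a0)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return (n_correct[None, :] * np.log(p)
            + (n - n_correct)[None, :] * np.log1p(-p)).sum(axis=1)


def estimate_ccc(trials: pd.DataFrame, subject_id: str | None = None,
                 grid_min: float = 0.05, grid_max: float = 10.0,
                 n_coarse: int = 400, refine_step: float = 0.001,
                 fixed_a0: float | None = None) -> CapacityEstimate:
    """Maximum-likelihood CCC for one subject's majority-task trials.

    ``trials`` needs columns majority_n, minority_n, exposure_s, responded,
    correct.  The ceiling a0 is fixed from the 1:0-condition accuracy
    (clipped to [0.51, 0.999]) unless ``fixed_a0`` overrides it; capacity is
    the only free parameter, maximized on a log-spaced coarse grid and then
    refined arithmetically around the coarse optimum.
    """
    required = {"majority_n", "minority_n", "exposure_s", "responded", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table is missing columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValueError("no trials supplied")
    if subject_id is None:
        subject_id = (str(trials["subject_id"].iloc[0])
                      if "subject_id" in trials.columns else "")

    info, t, counts, n0, c0, n_total = _cells_from_trials(trials)
    n_cells = len(info) + (1 if n0 else 0)
    if n_cells < 6:
        raise ValueError(f"need trials in >= 6 of the 18 cells, got {n_cells}")

    if fixed_a0 is not None:
        a0 = float(fixed_a0)
        if not GUESS_FLOOR < a0 <= 1.0:
            raise ValueError("fixed_a0 must lie in (0.5, 1]")
    else:
        if n0 == 0:
            raise ValueError("no zero-information (1:0) trials to anchor the ceiling; "
                             "pass fixed_a0 instead")
        a0 = float(np.clip(c0 / n0, 0.51, 0.999))

    coarse = np.geomspace(grid_min, grid_max, n_coarse)
    ll = _loglik(coarse, info, t, counts, a0)
    best = int(np.argmax(ll))
    lo = coarse[max(best - 1, 0)]
    hi = coarse[min(best + 1, n_coarse - 1)]
    fine = np.arange(lo, hi + refine_step, refine_step)
    llf = _loglik(fine, info, t, counts, a0)
    j = int(np.argmax(llf))
    c_hat = float(fine[j])
    ll_hat = float(llf[j])

    if c_hat <= coarse[1]:  # within one coarse step of a bound
        flag = "lower"
    elif c_hat >= coarse[-2]:
        flag = "upper"
    else:
        flag = "none"
    return CapacityEstimate(subject_id=subject_id, ccc_bps=c_hat, ceiling_acc=a0,
                            log_likelihood=ll_hat, boundary_flag=flag,
                            n_trials=n_total, grid=(grid_min, grid_max, n_coarse))


def estimate_cohort(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-subject CCC estimates for a multi-subject trial table."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        est = estimate_ccc(sub, subject_id=str(sid), **kwargs)
        rows.append({"subject_id": est.subject_id, "ccc_bps": est.ccc_bps,
                     "ceiling_acc": est.ceiling_acc,
                     "log_likelihood": est.log_likelihood,
                     "boundary_flag": est.boundary_flag,
                     "n_trials": est.n_trials})
    return pd.DataFrame(rows)
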