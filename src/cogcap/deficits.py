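"""Normative-decile deficit flagging and group frequency comparison.

The cut point for each measure is the decile of the typically-developing
(TD) reference distribution that bounds its worst tail: the 10th percentile
of CCC (lower is worse) and, by default, the 90th percentile of each
attention effect (larger is worse).  A subject is flagged when strictly
beyond the cut in the deficit direction.  Deficit frequencies between two
groups are compared with a Pearson chi-square test of independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cogcap.inference import chisq_independence, ChisqResult

#: deficit direction per measure: True = larger values are deficient
ABOVE_IS_DEFICIT = {
    "alerting_rt": True,
    "orienting_rt": True,
    "conflict_rt": True,
    "overall_rt": True,
    "ccc_bps": False,
}
DECILE = 0.10


@dataclass(frozen=True)
class DeficitCutpoints:
    cuts: dict[str, float]
    directions: dict[str, str]  # "above" / "below"
    n_reference: int


def compute_cutpoints(td_measures: pd.DataFrame,
                      measures: list[str] | None = None,
                      literal_tenth: bool = False) -> DeficitCutpoints:
    """TD-decile cut points by linear interpolation between order statistics.

    With ``literal_tenth`` the 10th percentile is used for every measure
    regardless of deficit direction (for effects that tail holds the *best*
    performers); the default places the cut in each measure's worst decile.
    """
    if measures is None:
        measures = [m for m in ABOVE_IS_DEFICIT if m in td_measures.columns]
    cuts, directions = {}, {}
    for m in measures:
        vals = td_measures[m].dropna().to_numpy(dtype=float)
        if len(vals) < 10:
            raise ValueError(f"need >= 10 TD subjects for measure {m!r}, got {len(vals)}")
        above = ABOVE_IS_DEFICIT.get(m, True)
        q = DECILE if (literal_tenth or not above) else 1.0 - DECILE
        cuts[m] = float(np.quantile(vals, q))  # linear interpolation
        directions[m] = "above" if above else "below"
    return DeficitCutpoints(cuts=cuts, directions=directions, n_reference=len(td_measures))


def flag_deficits(measures: pd.DataFrame, cutpoints: DeficitCutpoints) -> pd.DataFrame:
    """Boolean deficit flags per subject; strictly beyond the cut flags a
    deficit, at-cut does not; missing measures give missing flags."""
    out = {}
    if "subject_id" in measures.columns:
        out["subject_id"] = measures["subject_id"]
    for m, cut in cutpoints.cuts.items():
        vals = measures[m].astype(float)
        if cutpoints.directions[m] == "above":
            flags = vals > cut
        else:
            flags = vals < cut
        out[m] = flags.where(vals.notna())
    return pd.DataFrame(out, index=measures.index)


@dataclass(frozen=True)
class FrequencyComparison:
    table: np.ndarray  # 2x2 [flagged, not] x [group A, group B]
    chi2: float
    df: int
    p: float
    frequency_a: float
    frequency_b: float
    note: str = ""


def deficit_frequency_test(flags_a, flags_b) -> FrequencyComparison:
    """Compare deficit frequency between two groups (chi-square, 2x2)."""
    a = pd.Series(flags_a).dropna().astype(bool).to_numpy()
    b = pd.Series(flags_b).dropna().astype(bool).to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one non-missing flag")
    table = np.array([[a.sum(), len(a) - a.sum()],
                      [b.sum(), len(b) - b.sum()]], dtype=int)
    res: ChisqResult = chisq_independence(table)
    return FrequencyComparison(table=table, chi2=res.chi2, df=res.df, p=res.p,
                               frequency_a=float(a.mean()), frequency_b=float(b.mean()),
                               note=res.note)
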