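"""Trial schedules and response simulation for the ANT-I and the MFT-M.

The Attention Network Test - Interaction (ANT-I) crosses alerting signal
(present/absent) x orienting cue (valid/invalid/none) x flanker congruency
(congruent/incongruent/neutral): 18 conditions, 4 trials each per block, two
blocks of 72 trials.  Responses fall in a 1,700 ms window after target
onset.

The backward-masked Majority Function Task (MFT-M) crosses exposure time
(0.25/0.5/1 s) x set size (1/3/5), one combination per block, nine blocks of
36 trials with set-ratio counts 36 (1:0), 18 (3:0, 2:1), and 12 (5:0, 4:1,
3:2); 324 trials in total, with a 2,500 ms response window.

Reaction times are ex-Gaussian; condition means are the subject's base RT
plus additive deltas (no alerting signal, invalid cue, incongruent
flankers).  Majority-task correctness follows the capacity model in
:mod:`cogcap.capacity`.  Timing internals (fixation jitter, SOAs, masks,
feedback) do not affect the simulated measures and are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from cogcap.capacity import group_search_information, predict_accuracy
from cogcap.cohort import SubjectProfile

ANT_RESPONSE_WINDOW_MS = 1700.0
MFT_RESPONSE_WINDOW_MS = 2500.0

ALERTING_LEVELS = ("present", "absent")
ORIENTING_LEVELS = ("valid", "invalid", "none")
CONGRUENCY_LEVELS = ("congruent", "incongruent", "neutral")
ANT_TRIALS_PER_CELL = 4
ANT_BLOCKS = 2

MFT_EXPOSURES = (0.25, 0.5, 1.0)
MFT_SET_SIZES = (1, 3, 5)
MFT_BLOCK_TRIALS = 36
#: per-block trial counts by majority:minority ratio within each set size
MFT_RATIO_COUNTS = {
    1: {(1, 0): 36},
    3: {(3, 0): 18, (2, 1): 18},
    5: {(5, 0): 12, (4, 1): 12, (3, 2): 12},
}

DEFAULT_SEED = 20220311


@dataclass(frozen=True)
class AntTrial:
    subject_id: str
    block: int
    alerting: str
    orienting: str
    congruency: str
    responded: bool
    rt_ms: float | None
    correct: bool


@dataclass(frozen=True)
class MftTrial:
    subject_id: str
    block: int
    set_size: int
    majority_n: int
    minority_n: int
    exposure_s: float
    responded: bool
    rt_ms: float | None
    correct: bool


def make_ant_schedule(seed: int = DEFAULT_SEED) -> list[tuple[int, str, str, str]]:
    """Two blocks of 72 trials: every alerting x orienting x congruency cell
    four times per block, order randomized within block."""
    rng = np.random.default_rng(seed)
    cells = list(product(ALERTING_LEVELS, ORIENTING_LEVELS, CONGRUENCY_LEVELS))
    schedule = []
    for block in range(1, ANT_BLOCKS + 1):
        trials = cells * ANT_TRIALS_PER_CELL
        order = rng.permutation(len(trials))
        schedule.extend((block, *trials[i]) for i in order)
    return schedule


def make_mft_schedule(seed: int = DEFAULT_SEED) -> list[tuple[int, int, tuple[int, int], float]]:
    """Nine 36-trial blocks, one per exposure x set-size combination, with
    the fixed ratio proportions; block order and within-block order are
    randomized."""
    rng = np.random.default_rng(seed)
    combos = list(product(MFT_EXPOSURES, MFT_SET_SIZES))
    rng.shuffle(combos)
    schedule = []
    for block, (exposure, set_size) in enumerate(combos, start=1):
        trials: list[tuple[int, int]] = []
        for ratio, count in MFT_RATIO_COUNTS[set_size].items():
            trials.extend([ratio] * count)
        order = rng.permutation(len(trials))
        schedule.extend((block, set_size, trials[i], exposure) for i in order)
    return schedule


def _ex_gaussian(mu: float, sigma: float, tau: float, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    rt = rng.normal(mu, sigma, size) if sigma > 0 else np.full(size, mu)
    if tau > 0:
        rt = rt + rng.exponential(tau, size)
    return rt


def simulate_ant(profile: SubjectProfile, schedule: list | None = None,
                 seed: int = DEFAULT_SEED) -> list[AntTrial]:
    """Simulate ANT-I responses for one subject.

    Condition mean RT = base + alerting delta (no signal) + orienting delta
    (invalid cue) + conflict delta (incongruent flankers); neutral flankers
    and absent cues sit at the base.  Error probability rises for
    incongruent trials.  Lapses and RTs beyond the response window become
    no-response trials (marked incorrect).
    """
    if schedule is None:
        schedule = make_ant_schedule(seed)
    for entry in schedule:
        if len(entry) != 4:
            raise ValueError("schedule entries must be (block, alerting, orienting, congruency)")
    rng = np.random.default_rng(seed)
    n = len(schedule)
    blocks = np.array([e[0] for e in schedule])
    alert = np.array([e[1] for e in schedule])
    orient = np.array([e[2] for e in schedule])
    cong = np.array([e[3] for e in schedule])

    mu = (profile.latent_rt.mu_ms
          + np.where(alert == "absent", profile.alerting_ms, 0.0)
          + np.where(orient == "invalid", profile.orienting_ms, 0.0)
          + np.where(cong == "incongruent", profile.conflict_ms, 0.0))
    rt = _ex_gaussian(0.0, profile.latent_rt.sigma_ms, profile.latent_rt.tau_ms, n, rng) + mu
    rt = np.maximum(rt, 120.0)  # physiological floor

    p_err = profile.ant_base_error + np.where(
        cong == "incongruent", profile.ant_conflict_error_extra, 0.0)
    correct = rng.random(n) >= p_err
    lapsed = rng.random(n) < profile.lapse_rate
    responded = ~lapsed & (rt <= ANT_RESPONSE_WINDOW_MS)

    return [AntTrial(profile.subject_id, int(blocks[i]), str(alert[i]), str(orient[i]),
                     str(cong[i]), bool(responded[i]),
                     float(rt[i]) if responded[i] else None,
                     bool(correct[i] and responded[i]))
            for i in range(n)]


def simulate_mft(profile: SubjectProfile, schedule: list | None = None,
                 seed: int = DEFAULT_SEED) -> list[MftTrial]:
    """Simulate MFT-M responses: correctness follows the capacity model at
    the subject's true CCC and ceiling; lapses become no-response trials."""
    if schedule is None:
        schedule = make_mft_schedule(seed)
    for entry in schedule:
        if len(entry) != 4 or not isinstance(entry[2], tuple):
            raise ValueError("schedule entries must be (block, set_size, (m, k), exposure_s)")
    rng = np.random.default_rng(seed)
    n = len(schedule)
    info = np.array([group_search_information(*e[2]) for e in schedule])
    exposure = np.array([e[3] for e in schedule])

    p = predict_accuracy(info, exposure, profile.true_ccc, profile.ceiling_acc)
    correct = rng.random(n) < p
    # RT rises with difficulty; analysis uses it only descriptively
    mu = profile.latent_rt.mu_ms + 80.0 * info
    rt = _ex_gaussian(0.0, profile.latent_rt.sigma_ms, profile.latent_rt.tau_ms, n, rng) + mu
    rt = np.maximum(rt, 150.0)
    lapsed = rng.random(n) < profile.lapse_rate
    responded = ~lapsed & (rt <= MFT_RESPONSE_WINDOW_MS)

    return [MftTrial(profile.subject_id, int(schedule[i][0]), int(schedule[i][1]),
                     int(schedule[i][2][0]), int(schedule[i][2][1]),
                     float(schedule[i][3]), bool(responded[i]),
                     float(rt[i]) if responded[i] else None,
                     bool(correct[i] and responded[i]))
            for i in range(n)]


def ant_trials_to_frame(trials: list[AntTrial]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": t.subject_id, "block": t.block,
        "alerting": 1 if t.alerting == "present" else 0,
        "orienting": t.orienting, "congruency": t.congruency,
        "responded": int(t.responded),
        "rt_ms": t.rt_ms if t.rt_ms is not None else np.nan,
        "correct": int(t.correct),
    } for t in trials])


def mft_trials_to_frame(trials: list[MftTrial]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": t.subject_id, "block": t.block, "set_size": t.set_size,
        "majority_n": t.majority_n, "minority_n": t.minority_n,
        "exposure_s": t.exposure_s, "responded": int(t.responded),
        "rt_ms": t.rt_ms if t.rt_ms is not None else np.nan,
        "correct": int(t.correct),
    } for t in trials])
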