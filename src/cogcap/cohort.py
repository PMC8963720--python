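"""Synthetic cohorts and two-informant SNAP-IV / ASQ screening.

The generator emulates the structure of a three-group school-screening
study: children with ADHD, children with subthreshold ADHD, and typically
developing (TD) peers.  Each subject carries

* demographics (sex, age, school),
* parent- and teacher-rated symptom questionnaires (SNAP-IV: 9 inattention,
  9 hyperactivity/impulsivity, 8 opposition/defiance items on a 0-3 scale;
  ASQ total 0-30), and
* latent task parameters (ex-Gaussian reaction-time base, additive
  attention-effect deltas, lapse rate, ceiling accuracy, true cognitive
  control capacity in bits/s) that drive the trial simulators.

Group labels are not assigned by fiat: symptom reports are drawn from
group-conditional distributions and the subject is accepted only when the
two-informant diagnostic rule (`diagnose`) reproduces the intended group,
so labels genuinely arise from the simulated reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("ADHD", "subthreshold", "TD")

N_INATTENTION_ITEMS = 9
N_HYPERACTIVITY_ITEMS = 9
N_OPPOSITION_ITEMS = 8
ASQ_MAX = 30
ASQ_CUTOFF = 10
SYMPTOMATIC_SCORE = 2  # an item counts as a symptom when rated >= 2
ADHD_MIN_ITEMS = 6  # >= 6 symptomatic items in a subscale
SUBTHRESHOLD_MIN_ITEMS = 3  # 3-5 symptomatic items


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian reaction-time parameters (ms); mean = mu + tau."""

    mu_ms: float
    sigma_ms: float
    tau_ms: float


@dataclass(frozen=True)
class InformantReport:
    """One rater's SNAP-IV + ASQ report for a child.

    ``impairment`` stands in for the DSM-IV age-of-onset / two-setting
    impairment condition, which questionnaires alone cannot establish; the
    simulator sets it True for every report.
    """

    rater: str  # "parent" or "teacher"
    inattention_items: tuple[int, ...]
    hyperactivity_items: tuple[int, ...]
    opposition_items: tuple[int, ...]
    asq_total: int
    impairment: bool = True

    def __post_init__(self) -> None:
        if len(self.inattention_items) != N_INATTENTION_ITEMS:
            raise ValueError(f"expected {N_INATTENTION_ITEMS} inattention items, "
                             f"got {len(self.inattention_items)}")
        if len(self.hyperactivity_items) != N_HYPERACTIVITY_ITEMS:
            raise ValueError(f"expected {N_HYPERACTIVITY_ITEMS} hyperactivity items, "
                             f"got {len(self.hyperactivity_items)}")
        for items in (self.inattention_items, self.hyperactivity_items, self.opposition_items):
            if any((s < 0 or s > 3) for s in items):
                raise ValueError("item scores must lie in 0-3 (4-point scale)")
        if not 0 <= self.asq_total <= ASQ_MAX:
            raise ValueError(f"ASQ total must lie in 0-{ASQ_MAX}")

    @property
    def n_inattention(self) -> int:
        """Number of symptomatic (>= 2) inattention items."""
        return sum(s >= SYMPTOMATIC_SCORE for s in self.inattention_items)

    @property
    def n_hyperactivity(self) -> int:
        return sum(s >= SYMPTOMATIC_SCORE for s in self.hyperactivity_items)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    sex: str  # "M" / "F"
    age: float  # years
    school: int
    parent_report: InformantReport
    teacher_report: InformantReport
    latent_rt: ExGaussian
    alerting_ms: float
    orienting_ms: float
    conflict_ms: float
    ant_base_error: float
    ant_conflict_error_extra: float
    lapse_rate: float
    ceiling_acc: float
    true_ccc: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.5 < self.ceiling_acc <= 1.0:
            raise ValueError("ceiling_acc must lie in (0.5, 1]")
        if self.true_ccc <= 0:
            raise ValueError("true_ccc must be positive")
        if not 0.0 <= self.lapse_rate <= 0.2:
            raise ValueError("lapse_rate must lie in [0, 0.2]")

    @property
    def snap_inattention_n(self) -> int:
        return self.parent_report.n_inattention

    @property
    def snap_hyperactivity_n(self) -> int:
        return self.parent_report.n_hyperactivity


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one group.

    RT quantities are in ms (between-subject mean, SD); symptom "counts"
    are the number of items rated >= 2 per subscale, drawn from a
    discretized Gaussian; ccc is the true capacity in bits/s, truncated
    below at ``ccc_floor``.
    """

    congruent_rt: tuple[float, float]
    alerting: tuple[float, float]
    orienting: tuple[float, float]
    conflict: tuple[float, float]
    ccc: tuple[float, float]
    inattention_count: tuple[float, float]
    hyperactivity_count: tuple[float, float]
    asq: tuple[float, float]


#: Group-level defaults.  RT condition means/SDs and CCC distributions follow
#: the study's descriptive statistics; symptom-count distributions are set so
#: the two-informant rule recovers the intended label for the large majority
#: of simulated children.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "ADHD": GroupParams(
        congruent_rt=(662.4, 137.2), alerting=(50.0, 49.4),
        orienting=(35.2, 44.5), conflict=(131.7, 57.4), ccc=(2.73, 0.73),
        inattention_count=(7.0, 1.0), hyperactivity_count=(5.0, 1.6),
        asq=(18.0, 3.0),
    ),
    "subthreshold": GroupParams(
        congruent_rt=(594.4, 113.2), alerting=(37.4, 36.0),
        orienting=(31.8, 39.0), conflict=(136.1, 36.3), ccc=(2.82, 0.71),
        inattention_count=(4.0, 0.7), hyperactivity_count=(2.4, 1.0),
        asq=(15.0, 2.5),
    ),
    "TD": GroupParams(
        congruent_rt=(566.5, 129.5), alerting=(26.2, 19.7),
        orienting=(37.3, 31.8), conflict=(101.4, 33.7), ccc=(3.26, 0.61),
        inattention_count=(0.2, 0.4), hyperactivity_count=(0.1, 0.4),
        asq=(3.0, 2.5),
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"ADHD": 39, "subthreshold": 34, "TD": 36})
    male_proportion: dict[str, float] = field(
        default_factory=lambda: {"ADHD": 29 / 39, "subthreshold": 24 / 34, "TD": 17 / 36})
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ADHD": (10.6, 1.9), "subthreshold": (11.0, 1.9),
                                 "TD": (11.6, 1.5)})
    n_schools: int = 12
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    #: within-subject ex-Gaussian spread (ms), shared across groups
    rt_sigma_ms: float = 60.0
    rt_tau_ms: float = 120.0
    lapse_mean_sd: tuple[float, float] = (0.02, 0.01)
    ceiling_mean_sd: tuple[float, float] = (0.985, 0.008)
    ant_base_error: float = 0.015
    ant_conflict_error_extra: float = 0.065
    ccc_floor: float = 0.3
    #: per-item probability that the teacher's rating deviates (+-1) from the
    #: parent's — imperfect informant agreement
    teacher_item_noise: float = 0.05
    #: require ASQ >= 10 of "both" raters or "either" for the subthreshold rule
    asq_requirement: str = "both"
    seed: int = 20220311

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.n_per_group:
                raise ConfigError(f"n_per_group missing group {g!r}")
            if self.n_per_group[g] <= 0:
                raise ConfigError(f"n_per_group[{g!r}] must be > 0")
            p = self.male_proportion[g]
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"male_proportion[{g!r}] must lie in [0, 1]")
            gp = self.group_params[g]
            for name in ("congruent_rt", "alerting", "orienting", "conflict", "ccc",
                         "inattention_count", "hyperactivity_count", "asq"):
                mean, sd = getattr(gp, name)
                if sd < 0:
                    raise ConfigError(f"group_params[{g!r}].{name} SD must be >= 0")
            if gp.ccc[0] <= 0:
                raise ConfigError(f"group_params[{g!r}].ccc mean must be > 0")
        if self.n_schools <= 0:
            raise ConfigError("n_schools must be > 0")
        if self.asq_requirement not in ("both", "either"):
            raise ConfigError("asq_requirement must be 'both' or 'either'")


def _rater_meets(report: InformantReport) -> tuple[bool, bool, bool]:
    """(meets ADHD symptom criterion, meets subthreshold-or-stronger, ASQ >= cutoff)."""
    adhd = (report.n_inattention >= ADHD_MIN_ITEMS
            or report.n_hyperactivity >= ADHD_MIN_ITEMS) and report.impairment
    # 3-5 symptomatic items in either subscale, or the full criterion: i.e.
    # at least 3 in either subscale.  Expressed this way the rule is monotone
    # in the item scores.
    sub_or_stronger = (report.n_inattention >= SUBTHRESHOLD_MIN_ITEMS
                       or report.n_hyperactivity >= SUBTHRESHOLD_MIN_ITEMS)
    return adhd, sub_or_stronger, report.asq_total >= ASQ_CUTOFF


def diagnose(parent: InformantReport, teacher: InformantReport,
             asq_requirement: str = "both") -> str:
    """Assign ADHD / subthreshold / TD from two informant reports.

    A child is labelled ADHD only when *both* raters report at least six
    symptomatic (>= 2) items on the inattention and/or the
    hyperactivity/impulsivity subscale and an ASQ total of at least 10.
    Subthreshold requires both raters to report at least the 3-5-item level
    (with the ASQ cutoff, of both raters by default) without both meeting
    the full criterion.  Anything weaker is TD.
    """
    if asq_requirement not in ("both", "either"):
        raise ValueError("asq_requirement must be 'both' or 'either'")
    p_adhd, p_sub, p_asq = _rater_meets(parent)
    t_adhd, t_sub, t_asq = _rater_meets(teacher)
    both_asq = p_asq and t_asq
    either_asq = p_asq or t_asq
    if p_adhd and t_adhd and both_asq:
        return "ADHD"
    sub_asq = both_asq if asq_requirement == "both" else either_asq
    if p_sub and t_sub and sub_asq:
        return "subthreshold"
    return "TD"


def _items_from_count(count: int, n_items: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Expand a symptomatic-item count into item scores on the 0-3 scale."""
    scores = np.where(rng.random(n_items) < 0.3, 1, 0)
    hot = rng.choice(n_items, size=count, replace=False)
    scores[hot] = np.where(rng.random(count) < 0.5, 2, 3)
    return tuple(int(s) for s in scores)


def _draw_count(mean_sd: tuple[float, float], n_items: int,
                rng: np.random.Generator) -> int:
    mean, sd = mean_sd
    return int(np.clip(round(rng.normal(mean, sd)), 0, n_items))


def _perturb_items(items: tuple[int, ...], rate: float,
                   rng: np.random.Generator) -> tuple[int, ...]:
    out = np.asarray(items, dtype=int)
    flip = rng.random(out.size) < rate
    step = rng.choice([-1, 1], size=out.size)
    out = np.clip(out + flip * step, 0, 3)
    return tuple(int(s) for s in out)


def simulate_reports(params: GroupParams, rng: np.random.Generator,
                     teacher_item_noise: float = 0.05,
                     ) -> tuple[InformantReport, InformantReport]:
    """Draw a parent report from the group-conditional symptom distribution
    and a teacher report as a noisy copy of it."""
    inatt = _items_from_count(
        _draw_count(params.inattention_count, N_INATTENTION_ITEMS, rng),
        N_INATTENTION_ITEMS, rng)
    hyper = _items_from_count(
        _draw_count(params.hyperactivity_count, N_HYPERACTIVITY_ITEMS, rng),
        N_HYPERACTIVITY_ITEMS, rng)
    # opposition/defiance is carried along but plays no role in diagnosis
    opp = _items_from_count(
        _draw_count((params.hyperactivity_count[0] * 0.6, 1.0), N_OPPOSITION_ITEMS, rng),
        N_OPPOSITION_ITEMS, rng)
    asq = int(np.clip(round(rng.normal(*params.asq)), 0, ASQ_MAX))
    parent = InformantReport("parent", inatt, hyper, opp, asq)
    teacher = InformantReport(
        "teacher",
        _perturb_items(inatt, teacher_item_noise, rng),
        _perturb_items(hyper, teacher_item_noise, rng),
        _perturb_items(opp, teacher_item_noise, rng),
        int(np.clip(asq + round(rng.normal(0, 1.5)), 0, ASQ_MAX)),
    )
    return parent, teacher


def _truncated_normal(mean: float, sd: float, low: float,
                      rng: np.random.Generator, high: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise RuntimeError("truncated normal draw failed; check mean/SD vs bounds")


def _make_subject(subject_id: str, group: str, sex: str, config: CohortConfig,
                  rng: np.random.Generator) -> SubjectProfile:
    gp = config.group_params[group]
    age_mean, age_sd = config.age_mean_sd[group]
    age = float(np.clip(rng.normal(age_mean, age_sd), 6.0, 13.0))
    school = int(rng.integers(config.n_schools))

    # reports must actually pass the diagnostic rule for the intended group
    for _ in range(1000):
        parent, teacher = simulate_reports(gp, rng, config.teacher_item_noise)
        if diagnose(parent, teacher, config.asq_requirement) == group:
            break
    else:
        raise RuntimeError(
            f"could not draw reports consistent with group {group!r}; "
            "symptom-count parameters are too far from the diagnostic bands")

    alerting = float(rng.normal(*gp.alerting))
    orienting = float(rng.normal(*gp.orienting))
    conflict = float(rng.normal(*gp.conflict))
    congruent_mean = _truncated_normal(*gp.congruent_rt, low=250.0, rng=rng)
    # congruent trials average over alerting (1/2 no-signal) and orienting
    # (1/3 invalid) levels; back out the all-benefits base so that the
    # subject's expected congruent mean equals the drawn target
    base_mean = congruent_mean - alerting / 2.0 - orienting / 3.0
    mu = max(base_mean - config.rt_tau_ms, 150.0)
    lapse = float(np.clip(rng.normal(*config.lapse_mean_sd), 0.0, 0.2))
    ceiling = float(np.clip(rng.normal(*config.ceiling_mean_sd), 0.51, 0.999))
    ccc = _truncated_normal(*gp.ccc, low=config.ccc_floor, rng=rng)
    return SubjectProfile(
        subject_id=subject_id, group=group, sex=sex, age=age, school=school,
        parent_report=parent, teacher_report=teacher,
        latent_rt=ExGaussian(mu, config.rt_sigma_ms, config.rt_tau_ms),
        alerting_ms=alerting, orienting_ms=orienting, conflict_ms=conflict,
        ant_base_error=config.ant_base_error,
        ant_conflict_error_extra=config.ant_conflict_error_extra,
        lapse_rate=lapse, ceiling_acc=ceiling, true_ccc=ccc,
    )


def generate_cohort(config: CohortConfig | None = None) -> list[SubjectProfile]:
    """Generate a full synthetic cohort, deterministically for a given seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectProfile] = []
    idx = 1
    for group in GROUPS:
        n = config.n_per_group[group]
        n_male = int(round(n * config.male_proportion[group]))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        for sex in sexes:
            subjects.append(_make_subject(f"S{idx:03d}", group, str(sex), config, rng))
            idx += 1
    return subjects


def subjects_to_frame(subjects: list[SubjectProfile],
                      include_latent: bool = True) -> pd.DataFrame:
    """Tabulate a cohort; latent generative columns are optional."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id, "group": s.group, "sex": s.sex,
            "age": round(s.age, 2), "school": s.school,
            "snap_inatt_n": s.snap_inattention_n,
            "snap_hyper_n": s.snap_hyperactivity_n,
            "asq_parent": s.parent_report.asq_total,
            "asq_teacher": s.teacher_report.asq_total,
        }
        if include_latent:
            row.update({
                "true_ccc": s.true_ccc, "ceiling_acc": s.ceiling_acc,
                "lapse_rate": s.lapse_rate, "rt_mu_ms": s.latent_rt.mu_ms,
                "alerting_ms": s.alerting_ms, "orienting_ms": s.orienting_ms,
                "conflict_ms": s.conflict_ms,
            })
        rows.append(row)
    return pd.DataFrame(rows)
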