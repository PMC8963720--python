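"""End-to-end pipeline: simulate -> score -> estimate -> infer -> classify.

Every stage is deterministic given the global seed; per-stage sub-seeds are
derived from it with ``numpy.random.SeedSequence.spawn`` so stages can be
re-run independently.  Artifacts are plain CSV/JSON files plus a
human-readable text report of group descriptives, deficit frequencies, and
classification accuracies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cogcap import ant, capacity, classify, cohort, deficits, inference, io, trials

log = logging.getLogger("cogcap")

GROUP_PAIRS = (("ADHD", "TD"), ("subthreshold", "TD"), ("ADHD", "subthreshold"))
MEASURES = ("alerting_rt", "orienting_rt", "conflict_rt", "ccc_bps")


@dataclass
class PipelineConfig:
    out_dir: str = "cogcap_run"
    seed: int = 20220311
    n_per_group: dict = field(
        default_factory=lambda: {"ADHD": 39, "subthreshold": 34, "TD": 36})
    n_repeats: int = 1000
    deficit_literal_tenth: bool = False
    cv_mode: str = "subsample"  # or "kfold"
    include_latent_columns: bool = True
    feature_sets: tuple = ("attention", "ccc", "combined")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        raw["feature_sets"] = tuple(raw.get("feature_sets", cls.feature_sets))
        return cls(**raw)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def simulate_stage(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the cohort and both trial tables."""
    cohort_seed, ant_seed, mft_seed = _spawn_seeds(config.seed, 3)
    cc = cohort.CohortConfig(n_per_group=dict(config.n_per_group), seed=cohort_seed)
    subjects = cohort.generate_cohort(cc)
    subj_df = cohort.subjects_to_frame(subjects, include_latent=config.include_latent_columns)

    ant_rows, mft_rows = [], []
    for i, prof in enumerate(subjects):
        ant_rows.append(trials.ant_trials_to_frame(
            trials.simulate_ant(prof, seed=ant_seed + i)))
        mft_rows.append(trials.mft_trials_to_frame(
            trials.simulate_mft(prof, seed=mft_seed + i)))
    ant_df = pd.concat(ant_rows, ignore_index=True)
    mft_df = pd.concat(mft_rows, ignore_index=True)
    log.info("simulated %d subjects, %d ANT-I trials, %d MFT-M trials",
             len(subjects), len(ant_df), len(mft_df))
    return subj_df, ant_df, mft_df


def analysis_stage(subj_df: pd.DataFrame, ant_df: pd.DataFrame, mft_df: pd.DataFrame,
                   config: PipelineConfig) -> dict:
    """Score, estimate, flag deficits, test, and classify; returns a bundle
    of tables and JSON-serializable records."""
    effects = ant.score_cohort(ant_df)
    cap = capacity.estimate_cohort(mft_df)
    merged = (effects.merge(cap[["subject_id", "ccc_bps"]], on="subject_id")
              .merge(subj_df[["subject_id", "group", "sex", "age", "school"]],
                     on="subject_id"))

    # group descriptives (analogue of a per-group mean +- SD table)
    descriptives = merged.groupby("group")[
        ["alerting_rt", "orienting_rt", "conflict_rt", "overall_rt", "ccc_bps"]
    ].agg(["mean", "std"])

    # deficit flags against TD deciles
    td = merged[merged["group"] == "TD"]
    cuts = deficits.compute_cutpoints(td, measures=list(MEASURES),
                                      literal_tenth=config.deficit_literal_tenth)
    flags = deficits.flag_deficits(merged, cuts)
    flags["group"] = merged["group"].to_numpy()
    freq_tests = {}
    for m in MEASURES:
        fa = flags.loc[flags["group"] == "ADHD", m]
        fb = flags.loc[flags["group"] == "subthreshold", m]
        res = deficits.deficit_frequency_test(fa, fb)
        freq_tests[m] = {"chi2": res.chi2, "df": res.df, "p": res.p,
                         "f_ADHD": res.frequency_a, "f_subthreshold": res.frequency_b,
                         "table": res.table.tolist()}

    # covariate-adjusted group comparisons
    covs = merged[["sex", "age", "school"]]
    anova_records = {}
    for m in ("alerting_rt", "orienting_rt", "conflict_rt", "overall_rt", "ccc_bps"):
        res = inference.ancova(merged[m], merged["group"], covs)
        anova_records[m] = {
            "F": res.F, "df": [res.df_num, res.df_den], "p": res.p,
            "eta_sq": res.eta_sq, "adjusted_means": res.adjusted_group_means,
            "posthoc": [{"pair": [c.group_a, c.group_b], "diff": c.difference,
                         "t": c.t, "p_bonferroni": c.p_bonferroni}
                        for c in res.posthoc]}

    # SVM classifications
    cls_seeds = _spawn_seeds(config.seed + 1, len(GROUP_PAIRS) * len(config.feature_sets))
    classification = {}
    si = 0
    for pos, neg in GROUP_PAIRS:
        pair_sub = subj_df[subj_df["group"].isin([pos, neg])]
        for fset in config.feature_sets:
            fm = classify.build_features(effects, cap, pair_sub, feature_set=fset)
            res = classify.repeated_cv(fm, n_repeats=config.n_repeats,
                                       seed=cls_seeds[si], mode=config.cv_mode)
            si += 1
            n_pos = int((fm.labels == pos).sum())
            n_neg = int((fm.labels == neg).sum())
            classification[f"{pos}_vs_{neg}:{fset}"] = {
                "mean_accuracy": res.mean_accuracy, "sd_accuracy": res.sd_accuracy,
                "chance": classify.chance_level(n_pos, n_neg),
                "baseline_mean": float(res.baseline_accuracies.mean()),
                "t": res.t_stat, "p": res.p_value}

    return {"effects": effects, "capacity": cap, "merged": merged,
            "descriptives": descriptives, "cutpoints": cuts,
            "flags": flags, "frequency_tests": freq_tests,
            "anova": anova_records, "classification": classification}


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run all stages and write every artifact under ``config.out_dir``."""
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subj_df, ant_df, mft_df = simulate_stage(config)
    bundle = analysis_stage(subj_df, ant_df, mft_df, config)

    io.write_trials(ant_df, out / "ant_trials.csv", "ant")
    io.write_trials(mft_df, out / "mft_trials.csv", "mft")
    subj_df.to_csv(out / "subjects.csv", index=False)
    bundle["effects"].to_csv(out / "attention_effects.csv", index=False)
    bundle["capacity"].to_csv(out / "capacity.csv", index=False)
    bundle["flags"].to_csv(out / "deficit_flags.csv", index=False)
    (out / "config.json").write_text(config.to_json())

    summary = {
        "cutpoints": bundle["cutpoints"].cuts,
        "frequency_tests": bundle["frequency_tests"],
        "anova": bundle["anova"],
        "classification": bundle["classification"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "report.txt").write_text(render_report(bundle))
    log.info("pipeline artifacts written to %s", out)
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable run report."""
    lines = ["Cohort analysis report", "=" * 40, "", "Group descriptives (mean +- SD):"]
    desc = bundle["descriptives"]
    for measure in ("alerting_rt", "orienting_rt", "conflict_rt", "overall_rt", "ccc_bps"):
        lines.append(f"  {measure}:")
        for grp in desc.index:
            mean = desc.loc[grp, (measure, "mean")]
            sd = desc.loc[grp, (measure, "std")]
            lines.append(f"    {grp:>12}: {mean:8.2f} +- {sd:6.2f}")
    lines += ["", "Deficit frequencies (ADHD vs subthreshold):"]
    for m, rec in bundle["frequency_tests"].items():
        lines.append(f"  {m}: f={rec['f_ADHD']:.1%} vs {rec['f_subthreshold']:.1%}, "
                     f"chi2={rec['chi2']:.2f}, p={rec['p']:.3f}")
    lines += ["", "Group ANOVAs (sex, age, school adjusted):"]
    for m, rec in bundle["anova"].items():
        lines.append(f"  {m}: F({rec['df'][0]},{rec['df'][1]})={rec['F']:.2f}, "
                     f"p={rec['p']:.4f}, eta2={rec['eta_sq']:.3f}")
    lines += ["", "SVM classification (mean accuracy vs chance):"]
    for key, rec in bundle["classification"].items():
        lines.append(f"  {key}: {rec['mean_accuracy']:.1%} "
                     f"(chance {rec['chance']:.1%}, p={rec['p']:.2g})")
    return "\n".join(lines) + "\n"
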