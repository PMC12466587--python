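"""End-to-end runs: generate or load data, preprocess, profile, test, report.

A :class:`RunConfig` (YAML round-trippable) drives the full chain:

    dataset (on disk or simulated) -> eye selection & filtering ->
    choice assignment -> entropy profiles -> segment / event / rate /
    piecewise statistics -> tidy CSV tables + JSON manifest.

Runs are idempotent for a fixed config and seed: every random draw is
seeded from the config, and the manifest records the resolved
configuration so each statistic is traceable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (
    GeneratorConfig,
    SyntheticDataset,
    TrialSpec,
    generate_dataset,
    load_dataset,
    simulate_dataset,
)
from .preprocess import ChoiceSeries, ScreenSpec, assign_choices, filter_gaze, select_eye
from .entropy import UncertaintyProfile, build_profile
from . import stats as sgstats
from .embedding import (
    SyntheticEmbeddingProvider,
    build_sense_reference,
    compare_to_human,
    incremental_series,
)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "preprocess_dataset",
    "build_profiles",
    "run_pipeline",
    "validate_dataset",
]


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    dataset_root: str | None = None     # load if set, else simulate
    output_dir: str | None = None
    bin_width: float = 0.1
    segment_mode: str = "word_aligned"  # or "all_bins"
    window: float = 1.0                 # event-locked window, seconds
    n_permutations: int = 10_000
    n_boot: int = 10_000
    seed: int = 0
    n_segments: int = 3
    piecewise_stride: int = 1
    rate_denominator: str = "characters"
    model_uncertainty: bool = False
    provider: str = "synthetic"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            g = dict(self.generator)
            for key in ("bias_levels", "sentence_duration", "word_onset_fraction"):
                if key in g:
                    g[key] = tuple(g[key])
            self.generator = GeneratorConfig(**g)
        for name in ("n_permutations", "n_boot", "n_segments", "piecewise_stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bin_width not in (0.1, 0.5):
            # other widths work computationally; the two named analysis
            # resolutions are enforced here to keep runs comparable
            raise ValueError("bin_width must be 0.1 or 0.5")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class ReportBundle:
    """All tables and group statistics produced by one run."""

    segment_summaries: pd.DataFrame
    rates: pd.DataFrame
    turning_points: pd.DataFrame
    rm_anova: sgstats.RmAnovaResult
    event_test: sgstats.EventTestResult
    permutation: sgstats.PermutationResult
    bias_rates: sgstats.BiasRateResult
    second_diffs: sgstats.SecondDiffResult
    turning_anovas: pd.DataFrame
    mixed_anova: sgstats.MixedAnovaResult
    assignment_rate: float
    model_comparison: dict | None
    manifest: dict


def preprocess_dataset(
    dataset: SyntheticDataset, screen: ScreenSpec = ScreenSpec()
) -> tuple[dict[str, list[ChoiceSeries]], float]:
    """Clean every gaze stream and assign choices.

    Returns per-trial lists of ChoiceSeries and the overall assignment
    rate (assigned / retained samples, pooled over streams).
    """
    choices: dict[str, list[ChoiceSeries]] = {t.trial_id: [] for t in dataset.trials}
    n_assigned = 0
    n_retained = 0
    for trial in dataset.trials:
        for pi in dataset.participants:
            rec = dataset.recordings[(trial.trial_id, pi)]
            stream = select_eye(rec.samples, None)
            retained, _ = filter_gaze(stream, screen)
            series, _ = assign_choices(retained, trial.layout)
            choices[trial.trial_id].append(series)
            n_retained += len(series.times)
            n_assigned += int(np.sum(series.choice >= 0))
    rate = n_assigned / n_retained if n_retained else float("nan")
    return choices, rate


def build_profiles(
    dataset: SyntheticDataset,
    choices: Mapping[str, list[ChoiceSeries]],
    bin_width: float = 0.1,
) -> dict[str, UncertaintyProfile]:
    return {
        t.trial_id: build_profile(t, choices[t.trial_id], bin_width)
        for t in dataset.trials
    }


def _turning_point_table(
    profiles: Mapping[str, UncertaintyProfile],
    trials: list[TrialSpec],
    n_segments: int,
    stride: int,
) -> pd.DataFrame:
    rows = []
    for t in trials:
        fit = sgstats.piecewise_fit(
            profiles[t.trial_id], n_segments=n_segments, candidate_stride=stride
        )
        rows.append(
            {
                "trial_id": t.trial_id,
                "bias_level": t.bias_level,
                "turning_point": fit.turning_point,
                "fastest_slope": fit.fastest_slope,
                "sse": fit.sse,
                "no_decline": fit.no_decline,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every analysis stage and (optionally) write the report."""
    if config.dataset_root is not None:
        dataset = load_dataset(config.dataset_root)
    else:
        dataset = simulate_dataset(config.generator)

    choices, assignment_rate = preprocess_dataset(dataset)
    profiles = build_profiles(dataset, choices, config.bin_width)
    trials = dataset.trials
    by_id = {t.trial_id: t for t in trials}

    summaries = [
        sgstats.segment_means(profiles[t.trial_id], t, config.segment_mode)
        for t in trials
    ]
    sum_df = sgstats.summaries_frame(summaries)
    rm = sgstats.rm_anova_segments(sum_df)
    profile_list = [profiles[t.trial_id] for t in trials]
    event = sgstats.event_locked_test(profile_list, config.window)
    perm = sgstats.permutation_null(
        profile_list, n_iter=config.n_permutations, window=config.window, seed=config.seed
    )
    rates = sgstats.rates_frame(summaries, config.rate_denominator)
    bias = sgstats.bias_rate_analysis(rates)
    dm = sgstats.second_differences(rates, n_boot=config.n_boot, seed=config.seed)
    tp = _turning_point_table(profiles, trials, config.n_segments, config.piecewise_stride)
    tp_anovas = _turning_anovas(tp)
    mixed = sgstats.mixed_anova_segment_by_bias(sum_df)

    model_cmp = None
    if config.model_uncertainty:
        model_cmp = _model_comparison(trials, profiles, config)

    manifest = {
        "semgaze_version": __version__,
        "config": _manifest_config(config),
        "n_trials": len(trials),
        "n_participants": dataset.config.n_participants,
        "assignment_rate": assignment_rate,
    }
    bundle = ReportBundle(
        segment_summaries=sum_df,
        rates=rates,
        turning_points=tp,
        rm_anova=rm,
        event_test=event,
        permutation=perm,
        bias_rates=bias,
        second_diffs=dm,
        turning_anovas=tp_anovas,
        mixed_anova=mixed,
        assignment_rate=assignment_rate,
        model_comparison=model_cmp,
        manifest=manifest,
    )
    if config.output_dir is not None:
        write_report(bundle, config)
    return bundle


def _turning_anovas(tp: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for dv in ("turning_point", "fastest_slope"):
        res = sgstats.bias_rate_analysis(tp.rename(columns={dv: "rate"}), dv="rate")
        rows.append(
            {
                "dv": dv,
                "F": res.anova.F,
                "df1": res.anova.df1,
                "df2": res.anova.df2,
                "p": res.anova.p,
                "eta_sq": res.anova.eta_sq,
            }
        )
    return pd.DataFrame(rows)


def _model_comparison(trials, profiles, config: RunConfig) -> dict:
    if config.provider != "synthetic":
        raise ValueError(
            "only the synthetic provider is wired into run_pipeline; use "
            "semgaze.adapters.bert with the embedding API directly for a real model"
        )
    sense_of = {t.sentence: t.bias_level for t in trials}
    provider = SyntheticEmbeddingProvider(
        seed=config.seed, sense_of=sense_of, context_noise_sd=0.05
    )
    refs = build_sense_reference(
        [("#A", (0, 1))], [("#B", (0, 1))], provider
    )
    series = {}
    for t in trials:
        span = (0, len(t.words[0]))
        series[t.trial_id] = incremental_series(t.sentence, span, refs, provider)
    by_id = {t.trial_id: t for t in trials}
    out = {}
    for mode in ("per_trial_mean", "resampled_concat"):
        res = compare_to_human(series, profiles, by_id, mode=mode)
        out[mode] = {"r": res.r, "df": res.df, "p": res.p, "n": res.n}
    return out


def _manifest_config(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def write_report(bundle: ReportBundle, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.segment_summaries.to_csv(out / "segment_summaries.csv", index=False)
    bundle.rates.to_csv(out / "rates.csv", index=False)
    bundle.turning_points.to_csv(out / "turning_points.csv", index=False)
    bundle.bias_rates.tukey.to_csv(out / "tukey.csv", index=False)
    bundle.rm_anova.pairwise.to_csv(out / "segment_pairwise.csv", index=False)
    group = {
        "rm_anova": asdict(bundle.rm_anova.anova),
        "event_test": asdict(bundle.event_test),
        "permutation": {
            "observed_t": bundle.permutation.observed_t,
            "p_one_sided": bundle.permutation.p_one_sided,
            "n_iter": len(bundle.permutation.null_t),
            "seed": bundle.permutation.seed,
        },
        "bias_anova": asdict(bundle.bias_rates.anova),
        "second_differences": {
            "dm1": bundle.second_diffs.dm1,
            "dm2": bundle.second_diffs.dm2,
            "ci1": list(bundle.second_diffs.ci1),
            "ci2": list(bundle.second_diffs.ci2),
            "p1": bundle.second_diffs.p1,
            "p2": bundle.second_diffs.p2,
        },
        "turning_anovas": bundle.turning_anovas.to_dict("records"),
        "mixed_anova": bundle.mixed_anova.table.to_dict("records"),
        "mixed_simple_effects": bundle.mixed_anova.simple_effects.to_dict("records"),
        "assignment_rate": bundle.assignment_rate,
        "model_comparison": bundle.model_comparison,
    }
    with open(out / "group_stats.json", "w") as fh:
        json.dump(group, fh, indent=1, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, default=float)
    config.to_yaml(out / "resolved_config.yaml")


# ---------------------------------------------------------------------------
# dataset validation


def validate_dataset(root) -> list[str]:
    """Schema and invariant checks of an on-disk dataset.

    Returns a list of human-readable violations (empty = valid).
    """
    root = Path(root)
    problems: list[str] = []
    for name in ("manifest.json", "trials.json", "words.tsv"):
        if not (root / name).exists():
            problems.append(f"missing {name}")
    if problems:
        return problems
    try:
        with open(root / "manifest.json") as fh:
            manifest = json.load(fh)
        n_participants = int(manifest["n_participants"])
    except Exception as exc:
        return [f"unreadable manifest: {exc}"]
    try:
        with open(root / "trials.json") as fh:
            trial_records = json.load(fh)
    except Exception as exc:
        return [f"unreadable trials.json: {exc}"]

    from .synthetic import _trial_from_record

    trials = []
    seen = set()
    for rec in trial_records:
        tid = rec.get("trial_id", "?")
        if tid in seen:
            problems.append(f"duplicate trial id {tid}")
        seen.add(tid)
        try:
            trials.append(_trial_from_record(rec))
        except Exception as exc:
            problems.append(f"trial {tid}: invalid spec ({exc})")

    words = pd.read_csv(root / "words.tsv", sep="\t")
    need = {"trial_id", "word_index", "word", "onset_s"}
    if not need.issubset(words.columns):
        problems.append(f"words.tsv missing columns {sorted(need - set(words.columns))}")
    else:
        durations = {t.trial_id: t.duration for t in trials}
        for tid, grp in words.groupby("trial_id"):
            ons = grp.sort_values("word_index")["onset_s"].to_numpy()
            if np.any(np.diff(ons) <= 0):
                problems.append(f"words.tsv: onsets not strictly increasing in {tid}")
            if tid in durations and (ons.min() < 0 or ons.max() >= durations[tid]):
                problems.append(f"words.tsv: onset outside [0, D) in {tid}")

    gaze_cols = {"time_s", "x_deg", "y_deg", "eye", "valid"}
    for t in trials:
        for pi in range(n_participants):
            path = root / "gaze" / f"{t.trial_id}_p{pi:02d}.csv"
            if not path.exists():
                problems.append(f"missing gaze file {path.name}")
                continue
            if pi == 0:
                df = pd.read_csv(path)
                if not gaze_cols.issubset(df.columns):
                    problems.append(f"{path.name}: missing columns")
                elif np.any(np.diff(df["time_s"].to_numpy()) < 0):
                    problems.append(f"{path.name}: times not sorted")
    return problems
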