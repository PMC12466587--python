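"""Inferential layer over uncertainty profiles.

Four families of statistics characterise how group-level semantic
uncertainty evolves:

* **segment comparisons** — per-trial mean entropy in the initial
  ``[0, D/2)``, late ``[D/2, D)`` and post-sentence ``[D, D + tail)``
  segments, compared with a trial-level repeated-measures ANOVA and
  Bonferroni-corrected paired t-tests;
* **event-locked test** — mean entropy in the 1 s windows before vs after
  the ambiguous word's onset, paired t over trials, with a permutation
  null built from the same contrast at random timepoints (10,000 draws)
  to control for the global downward trend;
* **convergence rates** — per-trial uncertainty reduction rate
  ``(initial - post) / sentence length``, a between-trial one-way ANOVA
  over bias levels with Tukey HSD pairwise comparisons, plus bootstrap
  second differences (dM) that test deviation from a linear rate-vs-bias
  relation, and a 3 x 6 mixed ANOVA (segment within-trial, bias level
  between-trial) with per-segment simple effects;
* **piecewise fits** — continuous piecewise-linear regression of each
  profile with breakpoints on the bin grid, locating the period of the
  fastest uncertainty decline ("turning point").

Standard fits go through pingouin / statsmodels / scipy; the resampling
machinery (permutation null, bootstrap dM, breakpoint grid search) is
implemented here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .entropy import UncertaintyProfile, word_aligned_values
from .synthetic import TrialSpec

__all__ = [
    "SegmentSummary",
    "segment_means",
    "summaries_frame",
    "AnovaResult",
    "RmAnovaResult",
    "rm_anova_segments",
    "EventTestResult",
    "event_locked_test",
    "PermutationResult",
    "permutation_null",
    "reduction_rate",
    "rates_frame",
    "BiasRateResult",
    "bias_rate_analysis",
    "SecondDiffResult",
    "second_differences",
    "TurningPointResult",
    "piecewise_fit",
    "MixedAnovaResult",
    "mixed_anova_segment_by_bias",
]


# ---------------------------------------------------------------------------
# segments


@dataclass(frozen=True)
class SegmentSummary:
    """Per-trial mean entropy of the three temporal segments."""

    trial_id: str
    bias_level: float
    initial: float
    late: float
    post: float
    sentence_length: int
    duration: float


def _nanmean_or_nan(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    return float(values.mean()) if values.size else float("nan")


def segment_means(
    profile: UncertaintyProfile, trial: TrialSpec, mode: str = "word_aligned"
) -> SegmentSummary:
    """Mean entropy per segment for one trial.

    ``mode="word_aligned"`` averages entropy at the bins containing word
    onsets within each in-sentence segment; ``mode="all_bins"`` averages
    all defined bins.  The post-sentence segment always uses all bins — no
    word onsets occur after sentence offset.  A segment with no defined
    values yields NaN and a warning.
    """
    if mode not in ("word_aligned", "all_bins"):
        raise ValueError("mode must be 'word_aligned' or 'all_bins'")
    D = trial.duration
    h = profile.entropy
    starts = profile.bin_starts
    if mode == "word_aligned":
        initial = _nanmean_or_nan(word_aligned_values(profile, (0.0, D / 2)))
        late = _nanmean_or_nan(word_aligned_values(profile, (D / 2, D)))
    else:
        initial = _nanmean_or_nan(h[(starts >= 0) & (starts < D / 2)])
        late = _nanmean_or_nan(h[(starts >= D / 2) & (starts < D)])
    post = _nanmean_or_nan(h[starts >= D])
    if not all(np.isfinite(v) for v in (initial, late, post)):
        warnings.warn(f"trial {trial.trial_id}: a segment has no defined values", stacklevel=2)
    return SegmentSummary(
        trial_id=trial.trial_id,
        bias_level=trial.bias_level,
        initial=initial,
        late=late,
        post=post,
        sentence_length=trial.sentence_length,
        duration=D,
    )


def summaries_frame(summaries: Sequence[SegmentSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


# ---------------------------------------------------------------------------
# ANOVA containers


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float          # SS_effect / SS_total
    eta_sq_partial: float  # SS_effect / (SS_effect + SS_error)


@dataclass(frozen=True)
class RmAnovaResult:
    anova: AnovaResult
    pairwise: pd.DataFrame   # columns: pair, t, df, p_bonf, cohen_d


def _cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else float("nan")


def rm_anova_segments(
    summaries: pd.DataFrame | Sequence[SegmentSummary],
    segments: tuple[str, ...] = ("initial", "late", "post"),
) -> RmAnovaResult:
    """Trial-level one-way repeated-measures ANOVA over the segments, with
    Bonferroni-corrected paired t-tests and paired Cohen's d
    (mean difference / SD of differences).
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    df = df.dropna(subset=list(segments))
    if len(df) < 3:
        raise ValueError("need >= 3 trials with all segments defined")
    long = df.melt(
        id_vars="trial_id",
        value_vars=list(segments),
        var_name="segment",
        value_name="H",
    )
    grand = long["H"].to_numpy()
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    seg_means = df[list(segments)].to_numpy().mean(axis=0)
    ss_seg = len(df) * float(((seg_means - seg_means.mean()) ** 2).sum())
    if ss_seg <= 1e-12 * max(ss_total, 1.0):
        # no segment effect at all (e.g. every trial flat): F = 0 exactly
        anova = AnovaResult(
            F=0.0, df1=float(len(segments) - 1),
            df2=float((len(segments) - 1) * (len(df) - 1)), p=1.0,
            eta_sq=0.0, eta_sq_partial=0.0,
        )
    else:
        table = pg.rm_anova(
            data=long, dv="H", within="segment", subject="trial_id", detailed=True
        )
        eff = table.loc[table["Source"] == "segment"].iloc[0]
        err = table.loc[table["Source"] == "Error"].iloc[0]
        ss_e, ss_r = float(eff["SS"]), float(err["SS"])
        anova = AnovaResult(
            F=float(eff["F"]),
            df1=float(eff["DF"]),
            df2=float(err["DF"]),
            p=float(eff["p_unc"]),
            eta_sq=ss_e / ss_total if ss_total > 0 else float("nan"),
            eta_sq_partial=ss_e / (ss_e + ss_r) if ss_e + ss_r > 0 else float("nan"),
        )
    pairs = list(itertools.combinations(segments, 2))
    rows = []
    for a, b in pairs:
        va, vb = df[a].to_numpy(), df[b].to_numpy()
        if np.allclose(va - vb, (va - vb)[0]):
            t, p = (float("nan"), 1.0) if np.allclose(va, vb) else (float("inf"), 0.0)
        else:
            t, p = sps.ttest_rel(va, vb)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "t": float(t),
                "df": len(df) - 1,
                "p_bonf": min(1.0, len(pairs) * float(p)),
                "cohen_d": _cohens_d_paired(va, vb),
            }
        )
    return RmAnovaResult(anova, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# event-locked pre/post test and its permutation null


def _window_means(profile: UncertaintyProfile, k: int, m: int) -> tuple[float, float]:
    """Mean entropy of bins [k-m, k) and [k, k+m); NaN if a window is empty."""
    h = profile.entropy
    pre = _nanmean_or_nan(h[max(k - m, 0) : k])
    post = _nanmean_or_nan(h[k : k + m])
    return pre, post


@dataclass(frozen=True)
class EventTestResult:
    t: float
    df: int
    p: float               # two-sided
    cohen_d: float
    pre_mean: float
    post_mean: float
    n_trials: int
    n_excluded: int


def _prepost_diffs(
    profiles: Sequence[UncertaintyProfile], window: float
) -> tuple[np.ndarray, list[UncertaintyProfile], int]:
    """Per-trial (pre - post) entropy differences at the ambiguous word
    onset; trials whose windows do not fit inside the trial are excluded."""
    diffs, kept = [], []
    n_excluded = 0
    for p in profiles:
        m = int(round(window / p.bin_width))
        k = p.bin_of(p.amb_onset)
        nb = p.counts.shape[0]
        if k < m or k > nb - m:
            n_excluded += 1
            continue
        pre, post = _window_means(p, k, m)
        if not (np.isfinite(pre) and np.isfinite(post)):
            n_excluded += 1
            continue
        diffs.append(pre - post)
        kept.append(p)
    return np.asarray(diffs), kept, n_excluded


def event_locked_test(
    profiles: Sequence[UncertaintyProfile], window: float = 1.0
) -> EventTestResult:
    """Paired t over trials of mean entropy 1 s before vs after the
    ambiguous word onset (positive t = uncertainty drops after onset)."""
    diffs, kept, n_excl = _prepost_diffs(profiles, window)
    if len(diffs) < 2:
        raise ValueError("need >= 2 trials with full pre/post windows")
    t, p = sps.ttest_1samp(diffs, 0.0)
    m = int(round(window / kept[0].bin_width))
    pre_post = np.array([_window_means(q, q.bin_of(q.amb_onset), m) for q in kept])
    return EventTestResult(
        t=float(t),
        df=len(diffs) - 1,
        p=float(p),
        cohen_d=float(diffs.mean() / diffs.std(ddof=1)) if diffs.std(ddof=1) > 0 else float("nan"),
        pre_mean=float(pre_post[:, 0].mean()),
        post_mean=float(pre_post[:, 1].mean()),
        n_trials=len(diffs),
        n_excluded=n_excl,
    )


@dataclass
class PermutationResult:
    observed_t: float
    null_t: np.ndarray
    p_one_sided: float
    seed: int
    n_trials: int
    n_excluded: int

    def __post_init__(self) -> None:
        expect = (1 + int(np.sum(self.null_t >= self.observed_t))) / (1 + len(self.null_t))
        if abs(self.p_one_sided - expect) > 1e-12:
            raise ValueError("p must equal (1 + #{null >= observed}) / (1 + N)")


def permutation_null(
    profiles: Sequence[UncertaintyProfile],
    n_iter: int = 10_000,
    window: float = 1.0,
    seed: int = 0,
) -> PermutationResult:
    """Event-locked permutation test.

    Per iteration one random timepoint is drawn uniformly within each
    trial's valid range (both 1 s windows must fit), the same pre/post
    paired t is computed at those timepoints, and the observed t at the
    ambiguous word onset is compared one-sidedly against the null:
    ``p = (1 + #{null >= observed}) / (1 + N)``.

    Trials without a full observed window are excluded from both the
    observed statistic and the null.
    """
    diffs_obs, kept, n_excl = _prepost_diffs(profiles, window)
    if len(diffs_obs) < 2:
        raise ValueError("need >= 2 trials with full pre/post windows")
    n_trials = len(kept)
    observed_t = float(
        diffs_obs.mean() / (diffs_obs.std(ddof=1) / np.sqrt(n_trials))
    )

    rng = np.random.default_rng(seed)
    null_diffs = np.empty((n_iter, n_trials))
    for j, p in enumerate(kept):
        m = int(round(window / p.bin_width))
        h = p.entropy
        nb = len(h)
        finite = np.isfinite(h)
        cs = np.concatenate([[0.0], np.cumsum(np.where(finite, h, 0.0))])
        cn = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
        ks = rng.integers(m, nb - m + 1, size=n_iter)
        pre_sum = cs[ks] - cs[ks - m]
        pre_n = cn[ks] - cn[ks - m]
        post_sum = cs[np.minimum(ks + m, nb)] - cs[ks]
        post_n = cn[np.minimum(ks + m, nb)] - cn[ks]
        with np.errstate(invalid="ignore", divide="ignore"):
            null_diffs[:, j] = pre_sum / pre_n - post_sum / post_n

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(null_diffs, axis=1)
        sd = np.nanstd(null_diffs, axis=1, ddof=1)
        cnt = np.sum(np.isfinite(null_diffs), axis=1)
        null_t = mean / (sd / np.sqrt(cnt))
    # zero-variance iterations have no defined t and are dropped; +/-inf
    # (constant non-zero diffs) keep their ordering role
    null_t = null_t[~np.isnan(null_t)]
    p_val = (1 + int(np.sum(null_t >= observed_t))) / (1 + len(null_t))
    return PermutationResult(
        observed_t=observed_t,
        null_t=null_t,
        p_one_sided=p_val,
        seed=seed,
        n_trials=n_trials,
        n_excluded=n_excl,
    )


# ---------------------------------------------------------------------------
# reduction rates and bias-level structure


def reduction_rate(summary: SegmentSummary, denominator: str = "characters") -> float:
    """Uncertainty reduction rate of one trial.

    ``(initial segment mean - post-sentence mean) / sentence length``;
    length is in characters by default (``denominator="seconds"`` divides
    by the audio duration instead).  May be negative.
    """
    if denominator == "characters":
        length = float(summary.sentence_length)
    elif denominator == "seconds":
        length = float(summary.duration)
    else:
        raise ValueError("denominator must be 'characters' or 'seconds'")
    if length <= 0:
        raise ValueError("sentence length must be positive")
    return (summary.initial - summary.post) / length


def rates_frame(
    summaries: Sequence[SegmentSummary] | pd.DataFrame, denominator: str = "characters"
) -> pd.DataFrame:
    """Tidy per-trial rates: columns trial_id, bias_level, rate."""
    items = (
        [SegmentSummary(**r) for r in summaries.to_dict("records")]
        if isinstance(summaries, pd.DataFrame)
        else list(summaries)
    )
    return pd.DataFrame(
        {
            "trial_id": [s.trial_id for s in items],
            "bias_level": [s.bias_level for s in items],
            "rate": [reduction_rate(s, denominator) for s in items],
        }
    )


@dataclass(frozen=True)
class BiasRateResult:
    anova: AnovaResult
    group_means: pd.DataFrame    # bias_level, mean, se, n
    tukey: pd.DataFrame          # group1, group2, meandiff, ci_low, ci_high, p_adj, cohen_d


def _cohens_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else float("nan")


def bias_rate_analysis(rates: pd.DataFrame, dv: str = "rate") -> BiasRateResult:
    """One-way between-trials ANOVA of the rate over bias levels, plus
    Tukey HSD pairwise comparisons (studentized-range based, Tukey-Kramer
    for unequal group sizes) with pooled-SD Cohen's d."""
    counts = rates.groupby("bias_level")[dv].count()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 bias levels with >= 2 trials each")
    y = rates[dv].to_numpy(dtype=float)
    groups = rates["bias_level"].to_numpy()
    if y.var() == 0.0:
        # all groups equal constants: no effect, no variance to test
        levels = sorted(set(groups))
        gm = (rates.groupby("bias_level")[dv]
              .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index())
        gm["se"] = 0.0
        k, n = len(levels), len(y)
        tukey0 = pd.DataFrame(
            [{"group1": a, "group2": b, "meandiff": 0.0, "ci_low": 0.0,
              "ci_high": 0.0, "p_adj": 1.0, "cohen_d": float("nan")}
             for a, b in itertools.combinations(levels, 2)]
        )
        return BiasRateResult(
            AnovaResult(0.0, float(k - 1), float(n - k), 1.0, 0.0, 0.0), gm, tukey0
        )
    table = pg.anova(data=rates, dv=dv, between="bias_level", detailed=True)
    eff = table.loc[table["Source"] == "bias_level"].iloc[0]
    err = table.loc[table["Source"] == "Within"].iloc[0]
    ss_e, ss_r = float(eff["SS"]), float(err["SS"])
    anova = AnovaResult(
        F=float(eff["F"]),
        df1=float(eff["DF"]),
        df2=float(err["DF"]),
        p=float(eff["p_unc"]),
        eta_sq=ss_e / (ss_e + ss_r) if ss_e + ss_r > 0 else float("nan"),
        eta_sq_partial=ss_e / (ss_e + ss_r) if ss_e + ss_r > 0 else float("nan"),
    )
    gm = (
        rates.groupby("bias_level")[dv]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    gm["se"] = gm["sd"] / np.sqrt(gm["n"])

    hsd = pairwise_tukeyhsd(endog=y, groups=groups)
    levels = list(hsd.groupsunique)
    rows = []
    for (i, j), md, (lo, hi), padj in zip(
        itertools.combinations(range(len(levels)), 2),
        hsd.meandiffs,
        hsd.confint,
        hsd.pvalues,
    ):
        a = y[groups == levels[i]]
        b = y[groups == levels[j]]
        rows.append(
            {
                "group1": levels[i],
                "group2": levels[j],
                "meandiff": float(md),     # mean(group2) - mean(group1)
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_adj": float(padj),
                "cohen_d": _cohens_d_pooled(b, a),
            }
        )
    return BiasRateResult(anova, gm, pd.DataFrame(rows))


@dataclass(frozen=True)
class SecondDiffResult:
    """Bootstrap second differences of group-mean rates across bias levels.

    ``dm1 = (M[0] - M[0.2]) - (M[0.2] - M[0.4])`` and
    ``dm2 = (M[1] - M[0.8]) - (M[0.8] - M[0.6])``; both are zero when the
    rate is linear in bias level on each branch.
    """

    dm1: float
    dm2: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    p1: float
    p2: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        for val, (lo, hi) in ((self.dm1, self.ci1), (self.dm2, self.ci2)):
            if np.isfinite(val) and not (lo <= val <= hi):
                raise ValueError("bootstrap CI must contain the point estimate")


def _boot_p(draws: np.ndarray) -> float:
    n = len(draws)
    lo = (1 + int(np.sum(draws <= 0))) / (1 + n)
    hi = (1 + int(np.sum(draws >= 0))) / (1 + n)
    return min(1.0, 2.0 * min(lo, hi))


def second_differences(
    rates: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    branch1: tuple[float, float, float] = (0.0, 0.2, 0.4),
    branch2: tuple[float, float, float] = (1.0, 0.8, 0.6),
) -> SecondDiffResult:
    """Percentile-bootstrap (resampling trials within level) test of the
    linearity of group-mean rates across adjacent bias levels."""
    rng = np.random.default_rng(seed)
    values: dict[float, np.ndarray] = {}
    for lvl in set(branch1) | set(branch2):
        v = rates.loc[rates["bias_level"] == lvl, "rate"].to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"bias level {lvl} missing from rates")
        values[lvl] = v

    def second_diff(means: Mapping[float, float], branch) -> float:
        a, b, c = (means[l] for l in branch)
        return (a - b) - (b - c)

    point = {l: float(v.mean()) for l, v in values.items()}
    boot_means = {
        l: v[rng.integers(0, len(v), size=(n_boot, len(v)))].mean(axis=1)
        for l, v in values.items()
    }
    draws1 = second_diff(boot_means, branch1)
    draws2 = second_diff(boot_means, branch2)
    ci = lambda d: tuple(np.percentile(d, [2.5, 97.5]))
    return SecondDiffResult(
        dm1=second_diff(point, branch1),
        dm2=second_diff(point, branch2),
        ci1=ci(draws1),
        ci2=ci(draws2),
        p1=_boot_p(draws1),
        p2=_boot_p(draws2),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# piecewise-linear fit / turning point


@dataclass(frozen=True)
class TurningPointResult:
    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]          # bits/s per segment
    turning_point: float               # onset of the fastest-declining segment
    fastest_slope: float
    sse: float
    no_decline: bool

    def __post_init__(self) -> None:
        if self.slopes and self.fastest_slope > min(self.slopes) + 1e-12:
            raise ValueError("fastest slope must be the minimum slope")


def piecewise_fit(
    profile: UncertaintyProfile | tuple[np.ndarray, np.ndarray],
    n_segments: int = 3,
    min_seg: int = 3,
    candidate_stride: int = 1,
    decline_threshold: float = 1e-6,
) -> TurningPointResult:
    """Continuous piecewise-linear fit with breakpoints on the bin grid.

    Breakpoints are chosen by exhaustive grid search minimising the SSE of
    the least-squares fit with truncated-line basis
    ``[1, t, (t - b1)+, ..., (t - b_{k})+]``.  The turning point is the
    start time of the segment with the most negative slope; if that slope
    is not below ``-decline_threshold`` the profile is flagged as having
    no decline.  ``min_seg`` sets the minimum number of bins per segment.
    """
    if isinstance(profile, UncertaintyProfile):
        t_all, y_all = profile.bin_starts, profile.entropy
    else:
        t_all, y_all = profile
    mask = np.isfinite(np.asarray(y_all, dtype=float))
    t = np.asarray(t_all, dtype=float)[mask]
    y = np.asarray(y_all, dtype=float)[mask]
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if t.size == 0:
        raise ValueError("all-missing profile")
    if t.size < n_segments * min_seg or t.size < 2 * n_segments:
        raise ValueError("fewer defined bins than the model needs")

    n_break = n_segments - 1
    idx_cand = np.arange(min_seg, t.size - min_seg, candidate_stride)

    def fit(bps: tuple[float, ...]) -> tuple[float, np.ndarray]:
        cols = [np.ones_like(t), t] + [np.clip(t - b, 0.0, None) for b in bps]
        X = np.stack(cols, axis=1)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), beta

    best_sse, best_beta, best_bps = np.inf, None, ()
    if n_break == 0:
        best_sse, best_beta = fit(())
    else:
        for combo in itertools.combinations(idx_cand, n_break):
            if any(b - a < min_seg for a, b in zip(combo, combo[1:])):
                continue
            bps = tuple(t[list(combo)])
            sse, beta = fit(bps)
            if sse < best_sse - 1e-15:
                best_sse, best_beta, best_bps = sse, beta, bps
    if best_beta is None:
        raise ValueError("no admissible breakpoint placement")

    slopes = tuple(np.cumsum(best_beta[1:]).tolist())
    seg_starts = (float(t[0]),) + best_bps
    i_min = int(np.argmin(slopes))
    fastest = float(slopes[i_min])
    return TurningPointResult(
        breakpoints=best_bps,
        slopes=slopes,
        turning_point=float(seg_starts[i_min]),
        fastest_slope=fastest,
        sse=best_sse,
        no_decline=fastest >= -decline_threshold,
    )


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass(frozen=True)
class MixedAnovaResult:
    table: pd.DataFrame           # Source, SS, DF1, DF2, F, p, eta_sq, eta_sq_partial
    simple_effects: pd.DataFrame  # per-segment one-way bias ANOVAs


def mixed_anova_segment_by_bias(
    summaries: pd.DataFrame | Sequence[SegmentSummary],
) -> MixedAnovaResult:
    """3 (segment, within-trial) x k (bias level, between-trial) mixed
    ANOVA, plus per-segment simple-effects one-way ANOVAs of bias level."""
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    df = df.dropna(subset=["initial", "late", "post"])
    counts = df.groupby("bias_level")["trial_id"].count()
    if (counts < 2).any():
        raise ValueError("each bias level needs >= 2 trials")
    long = df.melt(
        id_vars=["trial_id", "bias_level"],
        value_vars=["initial", "late", "post"],
        var_name="segment",
        value_name="H",
    )
    if long["H"].var(ddof=0) == 0:
        # degenerate all-equal design: every effect is exactly zero
        table = pd.DataFrame(
            {
                "Source": ["bias_level", "segment", "Interaction"],
                "F": [0.0, 0.0, 0.0],
                "p": [1.0, 1.0, 1.0],
                "eta_sq": [0.0, 0.0, 0.0],
                "eta_sq_partial": [0.0, 0.0, 0.0],
            }
        )
    else:
        aov = pg.mixed_anova(
            data=long, dv="H", within="segment", between="bias_level", subject="trial_id"
        )
        y = long["H"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        table = aov.rename(columns={"p_unc": "p"})[
            ["Source", "SS", "DF1", "DF2", "F", "p", "np2"]
        ].rename(columns={"np2": "eta_sq_partial"})
        table["eta_sq"] = table["SS"] / ss_total
    rows = []
    for seg in ("initial", "late", "post"):
        sub = long[long["segment"] == seg]
        if sub["H"].var(ddof=0) == 0:
            rows.append({"segment": seg, "F": 0.0, "df1": counts.size - 1,
                         "df2": len(sub) - counts.size, "p": 1.0, "eta_sq": 0.0})
            continue
        t2 = pg.anova(data=sub, dv="H", between="bias_level", detailed=True)
        eff = t2.loc[t2["Source"] == "bias_level"].iloc[0]
        err = t2.loc[t2["Source"] == "Within"].iloc[0]
        rows.append(
            {
                "segment": seg,
                "F": float(eff["F"]),
                "df1": float(eff["DF"]),
                "df2": float(err["DF"]),
                "p": float(eff["p_unc"]),
                "eta_sq": float(eff["SS"] / (eff["SS"] + err["SS"])),
            }
        )
    return MixedAnovaResult(table, pd.DataFrame(rows))
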