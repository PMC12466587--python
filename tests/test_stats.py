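"""Segment statistics, permutation null, rates, bootstrap and piecewise fits.

ANOVA implementations are checked against brute-force sums-of-squares
oracles computed directly from their textbook definitions.
"""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from semgaze.entropy import UncertaintyProfile, build_profile
from semgaze.preprocess import ChoiceSeries
from semgaze.stats import (
    SegmentSummary,
    bias_rate_analysis,
    event_locked_test,
    mixed_anova_segment_by_bias,
    permutation_null,
    piecewise_fit,
    rates_frame,
    reduction_rate,
    rm_anova_segments,
    second_differences,
    segment_means,
    summaries_frame,
)
from conftest import make_trial


# ---------------------------------------------------------------------------
# brute-force oracles


def oneway_rm_anova_oracle(table: np.ndarray):
    """Within-subject one-way ANOVA from first principles.

    ``table`` is (subjects, conditions).  SS_cond = n * sum (cond mean -
    grand)^2; SS_err = SS_total - SS_subj - SS_cond.
    """
    n, k = table.shape
    grand = table.mean()
    ss_total = ((table - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    p = sps.f.sf(F, df1, df2)
    return F, df1, df2, p, ss_cond, ss_err, ss_total


def oneway_anova_oracle(groups: list[np.ndarray]):
    """Between-groups one-way ANOVA from first principles."""
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_y) - len(groups)
    F = (ss_between / df1) / (ss_within / df2)
    p = sps.f.sf(F, df1, df2)
    return F, df1, df2, p, ss_between, ss_within


def profile_from_entropy(h, bin_width=0.1, duration=None, amb_onset=None, trial_id="t0000"):
    """Profile whose per-bin entropy approximates ``h`` by planting a
    two-option count split with the requested entropy."""
    h = np.asarray(h, dtype=float)
    n = 100_000
    # solve -p log p - (1-p) log(1-p) = h for p in [0.5, 1]
    grid = np.linspace(0.5, 1.0 - 1e-12, 20001)
    hg = -grid * np.log2(grid) - (1 - grid) * np.log2(1 - grid)
    p = np.interp(np.clip(h, 0, 1), hg[::-1], grid[::-1])
    counts = np.zeros((len(h), 4), dtype=np.int64)
    counts[:, 0] = np.round(n * p).astype(np.int64)
    counts[:, 1] = n - counts[:, 0]
    nb = len(h)
    duration = duration if duration is not None else nb * bin_width
    return UncertaintyProfile(
        trial_id=trial_id,
        bias_level=0.0,
        bin_width=bin_width,
        duration=duration,
        t_end=nb * bin_width,
        counts=counts,
        word_onsets=np.arange(0.05, duration, 0.2),
        amb_onset=amb_onset if amb_onset is not None else duration / 2,
        sentence_length=31,
    )


# ---------------------------------------------------------------------------
# segments


class TestSegmentMeans:
    def _profile(self, h_fn, duration=8.0, tail=5.0, bw=0.1):
        nb = int((duration + tail) / bw)
        starts = np.arange(nb) * bw
        h = np.clip(h_fn(starts + bw / 2), 0.0, 1.0 + 0.0)
        return profile_from_entropy(h, bw, duration=duration)

    def test_constant_profile_gives_equal_means(self):
        prof = self._profile(lambda t: np.full_like(t, 0.8))
        trial = make_trial(duration=8.0)
        s = segment_means(prof, trial, mode="all_bins")
        assert (s.initial, s.late, s.post) == pytest.approx((0.8, 0.8, 0.8), abs=2e-4)

    def test_piecewise_constant_profile(self):
        """H = 1 before D/2, 0.5 in the late half, 0 after offset."""
        def h_fn(t):
            return np.where(t < 4.0, 1.0, np.where(t < 8.0, 0.5, 0.0))

        prof = self._profile(h_fn)
        s = segment_means(prof, make_trial(duration=8.0), mode="all_bins")
        assert (s.initial, s.late, s.post) == pytest.approx((1.0, 0.5, 0.0), abs=2e-4)

    def test_linear_profile_segment_integrals(self):
        """H(t) = 1 - t/(2D) over the sentence then 0: all-bins means are
        the segment integrals (0.875, 0.625, 0) up to discretization."""
        D = 8.0
        def h_fn(t):
            return np.where(t < D, 1.0 - t / (2 * D), 0.0)

        prof = self._profile(h_fn)
        s = segment_means(prof, make_trial(duration=D), mode="all_bins")
        assert s.initial == pytest.approx(0.875, abs=5e-3)
        assert s.late == pytest.approx(0.625, abs=5e-3)
        assert s.post == pytest.approx(0.0, abs=1e-3)


class TestRmAnova:
    def test_flat_trials_give_zero_F(self):
        rows = [
            SegmentSummary(f"t{i}", 0.0, 1.5 + 0.1 * i, 1.5 + 0.1 * i, 1.5 + 0.1 * i, 31, 8.0)
            for i in range(6)
        ]
        res = rm_anova_segments(rows)
        assert res.anova.F == 0.0 and res.anova.p == 1.0

    def test_matches_brute_force_oracle(self):
        """Planted 20-trial tables: F, dfs, p and effect sizes agree with
        the direct sums-of-squares computation to 1e-6."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            table = rng.normal(loc=[2.0, 1.5, 1.0], scale=0.2, size=(20, 3))
            rows = [
                SegmentSummary(f"t{i:02d}", 0.0, *table[i], 31, 8.0) for i in range(20)
            ]
            res = rm_anova_segments(rows)
            F, df1, df2, p, ss_c, ss_e, ss_t = oneway_rm_anova_oracle(table)
            assert res.anova.F == pytest.approx(F, abs=1e-6)
            assert (res.anova.df1, res.anova.df2) == (df1, df2)
            assert res.anova.p == pytest.approx(p, abs=1e-9)
            assert res.anova.eta_sq == pytest.approx(ss_c / ss_t, abs=1e-9)
            assert res.anova.eta_sq_partial == pytest.approx(ss_c / (ss_c + ss_e), abs=1e-9)

    def test_planted_separation_detected_with_bonferroni(self):
        rng = np.random.default_rng(3)
        table = rng.normal(loc=[2.0, 1.5, 1.0], scale=0.1, size=(10, 3))
        rows = [SegmentSummary(f"t{i}", 0.0, *table[i], 31, 8.0) for i in range(10)]
        res = rm_anova_segments(rows)
        assert res.anova.F > 50
        assert (res.pairwise["p_bonf"] < 0.05).all()
        d = res.pairwise.set_index("pair")["cohen_d"]
        diff = table[:, 0] - table[:, 1]
        assert d["initial-late"] == pytest.approx(diff.mean() / diff.std(ddof=1), abs=1e-9)

    def test_two_segment_case_reduces_to_paired_t(self):
        rng = np.random.default_rng(5)
        table = rng.normal(size=(12, 2))
        rows = [SegmentSummary(f"t{i}", 0.0, table[i, 0], table[i, 1], 0.0, 31, 8.0)
                for i in range(12)]
        res = rm_anova_segments(rows, segments=("initial", "late"))
        t, p = sps.ttest_rel(table[:, 0], table[:, 1])
        assert res.anova.F == pytest.approx(t**2, abs=1e-9)
        assert res.anova.p == pytest.approx(p, abs=1e-12)


# ---------------------------------------------------------------------------
# event-locked test and permutation null


class TestEventLocked:
    def test_flat_profiles_give_near_zero_t(self):
        rng = np.random.default_rng(0)
        profs = [
            profile_from_entropy(
                0.8 + rng.normal(0, 1e-4, 130), duration=8.0, amb_onset=4.0,
                trial_id=f"t{i}",
            )
            for i in range(10)
        ]
        res = event_locked_test(profs)
        assert abs(res.t) < 3.0
        assert abs(res.pre_mean - res.post_mean) < 1e-3

    def test_single_trial_rejected(self):
        prof = profile_from_entropy(np.linspace(1, 0.5, 130), amb_onset=6.0)
        with pytest.raises(ValueError):
            event_locked_test([prof])

    def test_onset_too_close_to_edge_excluded(self):
        good = [
            profile_from_entropy(np.linspace(1, 0.5, 130), amb_onset=6.0, trial_id=f"g{i}")
            for i in range(3)
        ]
        bad = profile_from_entropy(np.linspace(1, 0.5, 130), amb_onset=0.3, trial_id="bad")
        res = event_locked_test(good + [bad])
        assert res.n_trials == 3 and res.n_excluded == 1

    def test_word_boost_detected_on_generator_data(self):
        """With a planted onset boost, pre > post on average and t > 0;
        without it the contrast is small."""
        from semgaze.experiments import dataset_profiles
        from semgaze.synthetic import GeneratorConfig

        ts = {}
        for boost in (0.0, 2.0):
            cfg = GeneratorConfig(
                n_participants=25, n_trials_per_bias=3, word_boost=boost, seed=13
            )
            _, profiles, _ = dataset_profiles(cfg)
            ts[boost] = event_locked_test(profiles).t
        assert ts[2.0] > ts[0.0]
        assert ts[2.0] > 2.0


class TestPermutationNull:
    def _decline_profiles(self, n_trials=8, seed=0):
        rng = np.random.default_rng(seed)
        profs = []
        for i in range(n_trials):
            h = np.linspace(1.0, 0.4, 130) + rng.normal(0, 0.01, 130)
            profs.append(
                profile_from_entropy(np.clip(h, 0, 1), amb_onset=rng.uniform(3, 6),
                                     trial_id=f"t{i}")
            )
        return profs

    def test_same_seed_reproduces_null(self):
        profs = self._decline_profiles()
        a = permutation_null(profs, n_iter=200, seed=42)
        b = permutation_null(profs, n_iter=200, seed=42)
        assert np.array_equal(a.null_t, b.null_t)
        assert a.p_one_sided == b.p_one_sided

    def test_p_floor_when_observed_exceeds_all_null(self):
        """Observed t above every null draw gives p = 1/(N+1)."""
        h = np.concatenate([np.full(60, 1.0), np.full(70, 0.2)])
        profs = [
            profile_from_entropy(h, amb_onset=6.0, trial_id=f"t{i}") for i in range(6)
        ]
        res = permutation_null(profs, n_iter=99, seed=0)
        n_null = len(res.null_t)
        if np.all(res.null_t < res.observed_t):
            assert res.p_one_sided == pytest.approx(1 / (n_null + 1))
        assert res.p_one_sided >= 1 / (n_null + 1)

    def test_p_formula_invariant_enforced(self):
        profs = self._decline_profiles()
        res = permutation_null(profs, n_iter=500, seed=3)
        expect = (1 + np.sum(res.null_t >= res.observed_t)) / (1 + len(res.null_t))
        assert res.p_one_sided == pytest.approx(expect, abs=1e-15)

    def test_excluded_trials_leave_both_sides(self):
        profs = self._decline_profiles(6)
        short = profile_from_entropy(np.linspace(1, 0.5, 15), amb_onset=0.5,
                                     trial_id="short")
        res = permutation_null(profs + [short], n_iter=100, seed=2)
        assert res.n_trials == 6 and res.n_excluded == 1


# ---------------------------------------------------------------------------
# rates, bias structure, second differences


class TestReductionRate:
    def test_worked_example(self):
        s = SegmentSummary("t0", 0.0, 2.0, 1.4, 0.9, 31, 8.0)
        assert reduction_rate(s) == pytest.approx((2.0 - 0.9) / 31)
        assert reduction_rate(s) == pytest.approx(0.0355, abs=5e-4)

    def test_equal_means_give_zero(self):
        s = SegmentSummary("t0", 0.0, 1.0, 1.0, 1.0, 31, 8.0)
        assert reduction_rate(s) == 0.0

    def test_rate_scales_inversely_with_length(self):
        a = SegmentSummary("t0", 0.0, 2.0, 1.4, 0.9, 20, 8.0)
        b = SegmentSummary("t0", 0.0, 2.0, 1.4, 0.9, 40, 8.0)
        assert reduction_rate(a) == pytest.approx(2 * reduction_rate(b))

    def test_seconds_denominator(self):
        s = SegmentSummary("t0", 0.0, 2.0, 1.4, 0.9, 31, 10.0)
        assert reduction_rate(s, "seconds") == pytest.approx(1.1 / 10.0)


class TestBiasRateAnalysis:
    def _rates(self, means, n=8, scale=0.003, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for b, m in means.items():
            for i in range(n):
                rows.append({"trial_id": f"t{b}_{i}", "bias_level": b,
                             "rate": rng.normal(m, scale)})
        return pd.DataFrame(rows)

    def test_equal_groups_give_zero_F(self):
        df = self._rates({0.0: 0.02, 0.2: 0.02}, scale=0.0)
        df["rate"] = 0.02
        res = bias_rate_analysis(df)
        assert res.anova.F == 0.0
        assert res.anova.p == 1.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_matches_brute_force_oracle(self):
        """Random 20-per-level tables: F and p agree with the direct
        between/within sums-of-squares computation to 1e-6."""
        rng = np.random.default_rng(23)
        for _ in range(5):
            groups = {b: rng.normal(0.02 + 0.01 * b, 0.005, 20)
                      for b in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)}
            df = pd.DataFrame(
                [
                    {"trial_id": f"t{b}_{i}", "bias_level": b, "rate": v}
                    for b, vs in groups.items()
                    for i, v in enumerate(vs)
                ]
            )
            res = bias_rate_analysis(df)
            F, df1, df2, p, ssb, ssw = oneway_anova_oracle(list(groups.values()))
            assert res.anova.F == pytest.approx(F, abs=1e-6)
            assert (res.anova.df1, res.anova.df2) == (df1, df2)
            assert res.anova.p == pytest.approx(p, abs=1e-9)
            assert res.anova.eta_sq == pytest.approx(ssb / (ssb + ssw), abs=1e-9)

    def test_planted_increasing_means_flag_extreme_pairs(self):
        df = self._rates({0.0: 0.04, 0.2: 0.03, 0.4: 0.02}, n=10, scale=0.004, seed=2)
        res = bias_rate_analysis(df)
        assert res.anova.p < 0.001
        tk = res.tukey.set_index(["group1", "group2"])
        assert tk.loc[(0.0, 0.4), "p_adj"] < 0.01
        assert tk.loc[(0.0, 0.4), "cohen_d"] < 0  # group2 - group1 convention

    def test_two_groups_tukey_matches_t_test(self):
        """With two groups the studentized range collapses to the t
        distribution (q = t * sqrt(2)), so Tukey p equals the two-sample
        t-test p."""
        df = self._rates({0.0: 0.04, 1.0: 0.035}, n=12, scale=0.004, seed=5)
        res = bias_rate_analysis(df)
        a = df.loc[df.bias_level == 0.0, "rate"]
        b = df.loc[df.bias_level == 1.0, "rate"]
        _, p = sps.ttest_ind(a, b)
        assert res.tukey["p_adj"].iloc[0] == pytest.approx(p, abs=1e-7)

    def test_small_level_rejected(self):
        df = self._rates({0.0: 0.02, 0.2: 0.03})
        df = df[~((df.bias_level == 0.2) & (df.trial_id != "t0.2_0"))]
        with pytest.raises(ValueError):
            bias_rate_analysis(df)


class TestSecondDifferences:
    def _frame(self, means, n=30, scale=1e-4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for b, m in means.items():
            for i in range(n):
                rows.append({"trial_id": f"{b}_{i}", "bias_level": b,
                             "rate": rng.normal(m, scale)})
        return pd.DataFrame(rows)

    def test_linear_means_give_zero_second_difference(self):
        means = {0.0: 0.04, 0.2: 0.03, 0.4: 0.02, 0.6: 0.02, 0.8: 0.03, 1.0: 0.04}
        res = second_differences(self._frame(means), n_boot=500, seed=1)
        assert res.dm1 == pytest.approx(0.0, abs=1e-4)
        assert res.dm2 == pytest.approx(0.0, abs=1e-4)
        assert res.ci1[0] <= 0 <= res.ci1[1]

    def test_hand_computed_point_estimates(self):
        """Means (0.04, 0.03, 0.02) on levels (0, 0.2, 0.4) give dM1 = 0;
        convex means (0.05, 0.03, 0.02) give dM1 = 0.01."""
        means = {0.0: 0.05, 0.2: 0.03, 0.4: 0.02, 0.6: 0.02, 0.8: 0.03, 1.0: 0.04}
        res = second_differences(self._frame(means), n_boot=2000, seed=2)
        assert res.dm1 == pytest.approx(0.01, abs=1e-4)
        assert res.dm2 == pytest.approx(0.0, abs=1e-4)
        # with tiny noise the convex dM1 CI excludes zero and p is small
        assert res.ci1[0] > 0.0
        assert res.p1 < 0.01
        assert res.ci2[0] <= 0 <= res.ci2[1]

    def test_missing_level_rejected(self):
        means = {0.0: 0.04, 0.2: 0.03, 0.6: 0.02, 0.8: 0.03, 1.0: 0.04}
        with pytest.raises(ValueError):
            second_differences(self._frame(means), n_boot=100)

    def test_ci_contains_point_estimate(self):
        means = {0.0: 0.045, 0.2: 0.03, 0.4: 0.021, 0.6: 0.02, 0.8: 0.028, 1.0: 0.041}
        res = second_differences(self._frame(means, scale=0.004), n_boot=2000, seed=3)
        assert res.ci1[0] <= res.dm1 <= res.ci1[1]
        assert res.ci2[0] <= res.dm2 <= res.ci2[1]


# ---------------------------------------------------------------------------
# piecewise fits


class TestPiecewiseFit:
    def _planted(self, bw=0.1, t_break=3.0, slope=-0.5, t_flat=6.0, nb=120, noise=0.0,
                 seed=0):
        t = np.arange(nb) * bw
        h = np.where(
            t < t_break, 2.0,
            np.where(t < t_flat, 2.0 + slope * (t - t_break),
                     2.0 + slope * (t_flat - t_break)),
        )
        rng = np.random.default_rng(seed)
        return t, h + rng.normal(0, noise, nb)

    def test_recovers_planted_breakpoint_and_slope(self):
        t, h = self._planted()
        fit = piecewise_fit((t, h))
        assert fit.turning_point == pytest.approx(3.0, abs=0.1)
        assert fit.fastest_slope == pytest.approx(-0.5, abs=0.02)
        assert not fit.no_decline
        assert min(fit.slopes) == fit.fastest_slope

    def test_globally_linear_profile_recovers_slope(self):
        t = np.arange(100) * 0.1
        fit = piecewise_fit((t, 2.0 - 0.12 * t))
        assert fit.fastest_slope == pytest.approx(-0.12, abs=1e-6)
        for s in fit.slopes:
            assert s == pytest.approx(-0.12, abs=1e-6)

    def test_flat_profile_flagged_no_decline(self):
        t = np.arange(60) * 0.1
        fit = piecewise_fit((t, np.full(60, 1.3)))
        assert fit.no_decline
        for s in fit.slopes:
            assert s == pytest.approx(0.0, abs=1e-9)

    def test_too_few_bins_rejected(self):
        t = np.arange(5) * 0.1
        with pytest.raises(ValueError):
            piecewise_fit((t, np.ones(5)), n_segments=3)

    def test_all_missing_rejected(self):
        t = np.arange(30) * 0.1
        with pytest.raises(ValueError):
            piecewise_fit((t, np.full(30, np.nan)))

    def test_missing_bins_skipped(self):
        t, h = self._planted()
        h[10:14] = np.nan
        fit = piecewise_fit((t, h))
        assert fit.turning_point == pytest.approx(3.0, abs=0.2)


# ---------------------------------------------------------------------------
# mixed ANOVA


class TestMixedAnova:
    def _summaries(self, seg_means, bias_effect=None, n=6, scale=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for b in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            shift = bias_effect(b) if bias_effect else (0.0, 0.0, 0.0)
            for i in range(n):
                vals = rng.normal(np.asarray(seg_means) + np.asarray(shift), scale)
                rows.append(
                    SegmentSummary(f"t{b}_{i}", b, *vals, 31, 8.0)
                )
        return rows

    def test_identical_cells_give_zero_everywhere(self):
        rows = self._summaries((1.5, 1.5, 1.5), scale=0.0)
        res = mixed_anova_segment_by_bias(rows)
        assert (res.table["F"] == 0.0).all()
        assert (res.simple_effects["F"] == 0.0).all()

    def test_bias_effect_planted_only_post_sentence(self):
        """A bias effect confined to the post-sentence segment shows up in
        that segment's simple effect, not in the initial segment, and
        drives the interaction."""
        rows = self._summaries(
            (1.8, 1.4, 1.0),
            bias_effect=lambda b: (0.0, 0.0, -0.4 * 2 * abs(b - 0.5)),
            n=8,
            scale=0.05,
            seed=9,
        )
        res = mixed_anova_segment_by_bias(rows)
        se = res.simple_effects.set_index("segment")
        assert se.loc["post", "p"] < 0.001
        assert se.loc["initial", "p"] > 0.05
        inter = res.table.loc[res.table.Source == "Interaction"].iloc[0]
        assert inter["p"] < 0.001

    def test_interaction_f_calibrated_under_null(self):
        """Without a planted bias effect the interaction F stays near its
        null expectation E[F] = df2 / (df2 - 2) over simulations."""
        fs = []
        for seed in range(40):
            rows = self._summaries((1.8, 1.4, 1.0), n=3, scale=0.1, seed=seed)
            res = mixed_anova_segment_by_bias(rows)
            inter = res.table.loc[res.table.Source == "Interaction"].iloc[0]
            fs.append(float(inter["F"]))
        df2 = float(res.table.loc[res.table.Source == "Interaction", "DF2"].iloc[0])
        expected = df2 / (df2 - 2.0)
        assert np.mean(fs) == pytest.approx(expected, rel=0.35)

    def test_empty_cell_rejected(self):
        rows = self._summaries((1.8, 1.4, 1.0))
        rows = [r for r in rows if not (r.bias_level == 0.4 and r.trial_id != "t0.4_0")]
        with pytest.raises(ValueError):
            mixed_anova_segment_by_bias(rows)
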