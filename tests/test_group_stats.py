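import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eden_gaze.errors import GroupingError, InvalidConfigError
from eden_gaze.group_stats import (
    assign_groups,
    cohort_assignments,
    group_timecourse_contrast,
    mann_whitney_rb,
    normalize_ratings,
    paired_signed_rank,
    r_to_d,
    required_n_per_group,
    signed_rank_statistics,
    welch_test,
)


def ratings_frame(records):
    rows = []
    for pid, sid, val in records:
        rows.append(dict(participant_id=pid, stimulus_id=sid,
                         beauty=val, liking=val, composition=val, color=val,
                         seen_before=False))
    return pd.DataFrame(rows)


def brute_force_signrank(diffs):
    """Exact two-sided p and rank-biserial by enumerating sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    total = ranks.sum()
    r_rb = (w_obs - (total - w_obs)) / total
    return p, r_rb


class TestNormalizeRatings:
    def test_three_composites_give_unit_z(self):
        df = ratings_frame([("p1", f"s{i}", v) for i, v in enumerate((2, 4, 6))])
        out = normalize_ratings(df)
        np.testing.assert_allclose(sorted(out["z"]), [-1, 0, 1], atol=1e-12)

    def test_per_participant_zero_mean(self):
        rng = np.random.default_rng(0)
        df = ratings_frame(
            [(f"p{j}", f"s{i}", int(rng.integers(1, 11)))
             for j in range(5) for i in range(6)]
        )
        out = normalize_ratings(df)
        means = out.groupby("participant_id")["z"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-9)

    def test_additive_shift_invariance(self):
        base = [("p1", f"s{i}", v) for i, v in enumerate((2, 4, 6))]
        shifted = [("p1", f"s{i}", v + 3) for i, v in enumerate((2, 4, 6))]
        z0 = normalize_ratings(ratings_frame(base))["z"]
        z1 = normalize_ratings(ratings_frame(shifted))["z"]
        np.testing.assert_allclose(z0, z1, atol=1e-12)

    def test_zero_sd_participant_flagged(self):
        df = ratings_frame([("p1", "s1", 5), ("p1", "s2", 5)])
        out = normalize_ratings(df)
        assert out["degenerate"].all()
        assert out["z"].isna().all()

    def test_separate_sets_normalized_independently(self):
        df = ratings_frame(
            [("p1", "a1", 2), ("p1", "a2", 6), ("p1", "b1", 4), ("p1", "b2", 8)]
        )
        labels = {"a1": "primary", "a2": "primary",
                  "b1": "secondary", "b2": "secondary"}
        out = normalize_ratings(df, set_labels=labels).set_index("stimulus_id")
        for pair in (("a1", "a2"), ("b1", "b2")):
            np.testing.assert_allclose(
                out.loc[list(pair), "z"], [-math.sqrt(0.5), math.sqrt(0.5)]
            )

    def test_single_stimulus_rejected(self):
        with pytest.raises(GroupingError):
            normalize_ratings(ratings_frame([("p1", "s1", 5)]))


class TestAssignGroups:
    @staticmethod
    def normalized(n, n_stim=8, seed=0):
        rng = np.random.default_rng(seed)
        df = ratings_frame(
            [(f"p{j:03d}", f"s{i}", int(rng.integers(1, 11)))
             for j in range(n) for i in range(n_stim)]
        )
        return normalize_ratings(df)

    def test_48_participants_split_16_16_16(self):
        groups = assign_groups(self.normalized(48))
        counts = groups.groupby(["stimulus_id", "group"]).size().unstack()
        assert (counts["high"] == 16).all()
        assert (counts["medium"] == 16).all()
        assert (counts["low"] == 16).all()

    def test_six_participants_split_2_2_2(self):
        groups = assign_groups(self.normalized(6))
        counts = groups.groupby(["stimulus_id", "group"]).size().unstack()
        assert (counts == 2).all().all()

    def test_ties_resolved_deterministically_by_id(self):
        df = ratings_frame(
            [("pA", "s1", 8), ("pA", "s2", 2),
             ("pB", "s1", 8), ("pB", "s2", 2),
             ("pC", "s1", 2), ("pC", "s2", 8)]
        )
        norm = normalize_ratings(df)
        g1 = assign_groups(norm)
        g2 = assign_groups(norm)
        pd.testing.assert_frame_equal(g1, g2)
        s1 = g1[g1["stimulus_id"] == "s1"].set_index("participant_id")["group"]
        # pA and pB tie at the top of s1: the earlier id takes 'high'
        assert s1["pA"] == "high" and s1["pB"] == "medium"

    def test_too_few_participants_rejected(self):
        with pytest.raises(GroupingError):
            assign_groups(self.normalized(2))


class TestPairedSignedRank:
    def test_all_positive_differences(self):
        res = paired_signed_rank([2, 3, 4], [1, 1, 1])
        assert res.r_rank_biserial == 1.0

    def test_hand_ranked_example(self):
        # diffs (3, -1, 2): ranks of |d| are (3, 1, 2); W+ = 5, W- = 1
        res = paired_signed_rank([4, 0, 3], [1, 1, 1])
        w_pos, w_neg, _ = signed_rank_statistics(np.array([3.0, -1.0, 2.0]))
        assert (w_pos, w_neg) == (5.0, 1.0)
        assert res.r_rank_biserial == pytest.approx(4 / 6)

    def test_all_zero_differences_flagged(self):
        res = paired_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.undefined and math.isnan(res.p_signrank)

    def test_exact_p_matches_enumeration_n5(self):
        d = np.array([1.5, -0.5, 2.0, 0.7, -0.1])
        res = paired_signed_rank(d, np.zeros(5))
        p_oracle, r_oracle = brute_force_signrank(d)
        assert res.p_signrank == pytest.approx(p_oracle, abs=1e-12)
        assert res.r_rank_biserial == pytest.approx(r_oracle, abs=1e-12)

    def test_exact_p_matches_enumeration_with_ties(self):
        d = np.array([2.0, 2.0, -2.0, 1.0, 1.0, -3.0])
        res = paired_signed_rank(d, np.zeros(6))
        p_oracle, r_oracle = brute_force_signrank(d)
        assert res.p_signrank == pytest.approx(p_oracle, abs=1e-12)
        assert res.r_rank_biserial == pytest.approx(r_oracle, abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(12)
        res = paired_signed_rank(d, np.zeros(12))
        ref = sps.wilcoxon(d, zero_method="wilcox", method="exact")
        assert res.p_signrank == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal(60) + 0.4
        res = paired_signed_rank(d, np.zeros(60))
        ref = sps.wilcoxon(d, zero_method="wilcox", method="approx",
                           correction=False)
        assert res.p_signrank == pytest.approx(ref.pvalue, rel=1e-6)

    def test_rank_biserial_brute_force_short_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            d = np.round(rng.standard_normal(n), 1)
            if (d == 0).all():
                continue
            res = paired_signed_rank(d, np.zeros(n))
            p_oracle, r_oracle = brute_force_signrank(d)
            assert res.p_signrank == pytest.approx(p_oracle, abs=1e-12)
            assert res.r_rank_biserial == pytest.approx(r_oracle, abs=1e-12)


class TestMannWhitney:
    def test_complete_separation_gives_unit_effect(self):
        _, _, r = mann_whitney_rb([5, 6, 7], [1, 2, 3])
        assert r == 1.0

    def test_effect_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            _, _, r = mann_whitney_rb(rng.standard_normal(8), rng.standard_normal(9))
            assert -1.0 <= r <= 1.0

    def test_antisymmetry(self):
        x = [1.0, 3.0, 5.0]
        y = [2.0, 2.5, 6.0]
        _, _, r1 = mann_whitney_rb(x, y)
        _, _, r2 = mann_whitney_rb(y, x)
        assert r1 == pytest.approx(-r2)


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_tiny_closed_form(self):
        res = welch_test([4, 6], [1, 3])
        assert res.t == pytest.approx(3 / math.sqrt(2))
        assert res.df == pytest.approx(2.0)
        assert res.cohens_d == pytest.approx(3 / math.sqrt(2))
        assert res.d_ci_low < res.cohens_d < res.d_ci_high

    def test_label_swap_negates(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(10) + 1, rng.standard_normal(12)
        a = welch_test(x, y)
        b = welch_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.cohens_d == pytest.approx(-b.cohens_d)

    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(15) + 0.5, rng.standard_normal(20)
        res = welch_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_degenerate_equal_constants_flagged(self):
        res = welch_test([2.0, 2.0], [2.0, 2.0])
        assert res.undefined


class TestEffectSizeUtilities:
    def test_r_to_d_examples(self):
        assert r_to_d(0.30) == pytest.approx(0.6290, abs=5e-4)
        assert r_to_d(0.0) == 0.0
        assert r_to_d(0.6) == pytest.approx(1.5)

    def test_r_to_d_domain(self):
        with pytest.raises(InvalidConfigError):
            r_to_d(1.0)

    @pytest.mark.parametrize(
        "d,alpha,power,tails,expected",
        [
            (0.628, 0.05, 0.80, 1, 16),
            (2.0, 0.05, 0.80, 1, 2),
            (0.628, 0.05, 0.50, 1, 7),
        ],
    )
    def test_required_n(self, d, alpha, power, tails, expected):
        assert required_n_per_group(d, alpha, power, tails) == expected

    def test_required_n_domain(self):
        with pytest.raises(InvalidConfigError):
            required_n_per_group(-0.1)


def metrics_frame(values, cumulative=True):
    """Tiny metrics table: values[(pid, sid)] = per-window list."""
    rows = []
    for (pid, sid), vals in values.items():
        for i, v in enumerate(vals):
            rows.append(dict(participant_id=pid, stimulus_id=sid,
                             window_start_s=0.0 if cumulative else 3.0 * i,
                             window_end_s=3.0 * (i + 1),
                             cumulative=cumulative, dwell_ratio=v))
    return pd.DataFrame(rows)


class TestTimecourseContrast:
    def test_permuted_labels_center_on_zero(self):
        rng = np.random.default_rng(7)
        pids = [f"p{i:02d}" for i in range(16)]
        values = {(pid, "s1"): list(rng.random(3)) for pid in pids}
        metrics = metrics_frame(values)
        effects = []
        for _ in range(200):
            perm = rng.permutation(pids)
            asn = pd.DataFrame(
                dict(participant_id=perm, stimulus_id="s1",
                     normalized_rating=np.nan,
                     group=["high"] * 8 + ["low"] * 8)
            )
            out = group_timecourse_contrast(metrics, asn)
            effects.append(out["effect_r"].mean())
        assert abs(np.mean(effects)) < 0.05

    def test_paired_design_detects_artwork_level_effect(self):
        # each participant dwells more on the artworks they rate highest
        rng = np.random.default_rng(8)
        pids = [f"p{i:02d}" for i in range(12)]
        sids = [f"s{i}" for i in range(6)]
        asn_rows, values = [], {}
        for pid in pids:
            z = rng.permutation(np.linspace(-1, 1, len(sids)))
            for sid, zz in zip(sids, z):
                asn_rows.append(dict(participant_id=pid, stimulus_id=sid,
                                     normalized_rating=zz, group="medium"))
                boost = 0.10 if zz > 0.3 else 0.0
                values[(pid, sid)] = list(0.2 + boost + 0.01 * rng.random(3))
        metrics = metrics_frame(values)
        asn = pd.DataFrame(asn_rows)
        out = group_timecourse_contrast(metrics, asn,
                                        design="paired_per_participant")
        assert (out["effect_r"] > 0.8).all()

    def test_between_designs_agree_in_sign(self):
        rng = np.random.default_rng(9)
        pids = [f"p{i:02d}" for i in range(10)]
        values = {}
        asn_rows = []
        for i, pid in enumerate(pids):
            hi = i < 5
            for sid in ("s1", "s2"):
                values[(pid, sid)] = list((0.3 if hi else 0.1)
                                          + 0.02 * rng.random(3))
                asn_rows.append(dict(participant_id=pid, stimulus_id=sid,
                                     normalized_rating=np.nan,
                                     group="high" if hi else "low"))
        metrics = metrics_frame(values)
        asn = pd.DataFrame(asn_rows)
        pooled = group_timecourse_contrast(metrics, asn, design="between_pooled")
        per_art = group_timecourse_contrast(metrics, asn,
                                            design="between_per_artwork")
        assert (pooled["effect_r"] > 0).all()
        assert (per_art["effect_r"] > 0).all()

    def test_sparse_window_flagged_undefined(self):
        metrics = metrics_frame({("p1", "s1"): [0.1], ("p2", "s1"): [0.2]})
        asn = pd.DataFrame(
            dict(participant_id=["p1", "p2"], stimulus_id="s1",
                 normalized_rating=np.nan, group=["high", "low"])
        )
        out = group_timecourse_contrast(metrics, asn)
        assert out["undefined"].all()

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(10)
        pids = [f"p{i:02d}" for i in range(12)]
        values = {(pid, "s1"): list(rng.random(5)) for pid in pids}
        metrics = metrics_frame(values)
        asn = pd.DataFrame(
            dict(participant_id=pids, stimulus_id="s1",
                 normalized_rating=np.nan,
                 group=["high"] * 6 + ["low"] * 6)
        )
        out = group_timecourse_contrast(metrics, asn, holm=True)
        assert (out["p_holm"] >= out["p"] - 1e-12).all()

    def test_cohort_assignment_table_shape(self):
        asn = cohort_assignments({"a": "high-like", "b": "low-like"}, ["s1", "s2"])
        assert len(asn) == 4
        assert set(asn["group"]) == {"high", "low"}
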