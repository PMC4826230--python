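"""Marker statistics: AUC, t/rank-sum tests, BH adjustment, ANOVA, Venn sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirqval import (
    anova_three_group,
    auc,
    bh_adjust,
    two_group_stats,
    venn_partition,
)
from mirqval.differential import DifferentialError
from _oracles import auc_pair_counting, bh_step_up


class TestAuc:
    def test_perfect_separation(self):
        vals = [3, 4, 1, 2]
        labels = ["P", "P", "N", "N"]
        assert auc(vals, labels, positive="P") == 1.0

    def test_identical_distributions_give_half(self):
        assert auc([1, 2, 1, 2], ["P", "P", "N", "N"], "P") == 0.5

    def test_tied_pairs_count_half(self):
        # positives {1,2,3} vs others {2,3,4}: exhaustive pair count
        vals = [1, 2, 3, 2, 3, 4]
        labels = ["P"] * 3 + ["N"] * 3
        expect = auc_pair_counting([1, 2, 3], [2, 3, 4])
        assert auc(vals, labels, "P") == pytest.approx(expect)

    def test_matches_pair_counting_oracle_on_random_toys(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(1, 12, size=2)
            pos = rng.integers(0, 6, size=n1).astype(float)
            neg = rng.integers(0, 6, size=n2).astype(float)
            vals = np.concatenate([pos, neg])
            labels = np.array(["P"] * n1 + ["N"] * n2)
            assert auc(vals, labels, "P") == pytest.approx(
                auc_pair_counting(pos, neg), abs=1e-12
            )

    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_complementary_orientations_sum_to_one(self, pos, neg):
        vals = np.array(pos + neg, dtype=float)
        labels = np.array(["A"] * len(pos) + ["B"] * len(neg))
        assert auc(vals, labels, "A") + auc(vals, labels, "B") == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(DifferentialError):
            auc([1, 2], ["P", "P"], "P")


class TestBhAdjust:
    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(DifferentialError):
            bh_adjust([0.1, 1.5])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            m = rng.integers(1, 50)
            p = rng.random(m)
            assert np.allclose(bh_adjust(p), bh_step_up(p), atol=1e-12)

    def test_monotone_in_sorted_order_and_bounded(self, rng):
        p = rng.random(40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1).all() and (q >= p - 1e-15).all()


def delta_frame(data: dict, samples) -> pd.DataFrame:
    return pd.DataFrame(data, index=samples).T


class TestTwoGroupStats:
    def groups(self, labels, samples):
        return pd.Series(labels, index=samples)

    def test_flat_assay_has_null_statistics(self):
        samples = [f"s{i}" for i in range(8)]
        df = delta_frame({"flat": np.ones(8), "vary": np.arange(8.0)}, samples)
        g = self.groups(["A"] * 4 + ["B"] * 4, samples)
        ms = two_group_stats(df, g, ("A", "B"))
        assert ms.table.loc["flat", "p_t"] == pytest.approx(1.0)
        assert ms.table.loc["flat", "auc"] == 0.5
        assert ms.table.loc["flat", "direction"] == "none"

    def test_direction_follows_auc_orientation(self):
        samples = [f"s{i}" for i in range(8)]
        # lower delta-Ct in A = higher expression in A = up_in_A, auc < 0.5
        df = delta_frame({"up_a": [1, 1, 1, 1, 5, 5, 5, 5.0]}, samples)
        g = self.groups(["A"] * 4 + ["B"] * 4, samples)
        ms = two_group_stats(df, g, ("A", "B"))
        assert ms.table.loc["up_a", "auc"] == 0.0
        assert ms.table.loc["up_a", "direction"] == "up_in_A"

    def test_joint_relabeling_leaves_statistics_unchanged(self, rng):
        samples = [f"s{i}" for i in range(12)]
        df = delta_frame({f"a{j}": rng.normal(0, 1, 12) for j in range(5)}, samples)
        labels = ["A"] * 7 + ["B"] * 5
        g = self.groups(labels, samples)
        perm = rng.permutation(12)
        df2 = df.iloc[:, perm]
        g2 = g.iloc[perm]
        t1 = two_group_stats(df, g, ("A", "B")).table
        t2 = two_group_stats(df2, g2, ("A", "B")).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_q_dominates_base_p(self, small_curated, small_groups):
        from mirqval import delta_ct

        ref = small_curated.values.index[-1]
        delta = delta_ct(small_curated, ref)
        ms = two_group_stats(delta, small_groups, ("NSCLC", "control"))
        assert (ms.table["q"] >= ms.table["p_t"] - 1e-15).all()
        assert ms.table["auc"].between(0, 1).all()

    def test_planted_effect_detected_with_high_power(self):
        """A 2-cycle shift at n=40/20 and unit noise is essentially always
        detected at p < 1e-4 (power check over 100 seeds; the expected Welch
        t is about 7.3, so 1e-4 is cleared with wide margin)."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(60)]
            a = np.concatenate([r.normal(2.0, 1.0, 40), r.normal(0.0, 1.0, 20)])
            df = delta_frame({"m": a}, samples)
            g = self.groups(["A"] * 40 + ["B"] * 20, samples)
            ms = two_group_stats(df, g, ("A", "B"))
            if ms.table.loc["m", "p_t"] < 1e-4:
                hits += 1
        assert hits >= 95

    def test_absent_contrast_group_rejected(self):
        samples = ["s0", "s1", "s2", "s3"]
        df = delta_frame({"a": [1.0, 2, 3, 4]}, samples)
        g = self.groups(["A", "A", "B", "B"], samples)
        with pytest.raises(DifferentialError):
            two_group_stats(df, g, ("A", "C"))


class TestAnova:
    def test_identical_groups_give_null(self):
        samples = [f"s{i}" for i in range(9)]
        df = delta_frame({"a": np.tile([1.0, 2.0, 3.0], 3)}, samples)
        g = pd.Series(["A", "A", "A", "B", "B", "B", "C", "C", "C"], index=samples)
        res = anova_three_group(df, g)
        assert res.loc["a", "p"] > 0.99

    def test_shifted_group_detected_and_named(self, rng):
        samples = [f"s{i}" for i in range(30)]
        vals = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(5, 1, 10)]
        )
        df = delta_frame({"a": vals}, samples)
        g = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=samples)
        res = anova_three_group(df, g)
        assert res.loc["a", "p"] < 1e-4
        assert res.loc["a", "top_group"] == "C"

    def test_matches_statsmodels_ols_anova(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        samples = [f"s{i}" for i in range(21)]
        vals = rng.normal(0, 1, 21) + np.repeat([0.0, 0.5, 1.0], 7)
        df = delta_frame({"a": vals}, samples)
        g = pd.Series(np.repeat(["A", "B", "C"], 7), index=samples)
        res = anova_three_group(df, g)
        fit = ols("y ~ C(g)", data=pd.DataFrame({"y": vals, "g": g.to_numpy()})).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        assert res.loc["a", "p"] == pytest.approx(table["PR(>F)"].iloc[0], rel=1e-10)
        assert res.loc["a", "F"] == pytest.approx(table["F"].iloc[0], rel=1e-10)

    def test_two_groups_rejected(self):
        samples = ["s0", "s1", "s2", "s3"]
        df = delta_frame({"a": [1.0, 2, 3, 4]}, samples)
        g = pd.Series(["A", "A", "B", "B"], index=samples)
        with pytest.raises(DifferentialError):
            anova_three_group(df, g)


def stats_table(assays, pvals, aucs, contrast):
    a, b = contrast
    from mirqval.differential import MarkerStatsTable

    direction = np.where(np.asarray(aucs) < 0.5, f"up_in_{a}", f"down_in_{a}")
    df = pd.DataFrame(
        {"p_t": pvals, "p_w": pvals, "q": pvals, "auc": aucs, "direction": direction},
        index=assays,
    )
    return MarkerStatsTable(table=df, contrast=contrast)


class TestVennPartition:
    def test_disjoint_significant_sets_have_empty_cross_overlaps(self):
        sa = stats_table(["m1", "m2", "m3"], [0.01, 0.01, 0.9], [0.2, 0.8, 0.5], ("A", "B"))
        sb = stats_table(["m1", "m2", "m3"], [0.9, 0.9, 0.01], [0.5, 0.5, 0.9], ("A", "C"))
        venn = venn_partition(sa, sb, alpha=0.05, use_adjusted=False)
        for (la, lb), members in venn.overlaps.items():
            if ("A_vs_B" in la) != ("A_vs_B" in lb):
                assert members == set()

    def test_identical_tables_overlap_completely(self):
        sa = stats_table(["m1", "m2"], [0.01, 0.01], [0.2, 0.2], ("A", "B"))
        sb = stats_table(["m1", "m2"], [0.01, 0.01], [0.2, 0.2], ("A", "C"))
        venn = venn_partition(sa, sb, alpha=0.05, use_adjusted=False)
        assert venn.overlaps[("up_A_vs_B", "up_A_vs_C")] == {"m1", "m2"}

    def test_discordant_direction_overlap_reported(self):
        # up against B, down against C: the cross-direction cell is populated
        sa = stats_table(["m"], [0.01], [0.2], ("A", "B"))
        sb = stats_table(["m"], [0.01], [0.8], ("A", "C"))
        venn = venn_partition(sa, sb, alpha=0.05, use_adjusted=False)
        assert venn.overlaps[("up_A_vs_B", "down_A_vs_C")] == {"m"}

    def test_counts_match_set_algebra_oracle(self, rng):
        assays = [f"m{i}" for i in range(40)]
        pa, pb = rng.random(40), rng.random(40)
        aa, ab = rng.random(40), rng.random(40)
        sa = stats_table(assays, pa, aa, ("A", "B"))
        sb = stats_table(assays, pb, ab, ("A", "C"))
        venn = venn_partition(sa, sb, alpha=0.3, use_adjusted=False)
        up_a = {m for m, p, v in zip(assays, pa, aa) if p < 0.3 and v < 0.5}
        down_b = {m for m, p, v in zip(assays, pb, ab) if p < 0.3 and v > 0.5}
        assert venn.sets["up_A_vs_B"] == up_a
        assert venn.overlaps[("up_A_vs_B", "down_A_vs_C")] == up_a & down_b
        for k, members in venn.overlaps.items():
            assert len(members) <= min(len(venn.sets[k[0]]), len(venn.sets[k[1]]))
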