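"""Screening-vs-validation agreement: matching, direction, correlation, subsets."""

import numpy as np
import pandas as pd
import pytest

from mirqval import (
    ControlProfile,
    SimulationConfig,
    auc_correlation,
    curate_matrix,
    directional_concordance,
    generate_screening_stats,
    generate_study,
    match_identifiers,
    subset_comparison,
    two_group_stats,
)
from mirqval.concordance import ConcordanceError
from _oracles import pearson_formula


def screen_frame(assays, aucs, pvals):
    return pd.DataFrame({"assay_id": assays, "auc": aucs, "p_value": pvals})


def valid_frame(assays, aucs, pvals=None):
    df = pd.DataFrame({"auc": aucs}, index=assays)
    if pvals is not None:
        df["p_t"] = pvals
    return df


class TestMatchIdentifiers:
    def test_identity_sets_all_match(self):
        screen = screen_frame(["a", "b"], [0.6, 0.4], [0.01, 0.02])
        matched, unmatched = match_identifiers(screen, ["a", "b"])
        assert len(matched) == 2 and unmatched == []

    def test_mapping_renames_old_identifier(self):
        screen = screen_frame(["mir-X"], [0.7], [0.01])
        matched, unmatched = match_identifiers(
            screen, ["mir-X-5p"], mapping={"mir-X": "mir-X-5p"}
        )
        assert matched["assay_id"].tolist() == ["mir-X-5p"]
        assert unmatched == []

    def test_unmatched_ids_are_counted_not_dropped_silently(self):
        screen = screen_frame(["a", "b", "c"], [0.6, 0.4, 0.7], [0.01] * 3)
        matched, unmatched = match_identifiers(
            screen, ["A1", "B1"], mapping={"a": "A1", "b": "B1"}
        )
        assert len(matched) == 2
        assert unmatched == ["c"]

    def test_many_to_one_requires_flag(self):
        screen = screen_frame(["a", "b"], [0.6, 0.7], [0.01, 0.01])
        mapping = {"a": "X", "b": "X"}
        with pytest.raises(ConcordanceError):
            match_identifiers(screen, ["X"], mapping=mapping)
        matched, _ = match_identifiers(
            screen, ["X"], mapping=mapping, allow_many_to_one=True
        )
        assert len(matched) == 1


class TestDirectionalConcordance:
    def worked_example(self, n_sig, n_conc, n_total=128):
        """Screening/validation AUC tables realising given printed counts."""
        assays = [f"m{i}" for i in range(n_total)]
        s_auc = np.full(n_total, 0.7)
        s_p = np.where(np.arange(n_total) < n_sig, 0.01, 0.5)
        v_auc = np.where(np.arange(n_total) < n_conc, 0.7, 0.3)
        return screen_frame(assays, s_auc, s_p), valid_frame(assays, v_auc)

    def test_printed_counts_reproduce_percentages(self):
        screen, valid = self.worked_example(62, 56)
        rep = directional_concordance(screen, valid)
        assert rep.n_significant == 62 and rep.n_concordant == 56
        assert round(rep.percent_concordant, 1) == 90.3

        screen, valid = self.worked_example(46, 33)
        rep = directional_concordance(screen, valid)
        assert round(rep.percent_concordant, 1) == 71.7

    def test_full_agreement_closed_form_binomial(self):
        n = 10
        screen, valid = self.worked_example(n, n, n_total=n)
        rep = directional_concordance(screen, valid)
        assert rep.percent_concordant == 100.0
        assert rep.binomial_p == pytest.approx(min(2 * 0.5**n, 1.0))

    def test_half_concordant_maximises_binomial_p(self):
        ps = []
        for k in range(0, 21):
            screen, valid = self.worked_example(20, k, n_total=20)
            ps.append(directional_concordance(screen, valid).binomial_p)
        assert np.argmax(ps) == 10

    def test_undirected_aucs_excluded_and_logged(self):
        screen = screen_frame(["a", "b", "c"], [0.5, 0.7, 0.3], [0.01] * 3)
        valid = valid_frame(["a", "b", "c"], [0.6, 0.6, 0.2])
        rep = directional_concordance(screen, valid)
        assert rep.n_indeterminate == 1
        assert rep.n_significant == 2 and rep.n_concordant == 2

    def test_zero_significant_flagged_undefined(self):
        screen = screen_frame(["a"], [0.7], [0.9])
        valid = valid_frame(["a"], [0.7])
        rep = directional_concordance(screen, valid)
        assert rep.undefined and np.isnan(rep.percent_concordant)

    def test_percent_invariant_under_monotone_auc_transform(self):
        rng = np.random.default_rng(3)
        assays = [f"m{i}" for i in range(50)]
        s_auc = rng.uniform(0.1, 0.9, 50)
        v_auc = rng.uniform(0.1, 0.9, 50)
        screen = screen_frame(assays, s_auc, np.full(50, 0.01))
        base = directional_concordance(screen, valid_frame(assays, v_auc))

        def squash(a):  # strictly monotone, fixes 0.5
            return 0.5 + 0.5 * np.tanh(2 * (a - 0.5))

        rep2 = directional_concordance(
            screen_frame(assays, squash(s_auc), np.full(50, 0.01)),
            valid_frame(assays, squash(v_auc)),
        )
        assert rep2.percent_concordant == base.percent_concordant

    def test_discordant_markers_listed(self):
        screen = screen_frame(["a", "b"], [0.7, 0.7], [0.01, 0.01])
        valid = valid_frame(["a", "b"], [0.8, 0.2])
        rep = directional_concordance(screen, valid)
        assert list(rep.discordant.index) == ["b"]

    def test_planted_markers_fully_concordant_with_noiseless_screening(
        self, small_study, small_curated, small_groups
    ):
        from mirqval import delta_ct, expressed_panel

        wells, _, truth = small_study
        screen = generate_screening_stats(truth, noise_sd=0.0, seed=2)
        delta = delta_ct(small_curated, "RNU48")
        panel = expressed_panel(small_curated, ("RNU48", "RNU44", "RNU6B", "RNU24", "RPL21"))
        ms = two_group_stats(delta.values.loc[panel], small_groups, ("NSCLC", "control"))
        planted = [a for a in truth.planted_assays(("NSCLC", "control")) if a in panel]
        rep = directional_concordance(
            screen[screen["assay_id"].isin(planted)], ms
        )
        assert rep.percent_concordant == 100.0


class TestAucCorrelation:
    def test_identity_and_reflection(self):
        a = [0.1, 0.4, 0.6, 0.9]
        assert auc_correlation(a, a)[0] == pytest.approx(1.0)
        assert auc_correlation(a, [1 - x for x in a])[0] == pytest.approx(-1.0)

    def test_five_pair_hand_oracle(self):
        x = [0.1, 0.3, 0.5, 0.7, 0.9]
        y = [0.2, 0.3, 0.4, 0.8, 0.7]
        r, p = auc_correlation(x, y)
        assert r == pytest.approx(pearson_formula(x, y), abs=1e-12)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ConcordanceError):
            auc_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


def kit_study(seed, n_assays=25, effect=2.0, biological_sd=1.0, n_nsclc=14, n_control=10):
    cfg = SimulationConfig(
        n_per_group={"NSCLC": n_nsclc, "control": n_control},
        n_assays=n_assays,
        n_planted=5,
        effect_size=effect,
        biological_sd=biological_sd,
        control_profiles=(ControlProfile("RNU48", 8.0, 1.2),),
        dropout_base=0.0,
        target_ct_range=(10.0, 20.0),
        seed=seed,
    )
    wells, ann, truth = generate_study(cfg)
    curated = curate_matrix(wells)
    groups = ann.set_index("sample_id")["group"]
    return curated, groups, ann, truth


class TestSubsetComparison:
    def test_identical_subsets_correlate_perfectly(self):
        curated, groups, _, _ = kit_study(1)
        res = subset_comparison(curated, curated, groups, groups, ("NSCLC", "control"))
        assert res.ct_r == pytest.approx(1.0)
        assert res.auc_r == pytest.approx(1.0)

    def test_missing_contrast_group_skips_auc_with_warning(self):
        curated, groups, _, _ = kit_study(2)
        only_nsclc = groups[groups == "NSCLC"]
        sub = curated.values[only_nsclc.index]
        res = subset_comparison(curated, sub, groups, only_nsclc, ("NSCLC", "control"))
        assert res.auc_r is None and res.warning is not None
        assert np.isfinite(res.ct_r)

    @staticmethod
    def split_by_kit(curated, groups, ann):
        pax = ann.loc[ann["kit"] == "PAXgene", "sample_id"]
        mrn = ann.loc[ann["kit"] == "miRNeasy", "sample_id"]
        return (
            curated.values[list(pax)], groups[list(pax)],
            curated.values[list(mrn)], groups[list(mrn)],
        )

    def test_shared_truth_correlations_increase_as_noise_falls(self):
        """Two extraction-kit subsets of one study agree more as the
        biological noise shrinks (both mean-Ct and AUC correlations)."""
        mean_r = {}
        for noise in (3.0, 1.0, 0.25):
            rs = []
            for seed in range(6):
                curated, groups, ann, _ = kit_study(
                    100 + seed, biological_sd=noise, n_nsclc=24, n_control=16
                )
                da, ga, db, gb = self.split_by_kit(curated, groups, ann)
                res = subset_comparison(da, db, ga, gb, ("NSCLC", "control"))
                rs.append((res.ct_r, res.auc_r))
            mean_r[noise] = np.mean(rs, axis=0)
        assert mean_r[3.0][0] < mean_r[1.0][0] < mean_r[0.25][0]
        assert mean_r[3.0][1] < mean_r[0.25][1]

    def test_unrelated_truths_have_near_zero_correlations(self):
        """Subsets simulated from independent truths (different planted sets
        and baselines) show no systematic agreement."""
        rs = []
        for seed in range(40):
            ca, ga, _, _ = kit_study(300 + seed, effect=1.5)
            cb, gb, _, _ = kit_study(700 + seed, effect=1.5)
            # same panel names, independently drawn truths
            res = subset_comparison(ca, cb, ga, gb, ("NSCLC", "control"))
            rs.append(res.auc_r)
        mean_r = np.nanmean(rs)
        se = np.nanstd(rs) / np.sqrt(len(rs))
        assert abs(mean_r) < 4 * se + 0.05
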