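"""Generator contracts: determinism, window layout, distributional shape,
and the liability-threshold case-control model."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit.config import SimConfig
from twaskit.simulate import (ATC3_CODES, NEGATIVE_LABELS, POSITIVE_LABELS,
                              UNDIRECTED_LABEL, simulate_credible_sets,
                              simulate_drug_database,
                              simulate_expression_cohort,
                              simulate_feature_correlation,
                              simulate_gene_annotation,
                              simulate_twas_sumstats)


class TestAnnotation:
    def test_same_seed_identical(self, small_config):
        a = simulate_gene_annotation(small_config)
        b = simulate_gene_annotation(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_single_gene_has_no_window_pairs(self):
        cfg = SimConfig(n_genes=1, n_signal_genes=0, n_credible_sets=0)
        ann = simulate_gene_annotation(cfg)
        assert len(ann) == 1
        corr = simulate_feature_correlation(cfg, ann)
        # only cross-panel same-gene pairs can exist
        assert all(a.split("@")[0] == b.split("@")[0]
                   for a, b, _ in corr.pairs())

    def test_block_span_and_separation(self):
        """Exhaustive pairwise scan: within-block pairs span < window_bp,
        cross-block gene pairs are farther apart than window_bp."""
        cfg = SimConfig(n_genes=60, block_size=5, window_bp=500_000,
                        n_signal_genes=0)
        ann = simulate_gene_annotation(cfg)
        for _, sub in ann.groupby(["chrom", "block"]):
            span = sub["end"].max() - sub["start"].min()
            assert span < cfg.window_bp
        for c, sub in ann.groupby("chrom"):
            sub = sub.sort_values("start")
            rows = list(sub.itertuples())
            for i, a in enumerate(rows):
                for b in rows[i + 1:]:
                    if a.block != b.block:
                        gap = b.start - a.end
                        assert gap > cfg.window_bp


class TestTwasSumstats:
    def test_deterministic(self, small_study):
        cfg, ann, twas, truth, _ = small_study
        twas2, truth2 = simulate_twas_sumstats(cfg, ann)
        pd.testing.assert_frame_equal(twas, twas2)
        pd.testing.assert_frame_equal(truth, truth2)

    def test_p_is_exact_two_sided_tail(self, small_study):
        _, _, twas, _, _ = small_study
        expected = 2.0 * stats.norm.sf(np.abs(twas["z"]))
        np.testing.assert_allclose(twas["p"], expected, rtol=1e-12)

    def test_null_z_standard_normal(self):
        """Zero signal fraction: panel Z-scores look standard normal."""
        cfg = SimConfig(n_genes=5000, n_signal_genes=0, n_panels=1,
                        panel_strata=("blood",), seed=2)
        ann = simulate_gene_annotation(cfg)
        twas, _ = simulate_twas_sumstats(cfg, ann)
        z = twas.loc[twas["method"] == "fusion", "z"]
        assert len(z) == 5000
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_posterior_probability_constraints(self, small_study):
        _, _, twas, _, _ = small_study
        fus = twas[twas["method"] == "fusion"]
        assert (fus["pp3"] >= 0).all() and (fus["pp4"] >= 0).all()
        assert (fus["pp3"] + fus["pp4"] <= 1.0).all()

    def test_signal_genes_have_large_consistent_z(self, small_study):
        _, _, twas, truth, _ = small_study
        sig = set(truth.loc[truth["is_signal"], "gene_id"])
        sub = twas[twas["gene_id"].isin(sig) & (twas["method"] == "fusion")]
        signs = sub.groupby("gene_id")["z"].apply(
            lambda s: (np.sign(s) == np.sign(s.iloc[0])).all())
        assert signs.all()
        assert sub["z"].abs().mean() > 3


class TestFeatureCorrelation:
    def test_symmetry_and_window(self, small_study):
        cfg, ann, _, _, corr = small_study
        pos = ann.set_index("gene_id")
        for a, b, r in corr.pairs():
            assert corr.get(a, b) == corr.get(b, a) == r
            ga, gb = a.split("@")[0], b.split("@")[0]
            ra, rb = pos.loc[ga], pos.loc[gb]
            gap = max(rb["start"] - ra["end"], ra["start"] - rb["end"], 0)
            assert ra["chrom"] == rb["chrom"] and gap <= cfg.window_bp

    def test_zero_within_block_r_leaves_only_cross_panel(self):
        cfg = SimConfig(n_genes=20, within_block_r=0.0, n_signal_genes=0)
        ann = simulate_gene_annotation(cfg)
        corr = simulate_feature_correlation(cfg, ann)
        assert len(corr) > 0
        for a, b, r in corr.pairs():
            assert a.split("@")[0] == b.split("@")[0]
            assert r == cfg.cross_panel_r

    def test_blocks_positive_semidefinite(self, small_study):
        """Eigen-decomposition oracle on a reconstructed block."""
        cfg, ann, _, _, corr = small_study
        sub = ann[ann["block"] == 0]
        feats = [f"{g}@{p}" for g in sub["gene_id"] for p in cfg.panels]
        dense = np.array([[corr.get(a, b) for b in feats] for a in feats])
        assert np.linalg.eigvalsh(dense).min() >= -1e-8

    def test_rejects_non_psd_parameters(self):
        with pytest.raises(ValueError, match="semi-definite"):
            cfg = SimConfig(within_block_r=-0.5, block_size=5,
                            n_signal_genes=0)
            simulate_feature_correlation(cfg,
                                         simulate_gene_annotation(cfg))


class TestExpressionCohort:
    def test_deterministic(self, small_study):
        cfg, ann, _, truth, _ = small_study
        tw = dict(zip(truth.loc[truth.is_signal, "gene_id"],
                      truth.loc[truth.is_signal, "true_z"]))
        a = simulate_expression_cohort(cfg, ann, tw, 0)
        b = simulate_expression_cohort(cfg, ann, tw, 0)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_pre_ascertainment_case_fraction_matches_prevalence(self):
        """Binomial check of the liability-threshold model: the fraction of
        cases in the (unascertained) sampling pool is K."""
        cfg = SimConfig(n_genes=50, n_signal_genes=5, n_cases=170,
                        n_controls=170, target_liability_r2=0.05, seed=3)
        ann = simulate_gene_annotation(cfg)
        _, truth = simulate_twas_sumstats(cfg, ann)
        tw = dict(zip(truth.loc[truth.is_signal, "gene_id"],
                      truth.loc[truth.is_signal, "true_z"]))
        cohort = simulate_expression_cohort(cfg, ann, tw, 0)
        n, k = cohort.meta["n_pool"], cohort.meta["n_pool_cases"]
        assert n >= 50_000
        ci = stats.binomtest(k, n, cfg.prevalence_K).proportion_ci(0.999)
        assert ci.low <= cfg.prevalence_K <= ci.high

    def test_null_target_r2_gives_null_association(self):
        """target_liability_r2 = 0: the true score does not separate cases
        from controls beyond chance."""
        diffs = []
        for seed in range(20):
            cfg = SimConfig(n_genes=40, n_signal_genes=4, n_cases=100,
                            n_controls=100, target_liability_r2=0.0,
                            seed=100 + seed)
            ann = simulate_gene_annotation(cfg)
            _, truth = simulate_twas_sumstats(cfg, ann)
            tw = dict(zip(truth.loc[truth.is_signal, "gene_id"],
                          truth.loc[truth.is_signal, "true_z"]))
            cohort = simulate_expression_cohort(cfg, ann, tw, 0)
            s = cohort.meta["true_score"]
            case = cohort.phenotypes["case"].to_numpy()
            sd = s.std()
            diffs.append((s[case == 1].mean() - s[case == 0].mean()) / sd)
        assert abs(np.mean(diffs)) < 0.05

    def test_platform_dropout_disjoint(self, small_config):
        cfg = small_config.replace(target_liability_r2=0.0)
        ann = simulate_gene_annotation(cfg)
        cohorts = [simulate_expression_cohort(cfg, ann, {}, p)
                   for p in range(cfg.n_platforms)]
        sets = [set(c.expression.index) for c in cohorts]
        dropped = [set(ann["gene_id"]) - s for s in sets]
        assert all(len(d) == round(cfg.platform_dropout * cfg.n_genes)
                   for d in dropped)
        assert not (dropped[0] & dropped[1])

    def test_clinical_phenotypes_case_only(self, small_study):
        cfg, ann, _, truth, _ = small_study
        tw = dict(zip(truth.loc[truth.is_signal, "gene_id"],
                      truth.loc[truth.is_signal, "true_z"]))
        ph = simulate_expression_cohort(cfg, ann, tw, 0).phenotypes
        cases = ph[ph["case"] == 1]
        controls = ph[ph["case"] == 0]
        for col in ("onset_site", "onset_age", "survival"):
            assert cases[col].notna().all()
            assert controls[col].isna().all()
        assert set(cases["onset_site"].unique()) <= {0.0, 1.0}


class TestCredibleSets:
    def test_contained_sets_inside_signal_genes(self, small_study):
        cfg, ann, _, truth, _ = small_study
        credsets, contained = simulate_credible_sets(cfg, ann, truth)
        pos = ann.set_index("gene_id")
        sig = set(truth.loc[truth.is_signal, "gene_id"])
        assert len(contained) == cfg.n_credible_sets
        for g in contained:
            assert g in sig
        for locus, sub in credsets.groupby("locus_id"):
            if locus.startswith("decoy"):
                # decoys are contained in no single gene body
                inside = [
                    g for g, row in pos.iterrows()
                    if all((str(row["chrom"]) == str(c))
                           and (row["start"] <= p <= row["end"])
                           for c, p in zip(sub["chrom"], sub["pos"]))]
                assert inside == []


class TestDrugDatabase:
    def test_deterministic_and_vocabulary(self, small_study):
        cfg, _, _, truth, _ = small_study
        a, _ = simulate_drug_database(cfg, truth)
        b, _ = simulate_drug_database(cfg, truth)
        pd.testing.assert_frame_equal(a, b)
        vocab = set(NEGATIVE_LABELS) | set(POSITIVE_LABELS) | {UNDIRECTED_LABEL}
        assert set(a["label"]) <= vocab
        assert set(a["atc3"]) <= set(ATC3_CODES)
        assert a.groupby("drug_id").size().min() >= 1
        assert a["drug_id"].nunique() == cfg.n_drugs

    def test_enriched_drugs_overlap_signal_beyond_chance(self, small_study):
        """Hypergeometric oracle: planted drugs hit signal genes far more
        often than random draws would."""
        cfg, _, _, truth, _ = small_study
        inter, dtruth = simulate_drug_database(cfg, truth)
        sig = set(truth.loc[truth.is_signal, "gene_id"])
        n_genes, n_sig = len(truth), len(sig)
        for drug in dtruth["enriched_drugs"]:
            genes = set(inter.loc[inter["drug_id"] == drug, "gene_id"])
            k = len(genes & sig)
            p = stats.hypergeom.sf(k - 1, n_genes, n_sig, len(genes))
            assert p < 0.01
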