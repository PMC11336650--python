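"""PTS construction: windowed correlation, greedy clumping, weight
averaging, standardization and the weighted-sum score."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twaskit.scoring import (FeatureCorrelation, WeightSet, build_weight_set,
                             clump, compute_pts,
                             correlation_from_predicted_expression,
                             standardize_expression)


def clump_reference(features, pvals, r2, threshold):
    """Independent brute-force greedy clump (dict/list implementation)."""
    order = sorted(range(len(features)), key=lambda i: (pvals[i], features[i]))
    removed = set()
    retained = []
    for i in order:
        if features[i] in removed:
            continue
        retained.append(features[i])
        for j in order:
            fj = features[j]
            if fj in removed or fj == features[i]:
                continue
            if r2.get(frozenset((features[i], fj)), 0.0) > threshold:
                removed.add(fj)
    return retained


def _corr_from_r2(r2_map):
    entries = {}
    for pair, r2 in r2_map.items():
        a, b = sorted(pair)
        entries[(a, b)] = float(np.sqrt(r2))
    return FeatureCorrelation(entries)


class TestWindowedCorrelation:
    ANN = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"], "chrom": ["1", "1", "1"],
        "start": [100, 200_000, 900_000], "end": [1100, 201_000, 901_000]})

    def test_duplicated_feature_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        m = pd.DataFrame([x, x], index=["g1@a", "g1@b"])
        corr = correlation_from_predicted_expression(m, self.ANN)
        assert corr.get("g1@a", "g1@b") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["g1@a", "g2@a"])
        corr = correlation_from_predicted_expression(m, self.ANN)
        assert corr.get("g1@a", "g2@a") == pytest.approx(-1.0)

    def test_pairs_beyond_window_absent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(3, 8)),
                         index=["g1@a", "g2@a", "g3@a"])
        corr = correlation_from_predicted_expression(m, self.ANN,
                                                     window_bp=500_000)
        assert corr.get("g1@a", "g2@a") != 0.0  # gap ~ 199 kb
        assert corr.get("g1@a", "g3@a") == 0.0  # gap ~ 899 kb
        assert corr.get("g2@a", "g3@a") == 0.0  # gap ~ 699 kb

    def test_matches_dense_oracle(self):
        """Brute-force all-pairs Pearson restricted by window, 1e-12."""
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]
        starts = np.sort(rng.integers(1, 3_000_000, size=10))
        ann = pd.DataFrame({"gene_id": genes, "chrom": "1",
                            "start": starts, "end": starts + 1000})
        m = pd.DataFrame(rng.normal(size=(10, 20)),
                         index=[f"{g}@p" for g in genes])
        corr = correlation_from_predicted_expression(m, ann)
        dense = np.corrcoef(m.to_numpy())
        iv = ann.set_index("gene_id")
        for i in range(10):
            for j in range(i + 1, 10):
                gap = max(iv.iloc[j]["start"] - iv.iloc[i]["end"],
                          iv.iloc[i]["start"] - iv.iloc[j]["end"], 0)
                got = corr.get(f"{genes[i]}@p", f"{genes[j]}@p")
                if gap <= 500_000:
                    assert got == pytest.approx(dense[i, j], abs=1e-12)
                else:
                    assert got == 0.0

    def test_all_constant_matrix_empty(self):
        m = pd.DataFrame(np.ones((2, 5)), index=["g1@a", "g2@a"])
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_from_predicted_expression(m, self.ANN)
        assert len(corr) == 0

    def test_too_few_reference_individuals(self):
        m = pd.DataFrame(np.ones((2, 2)), index=["g1@a", "g2@a"])
        with pytest.raises(ValueError, match="3 reference"):
            correlation_from_predicted_expression(m, self.ANN)


class TestClump:
    def test_independent_features_all_retained(self):
        recs = pd.DataFrame({"feature": ["a", "b", "c"],
                             "p": [0.3, 0.1, 0.2]})
        assert set(clump(recs, FeatureCorrelation({}))) == {"a", "b", "c"}

    def test_worked_example(self):
        recs = pd.DataFrame({"feature": ["A", "B", "C"],
                             "p": [1e-8, 1e-5, 1e-4]})
        corr = _corr_from_r2({frozenset(("A", "B")): 0.5,
                              frozenset(("A", "C")): 0.0})
        assert clump(recs, corr) == ["A", "C"]

    def test_random_instances_match_reference(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(2, 9))
            feats = [f"f{i}" for i in range(n)]
            p = rng.random(n).round(3)  # rounding forces occasional p ties
            r2 = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        r2[frozenset((feats[i], feats[j]))] = \
                            float(rng.random())
            recs = pd.DataFrame({"feature": feats, "p": p})
            got = clump(recs, _corr_from_r2(r2), 0.1)
            assert got == clump_reference(feats, p, r2, 0.1)

    def test_block_structure_keeps_one_lead_per_block(self, small_study):
        cfg, _, twas, _, corr = small_study
        fus = twas[twas["method"] == "fusion"]
        fus = fus.sort_values(["p", "feature"]).drop_duplicates("feature")
        kept = clump(fus, corr, 0.1)
        # within-block r = 0.5 -> r2 = 0.25 > 0.1: exactly one feature
        # survives per annotation block
        blocks = small_study[1].set_index("gene_id")["block"]
        kept_blocks = [blocks[f.split("@")[0]] for f in kept]
        assert len(kept_blocks) == len(set(kept_blocks))
        assert len(set(kept_blocks)) == blocks.nunique()


class TestBuildWeightSet:
    def test_identity_when_nothing_filters(self):
        recs = pd.DataFrame({
            "gene_id": ["g1", "g2"], "feature": ["g1@a", "g2@a"],
            "stratum": "blood", "method": "fusion", "z": [2.0, -1.5],
            "p": [0.01, 0.2], "pp4": [0.9, 0.9]})
        ws = build_weight_set(recs, FeatureCorrelation({}), threshold=1.0)
        assert ws.weights == {"g1": 2.0, "g2": -1.5}

    def test_cross_panel_average(self):
        recs = pd.DataFrame({
            "gene_id": ["g1", "g1"], "feature": ["g1@a", "g1@b"],
            "stratum": "blood", "method": "fusion", "z": [2.0, 4.0],
            "p": [0.01, 0.02], "pp4": [0.9, 0.9]})
        ws = build_weight_set(recs, FeatureCorrelation({}), threshold=1.0)
        assert ws.weights == {"g1": 3.0}

    def test_coloc_filter_empties_set(self):
        recs = pd.DataFrame({
            "gene_id": ["g1"], "feature": ["g1@a"], "stratum": "blood",
            "method": "fusion", "z": [2.0], "p": [0.01], "pp4": [0.5]})
        ws = build_weight_set(recs, FeatureCorrelation({}), threshold=1.0,
                              coloc_only=True)
        assert ws.n_genes == 0

    def test_threshold_nesting(self, small_study):
        """Records entering the weight set at t1 < t2 are a subset."""
        _, _, twas, _, corr = small_study
        fus = twas[twas["method"] == "fusion"]
        for t1, t2 in [(1e-4, 1e-2), (1e-2, 1.0)]:
            s1 = set(fus.loc[fus["p"] <= t1, "feature"])
            s2 = set(fus.loc[fus["p"] <= t2, "feature"])
            assert s1 <= s2

    def test_nonzero_finite_weight_invariant(self):
        with pytest.raises(ValueError, match="finite and non-zero"):
            WeightSet({"g": 0.0}, threshold=1.0)


class TestStandardize:
    def test_two_sample_row(self):
        m = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["a", "b"])
        out = standardize_expression(m)
        np.testing.assert_allclose(out.loc["g"], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_row_dropped(self):
        m = pd.DataFrame([[1.0, 1.0], [0.0, 2.0]], index=["g1", "g2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize_expression(m)
        assert list(out.index) == ["g2"]

    def test_row_means_vanish(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 30)))
        out = standardize_expression(m)
        assert np.abs(out.mean(axis=1)).max() < 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            standardize_expression(pd.DataFrame([[1.0]]))


class TestComputePts:
    Z = pd.DataFrame([[1.0, -1.0], [0.5, -0.5]], index=["g1", "g2"],
                     columns=["s1", "s2"])

    def test_hand_arithmetic(self):
        ws = WeightSet({"g1": 2.0, "g2": -1.0}, threshold=1.0)
        pts = compute_pts(self.Z, ws)
        assert pts.scores["s1"] == pytest.approx(2.0 * 1.0 - 1.0 * 0.5)
        assert pts.n_genes_used == 2

    def test_empty_weight_set_scores_zero(self):
        pts = compute_pts(self.Z, WeightSet({}, threshold=1.0))
        assert (pts.scores == 0).all() and pts.n_genes_used == 0

    def test_unweighted_measured_gene_is_noop(self):
        ws = WeightSet({"g1": 2.0}, threshold=1.0)
        a = compute_pts(self.Z, ws).scores
        b = compute_pts(self.Z.drop(index="g2"), ws).scores
        pd.testing.assert_series_equal(a, b)

    def test_missing_gene_skipped_and_counted(self):
        ws = WeightSet({"g1": 2.0, "g9": 1.0}, threshold=1.0)
        pts = compute_pts(self.Z, ws)
        assert pts.n_genes_used == 1
        assert pts.scores["s1"] == pytest.approx(2.0)

    def test_ordering_invariance(self):
        ws = WeightSet({"g1": 2.0, "g2": -1.0}, threshold=1.0)
        perm = self.Z.iloc[::-1, ::-1]
        a = compute_pts(self.Z, ws).scores.sort_index()
        b = compute_pts(perm, ws).scores.sort_index()
        pd.testing.assert_series_equal(a, b)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_weights(self, factor):
        ws = WeightSet({"g1": 2.0, "g2": -1.0}, threshold=1.0)
        scaled = WeightSet({g: w * factor for g, w in ws.weights.items()},
                           threshold=1.0)
        a = compute_pts(self.Z, ws).scores
        b = compute_pts(self.Z, scaled).scores
        np.testing.assert_allclose(b, a * factor, rtol=1e-12)
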