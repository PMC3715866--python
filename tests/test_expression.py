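"""Expression concordance: robust z, IQR selection, clustering, PCA, ranking
and the Kendall rank-concordance test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, pearsonr

import linematch as lm
from linematch.io import ValidationError


def make_matrix(values, genes=None, samples=None, label="d"):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return lm.ExpressionMatrix.from_frame(
        pd.DataFrame(arr, index=genes, columns=samples), label
    )


class TestRobustZ:
    def test_direct_evaluation(self):
        em = make_matrix([[1, 2, 4]])
        z = lm.robust_z(em)
        np.testing.assert_allclose(z.values.iloc[0], [-1, 0, 2])

    def test_constant_gene_dropped(self):
        em = make_matrix([[1, 2, 4], [5, 5, 5]])
        z = lm.robust_z(em)
        assert list(z.values.index) == ["g0"]

    def test_postcondition_median_zero_mad_one(self, rng):
        em = make_matrix(rng.normal(size=(200, 15)))
        z = lm.robust_z(em)
        med = z.values.median(axis=1)
        mad = z.values.sub(med, axis=0).abs().median(axis=1)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)
        np.testing.assert_allclose(mad, 1.0, atol=1e-12)

    def test_consistency_factor_switch(self):
        em = make_matrix([[1, 2, 4]])
        z = lm.robust_z(em, consistency_factor=True)
        np.testing.assert_allclose(z.values.iloc[0], np.array([-1, 0, 2]) / 1.4826)

    def test_empty_rejected(self):
        em = make_matrix(np.zeros((0, 3)), genes=[])
        with pytest.raises(ValidationError):
            lm.robust_z(em)


class TestSelectTopIqr:
    def test_selects_largest_iqr(self):
        em = make_matrix(
            [[0, 5, 10, 15], [0, 1, 1, 2], [0, 3, 6, 9]], genes=["a", "b", "c"]
        )
        out = lm.select_top_iqr(em, 2)
        assert set(out.values.index) == {"a", "c"}

    def test_n_equal_gene_count_is_identity(self, rng):
        em = make_matrix(rng.normal(size=(20, 6)))
        out = lm.select_top_iqr(em, 20)
        assert set(out.values.index) == set(em.values.index)

    def test_n_too_large_rejected(self):
        em = make_matrix([[0, 1]])
        with pytest.raises(ValidationError, match="only 1"):
            lm.select_top_iqr(em, 2)

    def test_matches_brute_force_sort(self, rng):
        em = make_matrix(rng.normal(size=(2000, 12)))
        out = lm.select_top_iqr(em, 500)
        iqrs = {
            g: np.percentile(em.values.loc[g], 75) - np.percentile(em.values.loc[g], 25)
            for g in em.values.index
        }
        expected = sorted(iqrs, key=lambda g: (-iqrs[g], g))[:500]
        assert list(out.values.index) == expected


class TestCorrelationDistance:
    def test_duplicate_sample_distance_zero(self, rng):
        x = rng.normal(size=20)
        em = make_matrix(np.column_stack([x, x, rng.normal(size=20)]))
        d = lm.correlation_distance_matrix(em)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self, rng):
        x = rng.normal(size=20)
        em = make_matrix(np.column_stack([x, -x]))
        d = lm.correlation_distance_matrix(em)
        assert d.iloc[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_properties_and_brute_force(self, rng):
        em = make_matrix(rng.normal(size=(40, 20)))
        d = lm.correlation_distance_matrix(em)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert arr.min() >= 0.0 and arr.max() <= 2.0
        for i, j in [(0, 5), (3, 17), (10, 11)]:
            r = pearsonr(em.values.iloc[:, i], em.values.iloc[:, j])[0]
            assert arr[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_sample_named(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 1] = 2.0
        em = make_matrix(vals, samples=["a", "flatliner", "c"])
        with pytest.raises(ValidationError, match="flatliner"):
            lm.correlation_distance_matrix(em)


class TestHierarchicalCluster:
    def _dist(self, arr, labels):
        return pd.DataFrame(arr, index=labels, columns=labels)

    def test_forced_first_merge_complete_linkage(self):
        d = self._dist(
            [[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]], ["p1", "p2", "p3"]
        )
        result = lm.hierarchical_cluster(d, "complete")
        first = result.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    @pytest.mark.parametrize("method", ["ward", "complete"])
    def test_planted_groups_recovered_at_cut(self, rng, method):
        group = np.repeat([0, 1], 10)
        u, v = rng.normal(size=(50, 1)), rng.normal(size=(50, 1))
        shared = np.where(group[None, :] == 0, u, v)  # one signal per group
        x = shared + 0.2 * rng.normal(size=(50, 20))
        em = make_matrix(x)
        d = lm.correlation_distance_matrix(em)
        result = lm.hierarchical_cluster(d, method)
        labels = result.cut(2).to_numpy()
        assert len(set(labels[group == 0])) == 1
        assert len(set(labels[group == 1])) == 1
        assert labels[0] != labels[-1]

    def test_permutation_invariance_up_to_relabeling(self, rng):
        em = make_matrix(rng.normal(size=(30, 12)))
        d = lm.correlation_distance_matrix(em)
        perm = list(rng.permutation(d.index))
        d2 = d.loc[perm, perm]
        c1 = lm.hierarchical_cluster(d, "complete").cut(3)
        c2 = lm.hierarchical_cluster(d2, "complete").cut(3)
        # same partition of sample names
        p1 = {s: frozenset(c1.index[c1 == c1[s]]) for s in c1.index}
        p2 = {s: frozenset(c2.index[c2 == c2[s]]) for s in c2.index}
        assert p1 == p2

    def test_heights_monotone_and_shape(self, rng):
        em = make_matrix(rng.normal(size=(30, 15)))
        d = lm.correlation_distance_matrix(em)
        for method in ("ward", "complete"):
            result = lm.hierarchical_cluster(d, method)
            assert result.merges.shape[0] == 14
            heights = result.merges[:, 2]
            assert (np.diff(heights) >= -1e-10).all()

    def test_non_symmetric_rejected(self):
        d = pd.DataFrame([[0.0, 0.5], [0.2, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="symmetric"):
            lm.hierarchical_cluster(d, "complete")

    def test_newick_serialisation_contains_all_leaves(self, rng):
        em = make_matrix(rng.normal(size=(20, 6)))
        result = lm.hierarchical_cluster(lm.correlation_distance_matrix(em), "ward")
        nwk = result.to_newick()
        assert nwk.endswith(";")
        for s in em.values.columns:
            assert s in nwk


class TestCombineDatasets:
    def test_disjoint_gene_sets_rejected(self, rng):
        a = make_matrix(rng.normal(size=(5, 4)), genes=list("abcde"), label="A")
        b = make_matrix(rng.normal(size=(5, 4)), genes=list("fghij"),
                        samples=[f"t{i}" for i in range(4)], label="B")
        with pytest.raises(ValidationError, match="shared genes"):
            lm.combine_datasets(a, b)

    def test_identical_matrices_double_samples(self, rng):
        vals = rng.normal(size=(30, 5))
        a = make_matrix(vals, label="A")
        b = make_matrix(vals, samples=[f"t{i}" for i in range(5)], label="B")
        combined = lm.combine_datasets(a, b)
        assert combined.values.shape[1] == 10
        assert set(combined.sample_datasets) == {"A", "B"}

    def test_shared_gene_count_matches_intersection(self, rng):
        genes_a = [f"g{i}" for i in range(50)]
        genes_b = [f"g{i}" for i in range(30, 80)]
        a = make_matrix(rng.normal(size=(50, 6)), genes=genes_a, label="A")
        b = make_matrix(rng.normal(size=(50, 6)), genes=genes_b,
                        samples=[f"t{i}" for i in range(6)], label="B")
        combined = lm.combine_datasets(a, b)
        # intersection minus any MAD-0 genes (none here with continuous data)
        assert set(combined.values.index) == set(genes_a) & set(genes_b)

    def test_each_dataset_z_scored_separately(self, rng):
        vals = rng.normal(size=(40, 9))
        a = make_matrix(vals, label="A")
        b = make_matrix(vals * 100 + 7, samples=[f"t{i}" for i in range(9)], label="B")
        combined = lm.combine_datasets(a, b)
        left = combined.values[a.values.columns]
        right = combined.values[[f"t{i}" for i in range(9)]]
        np.testing.assert_allclose(left.to_numpy(), right.to_numpy(), atol=1e-9)


class TestPca:
    def test_duplicate_samples_identical_coordinates(self, rng):
        x = rng.normal(size=(30,))
        vals = np.column_stack([x, x, rng.normal(size=30), rng.normal(size=30)])
        em = make_matrix(vals)
        coords = lm.pca_embedding(em, 2).coordinates
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_rank_one_matrix_has_single_component(self, rng):
        u = rng.normal(size=30)
        f = rng.normal(size=8)
        em = make_matrix(np.outer(u, f))
        result = lm.pca_embedding(em, 2)
        assert result.explained_variance_ratio[1] <= 1e-8

    def test_planted_batch_offset_separates_on_pc1(self, rng):
        base = rng.normal(size=(60, 20))
        base[:30, 10:] += 8.0  # second batch offset on half the genes
        em = make_matrix(base)
        coords = lm.pca_embedding(em, 1).coordinates["PC1"]
        a, b = coords[:10], coords[10:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_sign_convention_deterministic(self, rng):
        em = make_matrix(rng.normal(size=(40, 10)))
        c1 = lm.pca_embedding(em, 3).coordinates
        c2 = lm.pca_embedding(em, 3).coordinates
        pd.testing.assert_frame_equal(c1, c2)

    def test_k_out_of_range_rejected(self, rng):
        em = make_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValidationError, match="out of range"):
            lm.pca_embedding(em, 5)


class TestExpressionRank:
    def test_tumour_duplicate_ranks_first(self, rng):
        tum = make_matrix(rng.normal(size=(50, 8)), label="T",
                          samples=[f"t{i}" for i in range(8)])
        cell_vals = np.column_stack(
            [tum.values.iloc[:, 0].to_numpy(), rng.normal(size=50), rng.normal(size=50)]
        )
        cells = make_matrix(cell_vals, samples=["clone", "c1", "c2"], label="C")
        ranked = lm.expression_rank(cells, tum)
        assert ranked["sample"].iloc[0] == "clone"

    def test_identical_lines_fall_to_tie_rule(self, rng):
        x = rng.normal(size=40)
        cells = make_matrix(np.column_stack([x, x, x]), samples=["b", "c", "a"], label="C")
        tum = make_matrix(rng.normal(size=(40, 5)), samples=[f"t{i}" for i in range(5)],
                          label="T")
        ranked = lm.expression_rank(cells, tum)
        assert list(ranked["sample"]) == ["a", "b", "c"]

    def test_matches_brute_force_mean_correlation(self, rng):
        cells = make_matrix(rng.normal(size=(60, 20)), label="C",
                            samples=[f"c{i}" for i in range(20)])
        tum = make_matrix(rng.normal(size=(60, 50)), label="T",
                          samples=[f"t{i}" for i in range(50)])
        ranked = lm.expression_rank(cells, tum)
        oracle = {
            c: np.mean([pearsonr(cells.values[c], tum.values[t])[0] for t in tum.values.columns])
            for c in cells.values.columns
        }
        expected = sorted(oracle, key=lambda c: (-oracle[c], c))
        assert list(ranked["sample"]) == expected
        for _, row in ranked.iterrows():
            assert row["mean_correlation"] == pytest.approx(oracle[row["sample"]], abs=1e-10)


class TestKendall:
    def test_identical_orders(self):
        r = lm.kendall_concordance(list("abcde"), list("abcde"))
        assert r.tau == pytest.approx(1.0)
        assert r.method == "exact"

    def test_reversed_orders(self):
        r = lm.kendall_concordance(list("abcde"), list("edcba"))
        assert r.tau == pytest.approx(-1.0)

    def test_item_set_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="item sets"):
            lm.kendall_concordance(list("abc"), list("abd"))

    def test_exact_p_matches_enumeration_n7(self, rng):
        items = list("abcdefg")
        for _ in range(3):
            other = list(rng.permutation(items))
            result = lm.kendall_concordance(items, other)
            assert result.method == "exact"
            # independent oracle: enumerate all 5,040 permutations with scipy's tau
            obs = kendalltau(range(7), [other.index(i) for i in items]).statistic
            count = 0
            for perm in itertools.permutations(range(7)):
                t = kendalltau(range(7), perm).statistic
                if abs(t) >= abs(obs) - 1e-12:
                    count += 1
            assert result.p_value == pytest.approx(count / 5040, abs=1e-12)

    def test_tau_matches_scipy_for_large_n(self, rng):
        items = [f"i{k}" for k in range(30)]
        other = list(rng.permutation(items))
        result = lm.kendall_concordance(items, other)
        assert result.method == "normal_approximation"
        ref = kendalltau(range(30), [other.index(i) for i in items])
        assert result.tau == pytest.approx(ref.statistic, abs=1e-12)
        assert 0 < result.p_value <= 1
        # continuity correction makes p slightly conservative vs scipy's normal
        assert result.p_value >= ref.pvalue * 0.5

    def test_tied_ranks_supported(self):
        r1 = {"a": 1, "b": 1, "c": 2, "d": 3, "e": 4, "f": 5, "g": 6, "h": 7, "i": 8, "j": 9}
        r2 = {k: v for v, k in enumerate("abcdefghij", start=1)}
        result = lm.kendall_concordance(r1, r2)
        ref = kendalltau(
            [r1[k] for k in sorted(r1)], [r2[k] for k in sorted(r2)]
        )
        assert result.tau == pytest.approx(ref.statistic, abs=1e-12)
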