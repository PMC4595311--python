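"""PCA, distances, agglomerative clustering and heat-map export."""

import io

import numpy as np
import pytest

from maldikd.exceptions import (
    ConsistencyError,
    EmptySelectionError,
    ParameterError,
)
from maldikd.multivariate import (
    distance,
    export_heatmap,
    hcluster,
    hcluster_vectors,
    pca,
    restrict_to_peaks,
)

from conftest import make_matrix
from oracles import brute_force_agglomerate


class TestPCA:
    def test_collinear_samples_have_rank_one_variance(self):
        base = np.array([1.0, 2.0, 3.0])
        values = np.outer([0.0, 1.0, 2.0, 3.0], base)
        m = make_matrix(values, mode="intensity")
        r = pca(m)
        assert r.retained_variance[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(r.retained_variance[1:], 0.0, atol=1e-9)

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, (8, 5))
        m = make_matrix(values, mode="intensity")
        r = pca(m)
        total = values.var(axis=0, ddof=1).sum()
        assert r.eigenvalues.sum() == pytest.approx(total, abs=1e-9)
        assert r.retained_variance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_by_two_block_closed_form(self):
        # covariance [[2, 1], [1, 2]] has eigenvalues 3 and 1
        x = np.array([
            [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
            [1.0, 1.0], [-1.0, -1.0],
        ])
        x = x * np.sqrt(10 / 6)  # scale so sample covariance is exactly [[2,1],[1,2]]
        cov = np.cov(x, rowvar=False)
        m = make_matrix(x, mode="intensity")
        r = pca(m)
        a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
        disc = np.sqrt(((a - c) / 2) ** 2 + b**2)
        expected = sorted([(a + c) / 2 + disc, (a + c) / 2 - disc], reverse=True)
        np.testing.assert_allclose(r.eigenvalues, expected, atol=1e-9)

    def test_scores_invariant_to_column_permutation(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, (6, 7))
        m1 = make_matrix(values, mode="intensity")
        perm = rng.permutation(7)
        m2 = make_matrix(values[:, perm], mode="intensity",
                         mz=100.0 * (np.arange(7) + 1))
        s1, s2 = pca(m1).scores, pca(m2).scores
        for k in range(3):
            assert (
                np.allclose(s1[:, k], s2[:, k], atol=1e-8)
                or np.allclose(s1[:, k], -s2[:, k], atol=1e-8)
            )

    def test_needs_three_samples(self):
        with pytest.raises(ParameterError):
            pca(make_matrix(np.ones((2, 3))))


class TestDistance:
    def test_hamming_counts_differences(self):
        assert distance([1, 0, 1], [1, 1, 1], "hamming") == 1

    def test_euclidean_three_four_five(self):
        assert distance([0, 0], [3, 4], "euclidean") == pytest.approx(5.0)

    @pytest.mark.parametrize("metric", ["euclidean", "hamming"])
    def test_identity(self, metric):
        x = np.array([1.0, 0.0, 1.0, 1.0])
        assert distance(x, x, metric) == 0.0

    def test_hamming_requires_binary(self):
        with pytest.raises(ParameterError):
            distance([0.5, 1.0], [0.0, 1.0], "hamming")


class TestHCluster:
    def test_one_dimensional_single_linkage_trace(self):
        d = hcluster_vectors(np.array([[0.0], [1.0], [10.0]]), ["a", "b", "c"],
                             "euclidean", "single")
        assert d.merges[0][0] == pytest.approx(1.0)
        assert set(d.merges[0][1]) | set(d.merges[0][2]) == {"a", "b"}
        assert d.merges[1][0] == pytest.approx(9.0)

    def test_identical_rows_merge_at_zero(self):
        d = hcluster_vectors(np.zeros((3, 2)), ["a", "b", "c"], "euclidean", "average")
        assert [h for h, _, _ in d.merges] == [0.0, 0.0]

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    @pytest.mark.parametrize("metric", ["euclidean", "hamming"])
    def test_matches_brute_force_oracle(self, metric, linkage):
        rng = np.random.default_rng(hash((metric, linkage)) % 2**31)
        for _ in range(25):
            n = int(rng.integers(2, 8))
            if metric == "hamming":
                vectors = (rng.random((n, 5)) < 0.5).astype(float)
            else:
                vectors = rng.normal(0, 1, (n, 3))
            ids = [f"l{i}" for i in range(n)]
            got = hcluster_vectors(vectors, ids, metric, linkage)
            dist = [[distance(vectors[i], vectors[j], metric) for j in range(n)]
                    for i in range(n)]
            expected = brute_force_agglomerate(dist, linkage)
            assert len(got.merges) == len(expected)
            for (h, left, right), (eh, eleft, eright) in zip(got.merges, expected):
                assert h == pytest.approx(eh, abs=1e-9)
                idx = {f"l{i}": i for i in range(n)}
                got_pair = {frozenset(idx[l] for l in left),
                            frozenset(idx[r] for r in right)}
                assert got_pair == {eleft, eright}

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_heights_non_decreasing(self, linkage):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            vectors = rng.normal(0, 1, (n, 4))
            d = hcluster_vectors(vectors, [f"l{i}" for i in range(n)],
                                 "euclidean", linkage)
            heights = [h for h, _, _ in d.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_default_metric_follows_matrix_mode(self):
        binary = make_matrix(np.eye(3))
        d = hcluster(binary, "samples")
        assert d.merges[0][0] == pytest.approx(2.0)  # hamming count

    def test_condition_recovery_on_simulated_data(self):
        """Cutting the sample dendrogram at k = #conditions recovers the
        planted condition partition exactly (ARI 1.0)."""
        from sklearn.metrics import adjusted_rand_score

        from maldikd.matching import build_consensus, intersample_match
        from maldikd.preprocess import preprocess_dataset
        from maldikd.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(seed=3, n_conditions=3, samples_per_condition=4)
        ds, _ = simulate_dataset(cfg)
        peaklists = preprocess_dataset(ds)
        consensus = [build_consensus(r, sid, tolerance=2.0, pop_threshold=50)
                     for sid, r in peaklists.items()]
        matrix = intersample_match(consensus, ds.condition_of,
                                   tolerance=2.0, unit="da")
        tree = hcluster(matrix, "samples", "hamming", "average")
        parts = tree.cut(3)
        label_of = {}
        for k, part in enumerate(parts):
            for sid in part:
                label_of[sid] = k
        pred = [label_of[s] for s in matrix.sample_ids]
        ari = adjusted_rand_score(matrix.conditions, pred)
        assert ari == pytest.approx(1.0)


class TestExportHeatmap:
    def _setup(self, tmp_path):
        values = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        m = make_matrix(values, conditions=["A", "B", "B"], mz=[100.0, 200.0])
        st = hcluster(m, "samples")
        mt = hcluster(m, "mz")
        return m, st, mt, export_heatmap(m, st, mt, tmp_path / "hm")

    def test_tsv_rows_follow_tree_leaf_order(self, tmp_path):
        m, st, mt, paths = self._setup(tmp_path)
        lines = paths["tsv"].read_text().strip().splitlines()
        header = lines[0].split("\t")
        assert header[1:] == st.leaf_order()
        assert [l.split("\t")[0] for l in lines[1:]] == mt.leaf_order()
        cells = {v for l in lines[1:] for v in l.split("\t")[1:]}
        assert cells <= {"0", "1"}

    def test_newick_roundtrip_topology(self, tmp_path):
        from skbio import TreeNode

        m, st, mt, paths = self._setup(tmp_path)
        tree = TreeNode.read(io.StringIO(paths["samples"].read_text()))
        assert {t.name for t in tree.tips()} == set(m.sample_ids)

    def test_leaf_mismatch_is_consistency_error(self, tmp_path):
        values = np.eye(2)
        m = make_matrix(values, mz=[100.0, 200.0])
        other = make_matrix(np.eye(2), sample_ids=["x", "y"], mz=[100.0, 200.0])
        st = hcluster(other, "samples")
        mt = hcluster(m, "mz")
        with pytest.raises(ConsistencyError):
            export_heatmap(m, st, mt, tmp_path / "hm")

    def test_treeview_triplet_written(self, tmp_path):
        values = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        m = make_matrix(values, conditions=["A", "B", "B"], mz=[100.0, 200.0])
        st, mt = hcluster(m, "samples"), hcluster(m, "mz")
        paths = export_heatmap(m, st, mt, tmp_path / "hm", treeview=True)
        for key in ("cdt", "gtr", "atr"):
            assert paths[key].exists()


class TestRestrictToPeaks:
    def test_exact_and_tolerant_matches(self):
        m = make_matrix(np.ones((2, 3)), mz=[100.0, 200.0, 300.0])
        r, unmatched = restrict_to_peaks(m, [200.0], tolerance=0.1)
        assert r.mz.tolist() == [200.0] and unmatched == []
        r, _ = restrict_to_peaks(m, [199.95], tolerance=0.1)
        assert r.mz.tolist() == [200.0]

    def test_unmatched_values_reported(self):
        m = make_matrix(np.ones((2, 2)), mz=[100.0, 200.0])
        r, unmatched = restrict_to_peaks(m, [100.0, 555.0], tolerance=0.1)
        assert unmatched == [555.0]

    def test_empty_selection_is_error(self):
        m = make_matrix(np.ones((2, 2)), mz=[100.0, 200.0])
        with pytest.raises(EmptySelectionError):
            restrict_to_peaks(m, [999.0], tolerance=0.1)
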