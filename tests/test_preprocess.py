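import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

import lineagescope as ls
from lineagescope.io import Dataset
from lineagescope.preprocess import EmbeddingGraph


def _toy_dataset(counts):
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = pd.DataFrame({
        "sample_id": ["s1"] * n, "condition": ["Vehicle"] * n},
        index=[f"c{i}" for i in range(n)])
    genes = pd.DataFrame(index=[f"g{i}" for i in range(g)])
    return Dataset(sp.csr_matrix(counts), cells, genes)


class TestNormalize:
    def test_arithmetic(self):
        ds = _toy_dataset([[1, 1, 2]])
        x, flag = ls.normalize_log(ds)
        np.testing.assert_allclose(
            np.asarray(x.todense())[0],
            [np.log1p(2500), np.log1p(2500), np.log1p(5000)])
        assert not flag.any()

    def test_zero_cell_flagged_not_dropped(self):
        ds = _toy_dataset([[0, 0, 0], [1, 0, 1]])
        x, flag = ls.normalize_log(ds)
        assert flag.tolist() == [True, False]
        assert np.asarray(x.todense())[0].sum() == 0

    def test_scaling_invariance(self):
        a, _ = ls.normalize_log(_toy_dataset([[1, 2, 3]]))
        b, _ = ls.normalize_log(_toy_dataset([[2, 4, 6]]))
        np.testing.assert_allclose(a.todense(), b.todense())


class TestHVG:
    def test_constant_gene_never_beats_varying(self):
        ds = _toy_dataset([[5, 1], [5, 9], [5, 5]])
        x, _ = ls.normalize_log(ds)
        flags = ls.select_hvg(x, ds.gene_ids, 1)
        assert flags.tolist() == [False, True]

    def test_all_genes_when_n_hvg_equals_n_genes(self):
        ds = _toy_dataset([[1, 2], [3, 4]])
        x, _ = ls.normalize_log(ds)
        assert ls.select_hvg(x, ds.gene_ids, 2).all()

    def test_tie_broken_lexically(self):
        x = sp.csr_matrix(np.array([[1.0, 1.0], [2.0, 2.0]]))
        flags = ls.select_hvg(x, pd.Index(["gB", "gA"]), 1)
        assert flags.tolist() == [False, True]   # gA wins the tie

    def test_too_many_requested(self):
        x = sp.csr_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            ls.select_hvg(x, pd.Index(["a", "b"]), 3)


class TestPCA:
    def test_rank_one_matrix(self):
        u = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, 0.5])
        emb = ls.compute_pca(sp.csr_matrix(u), np.ones(3, bool), 2)
        var = emb.var(axis=0, ddof=1)
        assert var[0] > 0 and var[1] == pytest.approx(0.0, abs=1e-20)

    def test_variances_non_increasing(self, rng):
        x = sp.csr_matrix(rng.normal(size=(40, 10)))
        emb = ls.compute_pca(x, np.ones(10, bool), 5)
        v = emb.var(axis=0, ddof=1)
        assert (np.diff(v) <= 1e-12).all()

    def test_reconstruction_error_is_discarded_spectrum(self, rng):
        x = rng.normal(size=(30, 8))
        c = x - x.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        emb = ls.compute_pca(sp.csr_matrix(x), np.ones(8, bool), 3)
        kept = (emb ** 2).sum()
        np.testing.assert_allclose((c ** 2).sum() - kept, (s[3:] ** 2).sum(),
                                   rtol=1e-10)

    def test_too_many_components(self):
        x = sp.csr_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError):
            ls.compute_pca(x, np.ones(2, bool), 3)


class TestKNN:
    def test_collinear_points(self):
        emb = np.array([[0.0], [1.0], [3.0]])
        g = ls.build_knn_graph(emb, 1, ["A", "B", "C"])
        assert g.neighbors.ravel().tolist() == [1, 0, 1]

    def test_neighbor_list_lengths(self, rng):
        emb = rng.normal(size=(25, 3))
        g = ls.build_knn_graph(emb, 7, [f"c{i}" for i in range(25)])
        assert g.neighbors.shape == (25, 7)
        assert (g.distances >= 0).all()
        assert not (g.neighbors == np.arange(25)[:, None]).any()

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            ls.build_knn_graph(np.zeros((3, 2)), 3, ["a", "b", "c"])

    def test_within_groups_do_not_mix(self, rng):
        emb = rng.normal(size=(30, 2))
        groups = np.array(["x"] * 15 + ["y"] * 15)
        g = ls.build_knn_graph(emb, 4, [f"c{i}" for i in range(30)],
                               within=groups)
        assert (groups[g.neighbors] == groups[:, None]).all()
        assert g.multi_component


class TestPseudotime:
    def _path_graph(self):
        emb = np.array([[0.0], [1.0], [2.0]])
        return ls.build_knn_graph(emb, 1, ["A", "B", "C"], root_cell_id="A")

    def test_path_graph_dijkstra(self):
        pt, unreachable = ls.compute_pseudotime(self._path_graph())
        np.testing.assert_allclose(pt, [0.0, 0.5, 1.0])
        assert not unreachable.any()

    def test_root_is_zero(self, preprocessed, small_dataset):
        _, _, graph, pt, _ = preprocessed
        root = graph.cell_ids.get_loc(graph.root_cell_id)
        assert pt[root] == 0.0
        finite = pt[np.isfinite(pt)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0

    def test_missing_root_raises(self):
        g = self._path_graph()
        g.root_cell_id = None
        with pytest.raises(ValueError, match="root"):
            ls.compute_pseudotime(g)
        g.root_cell_id = "Z"
        with pytest.raises(ValueError, match="Z"):
            ls.compute_pseudotime(g)

    def test_recovery_on_simulated_branching_data(self, midsize_fate_run):
        ds, pt = midsize_fate_run["ds"], midsize_fate_run["pt"]
        true = ds.cells["true_pseudotime"].to_numpy()
        rhos = []
        for cond in (ds.treated, ds.vehicle):
            m = (ds.cells["condition"] == cond).to_numpy() & np.isfinite(pt)
            rhos.append(spearmanr(pt[m], true[m])[0])
        assert min(rhos) > 0.9


def test_pipeline_determinism(small_dataset):
    a = ls.preprocess_dataset(small_dataset, 300, 20, 15)
    b = ls.preprocess_dataset(small_dataset, 300, 20, 15)
    np.testing.assert_array_equal(a[2].embedding, b[2].embedding)
    np.testing.assert_array_equal(a[3], b[3])
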