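import numpy as np
import pandas as pd
import pytest

import lineagescope as ls
from lineagescope.fate import (absorption_probabilities,
                               build_transition_matrix,
                               define_terminal_states)
from lineagescope.preprocess import EmbeddingGraph
from _oracles import monte_carlo_absorption


def _graph_from_lists(neighbors, pseudo_distances=None, embedding=None):
    neighbors = np.asarray(neighbors)
    n, k = neighbors.shape
    if embedding is None:
        embedding = np.zeros((n, 1))
    dist = (np.ones((n, k)) if pseudo_distances is None
            else np.asarray(pseudo_distances, dtype=float))
    return EmbeddingGraph(np.asarray(embedding, dtype=float), neighbors,
                          dist, pd.Index([f"c{i}" for i in range(n)]))


class TestTerminalStates:
    def _cells(self, clusters, conditions=None):
        n = len(clusters)
        return pd.DataFrame({
            "cluster": clusters,
            "condition": conditions or ["Vehicle"] * n,
            "sample_id": ["s"] * n,
        }, index=[f"c{i}" for i in range(n)])

    def test_quantile_zero_takes_whole_cluster(self):
        cells = self._cells(["erythroid"] * 6 + ["neutrophil"] * 4)
        pt = np.linspace(0, 1, 10)
        macro = define_terminal_states(cells, pt, terminal_quantile=0.0,
                                       lineages=["erythroid", "neutrophil"])
        assert len(macro["erythroid"]) == 6
        assert len(macro["neutrophil"]) == 4

    def test_top_decile_of_ten_cells_is_top_cell(self):
        cells = self._cells(["erythroid"] * 10)
        pt = np.arange(10) / 10.0
        macro = define_terminal_states(cells, pt, terminal_quantile=0.9,
                                       lineages=["erythroid"])
        assert macro["erythroid"].tolist() == [9]

    def test_macrostates_disjoint(self, midsize_fate_run):
        macro = midsize_fate_run["model"].macrostates
        all_ids = np.concatenate(list(macro.values()))
        assert len(all_ids) == len(set(all_ids))

    def test_empty_lineage_raises(self):
        cells = self._cells(["erythroid"] * 3)
        with pytest.raises(ValueError, match="neutrophil"):
            define_terminal_states(cells, np.ones(3) / 2,
                                   lineages=["neutrophil"])


class TestTransitionMatrix:
    def test_beta_zero_is_uniform(self):
        g = _graph_from_lists([[1, 2], [0, 2], [0, 1]])
        pt = np.array([0.0, 0.5, 1.0])
        model = build_transition_matrix(g, pt, 0.0, {"x": np.array([2])})
        row = model.transition[0].toarray().ravel()
        np.testing.assert_allclose(row[[1, 2]], 0.5)

    def test_softmax_arithmetic(self):
        # increments (+0.1, -0.1) at beta 10: exp(1)/(exp(1)+exp(-1))
        g = _graph_from_lists([[1, 2], [0, 2], [0, 1]])
        pt = np.array([0.5, 0.6, 0.4])
        model = build_transition_matrix(g, pt, 10.0, {"x": np.array([1])},
                                        scale=1.0)
        row = model.transition[0].toarray().ravel()
        e = np.exp(1.0)
        np.testing.assert_allclose(row[1], e / (e + 1 / e), rtol=1e-12)
        np.testing.assert_allclose(row[2], (1 / e) / (e + 1 / e), rtol=1e-12)

    def test_rows_sum_to_one(self, midsize_fate_run):
        rowsums = np.asarray(
            midsize_fate_run["model"].transition.sum(axis=1)).ravel()
        np.testing.assert_allclose(rowsums, 1.0, atol=1e-10)

    def test_negative_beta_rejected(self):
        g = _graph_from_lists([[1], [0]])
        with pytest.raises(ValueError, match="beta"):
            build_transition_matrix(g, np.array([0.0, 1.0]), -1.0, {})


class TestAbsorption:
    def _path_model(self, n=5):
        """Path graph, both ends absorbing, uniform interior walk."""
        neighbors = [[i - 1, i + 1] for i in range(1, n - 1)]
        neighbors = [[1, 2]] + neighbors + [[n - 2, n - 3]]
        g = _graph_from_lists(neighbors)
        macro = {"left": np.array([0]), "right": np.array([n - 1])}
        return build_transition_matrix(g, np.zeros(n), 0.0, macro)

    def test_gamblers_ruin_closed_form(self):
        fate = absorption_probabilities(self._path_model(5))
        # interior nodes 1..3: P(left) = 1 - i/4
        np.testing.assert_allclose(fate["left"].to_numpy()[1:4],
                                   [0.75, 0.5, 0.25], atol=1e-12)
        np.testing.assert_allclose(fate.sum(axis=1), 1.0, atol=1e-12)

    def test_terminal_cells_are_one_hot(self, midsize_fate_run):
        model, fate = midsize_fate_run["model"], midsize_fate_run["fate"]
        for lineage, idx in model.macrostates.items():
            np.testing.assert_allclose(fate.iloc[idx][lineage], 1.0)

    def test_unreachable_transient_cell_raises(self):
        # two isolated pairs; only one contains the terminal cell
        g = _graph_from_lists([[1], [0], [3], [2]])
        model = build_transition_matrix(g, np.array([0.0, 1.0, 0.0, 1.0]),
                                        1.0, {"x": np.array([1])})
        with pytest.raises(ValueError, match="cannot reach"):
            absorption_probabilities(model)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        emb = rng.normal(size=(30, 2))
        pt = rng.uniform(size=30)
        order = np.argsort(pt)
        g = ls.build_knn_graph(emb, 4, [f"c{i}" for i in range(30)])
        macro = {"a": order[-2:], "b": order[-4:-2]}
        model = build_transition_matrix(g, pt, 2.0, macro, scale=None)
        fate = absorption_probabilities(model)
        mc = monte_carlo_absorption(model.transition, macro,
                                    walks_per_cell=50_000,
                                    rng=np.random.default_rng(seed + 100))
        err = np.abs(fate.to_numpy() - mc).max()
        assert err < 0.01

    def test_beta_monotonicity_on_two_branch_toy(self):
        # root 0 -> hub 1 -> late tip 3 (t=1.0) or early tip 2 (t=0.55);
        # stronger directionality sends more mass to the late tip
        neighbors = [[1, 2], [2, 3], [1, 3], [1, 2]]
        g = _graph_from_lists(neighbors)
        pt = np.array([0.0, 0.5, 0.55, 1.0])
        macro = {"early": np.array([2]), "late": np.array([3])}
        vals = []
        for beta in (0.0, 2.0, 5.0):
            model = build_transition_matrix(g, pt, beta, macro, scale=1.0)
            fate = absorption_probabilities(model)
            vals.append(fate.loc["c0", "late"])
        assert vals[0] < vals[1] < vals[2]


class TestClusterComparison:
    def test_cluster_means_sum_to_one(self, midsize_fate_run):
        table = midsize_fate_run["table"]
        for col in ("mean_treated", "mean_vehicle"):
            sums = table.groupby("cluster")[col].sum().dropna()
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_injected_fate_bias_direction(self, midsize_fate_run):
        sub = midsize_fate_run["table"].set_index(["cluster", "lineage"])
        row = sub.loc[("MEP", "erythroid")]
        assert row["mean_treated"] < row["mean_vehicle"]

    def test_small_cluster_skipped(self, midsize_fate_run):
        fate, ds = midsize_fate_run["fate"], midsize_fate_run["ds"]
        table = ls.compare_fate_by_cluster(
            fate, ds.cells, ds.treated, ds.vehicle, min_cells=10**9)
        assert table["skipped"].all() and table["p"].isna().all()
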