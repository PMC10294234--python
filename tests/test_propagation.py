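"""Heat diffusion: closed-form oracles, locality, clustering, matrix comparison."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from _oracles import rwr_linear_solve
from tkiclone.errors import EmptySeedError, InputError
from tkiclone.filtering import FilterConfig, filter_and_classify
from tkiclone.propagation import (
    PropagationConfig,
    cluster,
    compare_matrices,
    propagate,
    propagate_sublines,
    score_genesets,
    seed_vector,
)


def _series(values, nodes):
    return pd.Series(values, index=nodes, dtype=float)


def test_two_node_closed_form():
    graph = nx.Graph([("A", "B")])
    f0 = _series([1.0, 0.0], ["A", "B"])
    f, iterations = propagate(f0, graph, PropagationConfig(restart=0.5, tol=1e-12))
    assert f["A"] == pytest.approx(2 / 3, abs=1e-9)
    assert f["B"] == pytest.approx(1 / 3, abs=1e-9)
    assert iterations < 200


def test_restart_dominates_at_tiny_alpha():
    graph = nx.path_graph(5)
    f0 = _series([1, 0, 0, 0, 0], list(graph.nodes))
    f, _ = propagate(f0, graph, PropagationConfig(restart=1e-9))
    assert np.abs(f - f0).max() < 1e-6


def test_iterative_matches_linear_solve_on_random_graphs():
    for seed, n, alpha in [(0, 30, 0.5), (1, 80, 0.3), (2, 200, 0.7), (3, 120, 0.5)]:
        rng = np.random.default_rng(seed)
        graph = nx.gnp_random_graph(n, 0.05, seed=seed)
        nodes = list(graph.nodes)
        raw = rng.random(n)
        f0 = _series(raw / raw.sum(), nodes)
        f, _ = propagate(f0, graph, PropagationConfig(restart=alpha, tol=1e-12))
        expected = rwr_linear_solve(graph, f0, alpha)
        assert np.abs(f.to_numpy() - expected).max() < 1e-6


def test_path_graph_scores_decrease_with_distance_from_seed():
    graph = nx.path_graph(12)
    f0 = _series([1.0] + [0.0] * 11, list(graph.nodes))
    f, _ = propagate(f0, graph, PropagationConfig(restart=0.5, tol=1e-12))
    values = f.to_numpy()
    assert np.all(np.diff(values) <= 1e-12)


def test_heat_never_crosses_components():
    graph = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
    f0 = _series([0.5, 0.5, 0, 0, 0], ["A", "B", "C", "X", "Y"])
    f, _ = propagate(f0, graph)
    assert f["X"] == 0.0 and f["Y"] == 0.0
    assert f[["A", "B", "C"]].sum() > 0


def test_propagation_is_deterministic():
    graph = nx.gnp_random_graph(50, 0.1, seed=5)
    f0 = _series(np.full(50, 1 / 50), list(graph.nodes))
    f1, _ = propagate(f0, graph)
    f2, _ = propagate(f0, graph)
    assert (f1 == f2).all()


def test_seed_vector_modes():
    graph = nx.Graph()
    graph.add_nodes_from(["A", "B", "C"])
    graph.add_edge("A", "B")

    def trio_with(genes_vafs):
        from _oracles import rows_to_trio

        rows = []
        for _gene, vaf in genes_vafs:
            rows.append({"consequence": "missense", "distance_to_exon": 0,
                         "sensitive": (1000, 0), "low": None,
                         "high": (1000, int(vaf * 1000))})
        trio = rows_to_trio(rows)
        return trio

    trio = trio_with([("A", 0.6), ("B", 0.3)])
    trajectories = filter_and_classify(trio)
    # rows_to_trio names genes G0, G1; rename graph accordingly
    g = nx.relabel_nodes(graph, {"A": "G0", "B": "G1", "C": "G2"})
    f0 = seed_vector(trajectories, "high", g, PropagationConfig(seed_weighting="binary"))
    assert f0.tolist() == [0.5, 0.5, 0.0]
    f0 = seed_vector(trajectories, "high", g, PropagationConfig(seed_weighting="vaf"))
    assert f0["G0"] == pytest.approx(2 / 3) and f0["G1"] == pytest.approx(1 / 3)
    # genes absent from the graph are dropped; none left → error
    tiny = nx.Graph()
    tiny.add_node("OTHER")
    with pytest.raises(EmptySeedError):
        seed_vector(trajectories, "high", tiny)


def test_geneset_scoring_conservation_and_locality(dataset):
    trajectories = {tid: filter_and_classify(dataset.trio_samples(tid)) for tid in dataset.trios}
    result = propagate_sublines(trajectories, dataset.graph)
    assert np.allclose(result.scores.sum(axis=0), 1.0, atol=1e-9)
    all_genes = {"ALL": set(dataset.graph.nodes)}
    raw = score_genesets(result.scores, all_genes, scale=False)
    assert np.allclose(raw.loc["ALL"], 1 / dataset.graph.number_of_nodes())
    gene = result.scores.index[0]
    singleton = score_genesets(result.scores, {"ONE": {gene}}, scale=False)
    assert np.allclose(singleton.loc["ONE"], result.scores.loc[gene])
    # community seeded from inside scores hotter than the other community
    communities = dataset.truth.communities
    sets = {
        "C1": {g for g, c in communities.items() if c == 0},
        "C2": {g for g, c in communities.items() if c == 1},
    }
    raw = score_genesets(result.scores, sets, scale=False)
    for trio_id, home in dataset.truth.trio_home_community.items():
        label = f"high{trio_id}"
        home_set, other_set = ("C1", "C2") if home == 0 else ("C2", "C1")
        assert raw.loc[home_set, label] > raw.loc[other_set, label]


def test_cluster_recovers_obvious_structure():
    rng = np.random.default_rng(3)
    base = rng.random(20)
    matrix = pd.DataFrame(
        {"a": base, "b": base + rng.normal(0, 0.01, 20), "c": rng.random(20)}
    ).T
    labels = cluster(matrix, k=2)
    assert labels["a"] == labels["b"] != labels["c"]
    single = cluster(matrix.iloc[:1])
    assert single.tolist() == [1]


def test_cluster_silhouette_automatic_k():
    rng = np.random.default_rng(8)
    a, b = rng.random(30), rng.random(30)
    rows = {f"a{i}": a + rng.normal(0, 0.02, 30) for i in range(4)}
    rows |= {f"b{i}": b + rng.normal(0, 0.02, 30) for i in range(4)}
    labels = cluster(pd.DataFrame(rows).T)
    truth = [0] * 4 + [1] * 4
    assert adjusted_rand_score(truth, labels.tolist()) == 1.0


def test_subline_clustering_recovers_planted_communities(dataset):
    trajectories = {tid: filter_and_classify(dataset.trio_samples(tid)) for tid in dataset.trios}
    result = propagate_sublines(trajectories, dataset.graph)
    geneset_scores = score_genesets(result.scores, dataset.genesets)
    labels = cluster(geneset_scores.T, k=2)
    truth = [
        dataset.truth.trio_home_community[label.removeprefix("low").removeprefix("high")]
        for label in labels.index
    ]
    assert adjusted_rand_score(truth, labels.tolist()) == 1.0


def test_compare_matrices():
    rng = np.random.default_rng(12)
    m = pd.DataFrame(rng.random((6, 8)),
                     index=[f"s{i}" for i in range(6)],
                     columns=[f"c{i}" for i in range(8)])
    per_row, median = compare_matrices(m, m)
    assert (per_row == 1.0).all() and median == 1.0
    per_row, median = compare_matrices(m, -m)
    assert (per_row == -1.0).all() and median == -1.0
    with pytest.raises(InputError):
        compare_matrices(m.iloc[:, :2], m.iloc[:, :2])
    medians = []
    for seed in range(50):
        rng2 = np.random.default_rng(seed)
        permuted = m.copy()
        permuted[:] = m.to_numpy()[:, rng2.permutation(8)]
        medians.append(compare_matrices(m, permuted)[1])
    assert abs(np.median(medians)) < 0.3
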