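"""Inference graph feature cases, ranking and top-k contracts."""

import numpy as np
import pandas as pd
import pytest

from lrgat.inference import (
    build_inference_graph,
    communication_probabilities,
    top_k,
)
from lrgat.preprocessing import ClusterProfile
from lrgat.prior_graph import NodeEmbedding, PriorGraph, position_matrix
from lrgat.spatial import SpatialMap


def _profiles(mean_rows, genes, expressed=None, sizes=None):
    K = len(mean_rows)
    mean_expr = pd.DataFrame(mean_rows, index=range(K), columns=genes)
    if expressed is None:
        expressed = {c: set(genes) for c in range(K)}
    return ClusterProfile(
        mean_expr=mean_expr,
        expressed_lr=expressed,
        tau=0.0,
        cluster_sizes=np.asarray(sizes if sizes is not None else [1] * K, float),
    )


def _prior(W_ab=1.0):
    W = np.array([[0.0, W_ab], [W_ab, 0.0]])
    return PriorGraph(nodes=("A", "B"), edges=(("A", "B"),), W=W)


def _position(value=0.0):
    emb = NodeEmbedding(
        nodes=("A", "B"),
        coords=np.array([[1.0, 0.0], [0.0, value]]),
        training_meta={},
    )
    return position_matrix(emb, ["A"], ["B"])


def test_gene_gene_entry_is_expression_product_plus_annotation():
    # overall means: A=2, B=3; annotation W=1 -> X[A][B] = 2*3 + 1 = 7
    profiles = _profiles([[2.0, 3.0]], ["A", "B"])
    graph = build_inference_graph(
        profiles, _prior(W_ab=1.0), _position(), a_source="annotation"
    )
    i, j = graph.index["A"], graph.index["B"]
    assert graph.X[i, j] == pytest.approx(7.0)
    assert graph.X[j, i] == pytest.approx(7.0)


def test_cluster_gene_entry_is_cluster_mean():
    profiles = _profiles([[0.5, 1.0], [2.0, 0.25]], ["A", "B"])
    graph = build_inference_graph(profiles, _prior(), _position(), a_source="annotation")
    assert graph.X[0, graph.index["A"]] == pytest.approx(0.5)
    assert graph.X[1, graph.index["B"]] == pytest.approx(0.25)


def test_cluster_cluster_entries_zero_without_spatial():
    profiles = _profiles([[1.0, 1.0], [1.0, 1.0]], ["A", "B"])
    graph = build_inference_graph(profiles, _prior(), _position())
    assert graph.X[0, 1] == 0.0 and graph.X[1, 0] == 0.0


def test_cluster_cluster_entries_are_min_distances_with_spatial():
    profiles = _profiles([[1.0, 1.0], [1.0, 1.0]], ["A", "B"])
    coords = pd.DataFrame(
        {"x": [0.0, 3.0], "y": [0.0, 4.0]}, index=["c0", "c1"]
    )
    labels = pd.Series([0, 1], index=["c0", "c1"])
    graph = build_inference_graph(
        profiles, _prior(), _position(), spatial=SpatialMap(coords, labels)
    )
    assert graph.X[0, 1] == pytest.approx(5.0)


def test_cluster_gene_edges_follow_expressed_sets():
    profiles = _profiles(
        [[1.0, 1.0], [1.0, 1.0]],
        ["A", "B"],
        expressed={0: {"A"}, 1: set()},
    )
    graph = build_inference_graph(profiles, _prior(), _position())
    cluster_edges = {
        (s, d) for s, d in graph.edges if graph.node_types[s] == "cluster"
    }
    assert cluster_edges == {(0, graph.index["A"])}


def test_position_value_used_for_curated_pairs():
    profiles = _profiles([[2.0, 3.0]], ["A", "B"])
    graph = build_inference_graph(
        profiles, _prior(W_ab=5.0), _position(value=1.0), a_source="position"
    )
    # position value <(1,0), (0,1)> = 0, so X = 2*3 + 0
    assert graph.X[graph.index["A"], graph.index["B"]] == pytest.approx(6.0)


# ------------------------------------------------------------- ranking

def _graph_for_ranking():
    genes = ("A", "B", "C", "D")
    profiles = _profiles([[1.0, 1.0, 1.0, 1.0]], genes)
    W = np.zeros((4, 4))
    prior = PriorGraph(nodes=genes, edges=(("A", "C"), ("B", "D")), W=W)
    emb = NodeEmbedding(nodes=genes, coords=np.eye(4)[:, :2], training_meta={})
    pos = position_matrix(emb, ["A", "B"], ["C", "D"])
    return build_inference_graph(profiles, prior, pos, a_source="annotation")


def test_ranking_covers_all_ligand_receptor_pairs():
    graph = _graph_for_ranking()
    emb = np.random.default_rng(0).normal(size=(len(graph.node_names), 2))
    res = communication_probabilities(emb, graph)
    assert len(res.ranking) == len(graph.ligands) * len(graph.receptors) == 4
    pairs = set(zip(res.ranking["ligand"], res.ranking["receptor"]))
    assert pairs == {(l, r) for l in graph.ligands for r in graph.receptors}


def test_ranking_ties_break_lexicographically():
    graph = _graph_for_ranking()
    emb = np.zeros((len(graph.node_names), 2))  # all scores identical
    res = communication_probabilities(emb, graph)
    ordered = list(zip(res.ranking["ligand"], res.ranking["receptor"]))
    assert ordered == sorted(ordered)


def test_ranking_matches_sorted_gram_matrix():
    graph = _graph_for_ranking()
    rng = np.random.default_rng(1)
    emb = rng.normal(size=(len(graph.node_names), 2))
    res = communication_probabilities(emb, graph)
    idx = graph.index
    naive = sorted(
        (
            (float(emb[idx[l]] @ emb[idx[r]]), l, r)
            for l in graph.ligands
            for r in graph.receptors
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    got = list(zip(res.ranking["score"], res.ranking["ligand"], res.ranking["receptor"]))
    for (s1, l1, r1), (s2, l2, r2) in zip(naive, got):
        assert (l1, r1) == (l2, r2)
        assert s1 == pytest.approx(s2)


def test_cluster_assignment_is_argmax_inner_product():
    graph = _graph_for_ranking()
    idx = graph.index
    emb = np.zeros((len(graph.node_names), 2))
    emb[idx["cluster_0"]] = [1.0, 0.0]
    emb[idx["A"]] = [2.0, 0.0]
    emb[idx["C"]] = [0.0, 1.0]
    res = communication_probabilities(emb, graph)
    row = res.ranking[(res.ranking.ligand == "A") & (res.ranking.receptor == "C")]
    assert row["source_cluster"].iloc[0] == 0


@pytest.mark.parametrize("k,expected", [(10, 4), (0, 0), (4, 4), (2, 2)])
def test_top_k_has_min_k_pairs_entries(k, expected):
    graph = _graph_for_ranking()
    emb = np.random.default_rng(2).normal(size=(len(graph.node_names), 2))
    res = communication_probabilities(emb, graph)
    assert len(top_k(res, k)) == expected
    if k >= 4:
        pd.testing.assert_frame_equal(top_k(res, k), res.ranking)
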