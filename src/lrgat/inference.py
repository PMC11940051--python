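"""Inference graph over clusters, ligands and receptors; ranked output.

The communication graph mixes two node types.  Every cell cluster points
to the ligand/receptor genes it expresses, and curated ligand->receptor
edges connect the gene nodes.  A nodes x nodes feature matrix ``X``
annotates every pair by case:

* gene-gene: ``Y_m * Y_n + A_{m,n}`` where ``Y`` is the overall mean
  normalised expression and ``A`` is the prior-model position value for a
  curated LR pair (or the raw co-membership annotation otherwise);
* cluster-gene: the within-cluster mean expression of the gene;
* cluster-cluster: the minimum spatial distance between the clusters when
  coordinates are available, else 0.

Initial per-node feature vectors are the node's row of ``X`` compressed
by truncated SVD and column-standardised; ``X`` is the only per-node
information the model defines, and the SVD keeps the input dimension
independent of graph size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import ClusterProfile
from .prior_graph import PositionMatrix, PriorGraph
from .spatial import SpatialMap, min_type_distance

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceGraph",
    "CommunicationResult",
    "build_inference_graph",
    "communication_probabilities",
    "top_k",
]

CLUSTER = "cluster"
GENE = "gene"


@dataclass(frozen=True)
class InferenceGraph:
    """Typed node set, directed message edges, pairwise features X."""

    node_names: tuple[str, ...]
    node_types: tuple[str, ...]  # CLUSTER or GENE per node
    edges: tuple[tuple[int, int], ...]  # directed (src, dst) node indices
    X: np.ndarray  # nodes x nodes, symmetric
    node_features: np.ndarray  # nodes x feature_dim
    ligands: tuple[str, ...]
    receptors: tuple[str, ...]
    clusters: tuple[int, ...]

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_names)}


def _reduce_rows(X: np.ndarray, dim: int) -> np.ndarray:
    """Truncated-SVD compression of the rows of a symmetric matrix.

    The rows are compressed without centring: entries of ``X`` are
    non-negative co-expression/annotation magnitudes whose zero point is
    meaningful, and centring would turn "both low" pairs into spuriously
    similar feature vectors.  A single global RMS rescaling keeps the
    optimiser well conditioned without distorting relative geometry.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(dim, len(s))
    feats = U[:, :k] * s[:k]
    if k < dim:
        feats = np.hstack([feats, np.zeros((X.shape[0], dim - k))])
    rms = np.sqrt((feats**2).mean())
    return feats / rms if rms > 0 else feats


def build_inference_graph(
    profiles: ClusterProfile,
    prior: PriorGraph,
    position: PositionMatrix,
    spatial: SpatialMap | None = None,
    feature_dim: int = 8,
    a_source: str = "position",
    exclude_edges: Sequence[tuple[str, str]] = (),
    ligands: Sequence[str] | None = None,
    receptors: Sequence[str] | None = None,
) -> InferenceGraph:
    """Assemble the cluster/ligand/receptor graph and its feature matrix.

    ``a_source`` selects what the gene-gene annotation ``A`` is for
    curated LR pairs: the prior-model position value (default) or the raw
    co-membership annotation ``W``.  ``exclude_edges`` removes specific
    LR pairs from message passing (held-out evaluation pairs), and the
    ``ligands``/``receptors`` overrides keep such pairs in the ranked
    candidate universe even when their edges are excluded.
    """
    if a_source not in ("position", "annotation"):
        raise ValueError(f"unknown a_source {a_source!r}")
    excluded = {tuple(e) for e in exclude_edges}
    lr_edges = [e for e in prior.edges if e not in excluded]
    if not lr_edges:
        raise ValueError("no ligand-receptor edges left for message passing")
    genes = prior.nodes
    K = profiles.mean_expr.shape[0]
    cluster_names = tuple(f"cluster_{c}" for c in range(K))
    node_names = cluster_names + genes
    node_types = (CLUSTER,) * K + (GENE,) * len(genes)
    idx = {n: i for i, n in enumerate(node_names)}

    gidx = prior.index
    overall = profiles.overall_mean
    Y = np.array([overall.get(g, 0.0) for g in genes])

    edge_set = set(prior.edges)
    n = len(node_names)
    X = np.zeros((n, n))
    # gene-gene block
    A = np.array(prior.W)  # default annotation for non-LR pairs
    for l, r in prior.edges:
        a_val = (
            position.value(l, r) if a_source == "position" else prior.W[gidx[l], gidx[r]]
        )
        A[gidx[l], gidx[r]] = a_val
        A[gidx[r], gidx[l]] = a_val
    X[K:, K:] = np.outer(Y, Y) + A
    # cluster-gene block
    for c in range(K):
        for g in genes:
            v = float(profiles.mean_expr.at[c, g]) if g in profiles.mean_expr.columns else 0.0
            X[c, idx[g]] = v
            X[idx[g], c] = v
    # cluster-cluster block (spatial only)
    if spatial is not None:
        for c1 in range(K):
            for c2 in range(K):
                if c1 != c2:
                    X[c1, c2] = min_type_distance(spatial, c1, c2)

    edges: list[tuple[int, int]] = []
    for c in range(K):
        expressed = profiles.expressed_lr.get(c, set())
        if not expressed:
            logger.warning("cluster %d expresses no ligand/receptor gene", c)
        for g in sorted(expressed):
            if g in idx:
                edges.append((c, idx[g]))
    for l, r in lr_edges:
        edges.append((idx[l], idx[r]))

    feats = _reduce_rows(X, feature_dim)
    ligands = tuple(sorted(ligands)) if ligands else tuple(sorted({l for l, _ in prior.edges}))
    receptors = tuple(sorted(receptors)) if receptors else tuple(sorted({r for _, r in prior.edges}))
    for s in ligands + receptors:
        if s not in idx:
            raise KeyError(f"ligand/receptor not a graph node: {s}")
    return InferenceGraph(
        node_names=node_names,
        node_types=node_types,
        edges=tuple(edges),
        X=X,
        node_features=feats,
        ligands=ligands,
        receptors=receptors,
        clusters=tuple(range(K)),
    )


@dataclass(frozen=True)
class CommunicationResult:
    """Dense LR score matrix plus the full ranked edge list.

    ``ranking`` has one row per (ligand, receptor) pair, sorted by
    descending inner-product score with lexicographic tie-breaks, and
    carries the argmax source/destination cluster for every pair.
    """

    scores: pd.DataFrame  # ligands x receptors
    ranking: pd.DataFrame  # rank, ligand, receptor, score, probability, source/dest
    embeddings: pd.DataFrame  # node embeddings (index: node name)

    def score_of(self, ligand: str, receptor: str) -> float:
        return float(self.scores.at[ligand, receptor])


def communication_probabilities(
    embeddings: np.ndarray,
    graph: InferenceGraph,
) -> CommunicationResult:
    """Rank all ligand x receptor pairs by embedding inner product.

    The communication score of a pair is the inner product of the learned
    2-D embeddings; a sigmoid-transformed ``probability`` column is added
    for readability but the ranking statistic is the raw inner product.
    Source (resp. destination) clusters are the cluster whose embedding
    has the largest inner product with the ligand (resp. receptor).
    """
    idx = graph.index
    emb = np.asarray(embeddings, float)
    if not np.isfinite(emb).all():
        raise ValueError("non-finite embeddings")
    L = emb[[idx[l] for l in graph.ligands]]
    R = emb[[idx[r] for r in graph.receptors]]
    C = emb[[idx[f"cluster_{c}"] for c in graph.clusters]]
    S = L @ R.T
    scores = pd.DataFrame(S, index=graph.ligands, columns=graph.receptors)

    src_for_ligand = {
        l: graph.clusters[int(np.argmax(C @ L[i]))] for i, l in enumerate(graph.ligands)
    }
    dst_for_receptor = {
        r: graph.clusters[int(np.argmax(C @ R[j]))] for j, r in enumerate(graph.receptors)
    }

    lig_flat = np.repeat(graph.ligands, len(graph.receptors))
    rec_flat = np.tile(graph.receptors, len(graph.ligands))
    s_flat = S.ravel()
    order = np.lexsort((rec_flat, lig_flat, -s_flat))
    ranking = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "ligand": lig_flat[order],
            "receptor": rec_flat[order],
            "score": s_flat[order],
            "probability": 1.0 / (1.0 + np.exp(-s_flat[order])),
            "source_cluster": [src_for_ligand[l] for l in lig_flat[order]],
            "dest_cluster": [dst_for_receptor[r] for r in rec_flat[order]],
        }
    ).reset_index(drop=True)
    emb_df = pd.DataFrame(emb, index=list(graph.node_names))
    return CommunicationResult(scores=scores, ranking=ranking, embeddings=emb_df)


def top_k(result: CommunicationResult, k: int = 10) -> pd.DataFrame:
    """First ``min(k, n_pairs)`` rows of the ranking (no padding)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return result.ranking.head(k).copy()
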