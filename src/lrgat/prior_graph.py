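"""Directed ligand->receptor prior graph, Node2Vec embedding, position matrix.

The prior model restricts the curated ligand->receptor interactions to
genes actually present in the dataset, annotates every node pair with the
complex/pathway co-membership count ``W[m, n] = z(m, n) + a(m, n)``, and
embeds the nodes in two dimensions with Node2Vec so that the inner
products of embeddings (the "position matrix") summarise how close a
ligand and a receptor sit in the prior interaction network.

Node2Vec is implemented here directly: second-order biased random walks
(return parameter ``p``, in-out parameter ``q``) followed by skip-gram
training with negative sampling.  Walks respect edge direction -- this
preserves the ligand->receptor semantics -- and restart from their start
node at dead ends (pure receptors have no out-edges).  Edge weights
``1 + W[m, n]`` bias walk transitions toward annotation-supported
interactions while keeping unannotated edges walkable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .prior import PriorBundle, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "PriorGraph",
    "Node2VecParams",
    "NodeEmbedding",
    "PositionMatrix",
    "build_prior_graph",
    "simulate_walks",
    "node2vec_embed",
    "position_matrix",
]


@dataclass(frozen=True)
class PriorGraph:
    """Directed LR graph over dataset genes, with pairwise annotations W."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # directed ligand -> receptor
    W: np.ndarray  # nodes x nodes, symmetric co-membership counts

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for l, r in self.edges:
            if l not in node_set or r not in node_set:
                raise ValueError(f"edge endpoint not a node: ({l}, {r})")
        if self.W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("W shape does not match node count")

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def ligands(self) -> tuple[str, ...]:
        seen = sorted({l for l, _ in self.edges})
        return tuple(seen)

    @property
    def receptors(self) -> tuple[str, ...]:
        return tuple(sorted({r for _, r in self.edges}))


@dataclass(frozen=True)
class Node2VecParams:
    dim: int = 2
    walks_per_node: int = 10
    walk_length: int = 20
    window: int = 5
    p: float = 1.0
    q: float = 1.0
    iterations: int = 100
    negative: int = 2
    # full-batch updates are averaged over the walk-pair corpus, so the
    # step size is larger than per-pair SGD conventions would suggest
    learning_rate: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class NodeEmbedding:
    nodes: tuple[str, ...]
    coords: np.ndarray  # nodes x dim
    training_meta: dict

    def vector(self, symbol: str) -> np.ndarray:
        try:
            return self.coords[self.nodes.index(normalize_symbol(symbol))]
        except ValueError as exc:
            raise KeyError(f"symbol not embedded: {symbol}") from exc


@dataclass(frozen=True)
class PositionMatrix:
    """Inner products of ligand and receptor embeddings."""

    P: pd.DataFrame  # ligands x receptors

    def value(self, ligand: str, receptor: str) -> float:
        return float(self.P.at[normalize_symbol(ligand), normalize_symbol(receptor)])


def build_prior_graph(
    data_genes: Iterable[str], bundle: PriorBundle
) -> PriorGraph:
    """Restrict bundle LR pairs to genes present in the dataset.

    Nodes are ligand/receptor symbols occurring both in ``data_genes`` and
    in at least one bundle LR pair; edges are the bundle pairs with both
    endpoints retained.  Raises if no edge survives (nothing to embed).
    """
    genes = {normalize_symbol(g) for g in data_genes}
    lr_symbols = bundle.ligands | bundle.receptors
    nodes = tuple(sorted(genes & lr_symbols))
    node_set = set(nodes)
    edges = tuple(
        sorted((l, r) for l, r in bundle.lr_pairs if l in node_set and r in node_set)
    )
    if not edges:
        raise ValueError(
            "no ligand-receptor pair from the bundle has both genes in the dataset"
        )
    # node x group membership indicators make W a pair of Gram matrices
    n = len(nodes)
    idx = {s: i for i, s in enumerate(nodes)}
    W = np.zeros((n, n))
    for groups in (bundle.complexes, bundle.pathways):
        M = np.zeros((n, len(groups)))
        for j, members in enumerate(groups.values()):
            for s in members:
                if s in idx:
                    M[idx[s], j] = 1.0
        W += M @ M.T
    return PriorGraph(nodes=nodes, edges=edges, W=W)


def _walk_structures(graph: PriorGraph):
    idx = graph.index
    n = len(graph.nodes)
    out: list[list[int]] = [[] for _ in range(n)]
    wts: list[list[float]] = [[] for _ in range(n)]
    for l, r in graph.edges:
        i, j = idx[l], idx[r]
        out[i].append(j)
        wts[i].append(1.0 + graph.W[i, j])
    edge_set = {(idx[l], idx[r]) for l, r in graph.edges}
    return out, wts, edge_set


def simulate_walks(
    graph: PriorGraph, params: Node2VecParams, rng: np.random.Generator
) -> list[list[int]]:
    """Second-order biased random walks over the directed prior graph.

    Transition weights follow the usual return/in-out biasing: from *v*
    (having arrived from *t*) the weight toward *x* is scaled by ``1/p``
    if ``x == t``, by 1 if the edge ``t -> x`` exists, else by ``1/q``.
    A node without out-neighbours sends the walk back to its start node.
    """
    out, wts, edge_set = _walk_structures(graph)
    n = len(graph.nodes)
    walks: list[list[int]] = []
    for _ in range(params.walks_per_node):
        for start in range(n):
            walk = [start]
            prev: int | None = None
            while len(walk) < params.walk_length:
                cur = walk[-1]
                if not out[cur]:
                    if cur == start and prev is None:
                        break  # isolated start: nothing to walk
                    walk.append(start)
                    prev = None
                    continue
                nbrs = out[cur]
                w = np.array(wts[cur], dtype=float)
                if prev is not None:
                    bias = np.ones(len(nbrs))
                    for k, x in enumerate(nbrs):
                        if x == prev:
                            bias[k] = 1.0 / params.p
                        elif (prev, x) not in edge_set:
                            bias[k] = 1.0 / params.q
                    w = w * bias
                probs = w / w.sum()
                nxt = nbrs[rng.choice(len(nbrs), p=probs)]
                prev = cur
                walk.append(nxt)
            if len(walk) > 1:
                walks.append(walk)
    return walks


def _skipgram_pairs(walks: list[list[int]], window: int) -> np.ndarray:
    pairs = []
    for walk in walks:
        for i, center in enumerate(walk):
            lo, hi = max(0, i - window), min(len(walk), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, walk[j]))
    return np.asarray(pairs, dtype=int)


def node2vec_embed(graph: PriorGraph, params: Node2VecParams | None = None) -> NodeEmbedding:
    """Train Node2Vec embeddings of the prior graph.

    Skip-gram with negative sampling is optimised by full-batch gradient
    descent over the walk corpus for ``params.iterations`` epochs, with
    negatives redrawn each epoch from the unigram^(3/4) distribution.
    Deterministic for a fixed seed.
    """
    params = params or Node2VecParams()
    if params.dim < 1:
        raise ValueError("dim must be >= 1")
    if not graph.edges:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(params.seed)
    n = len(graph.nodes)
    walks = simulate_walks(graph, params, rng)
    pairs = _skipgram_pairs(walks, params.window)
    centers, contexts = pairs[:, 0], pairs[:, 1]

    counts = np.bincount(contexts, minlength=n).astype(float)
    noise = counts**0.75
    noise = np.ones(n) / n if noise.sum() == 0 else noise / noise.sum()

    U = (rng.random((n, params.dim)) - 0.5) / params.dim  # in-embeddings
    V = np.zeros((n, params.dim))  # out-embeddings
    lr = params.learning_rate
    for _ in range(params.iterations):
        neg = rng.choice(n, size=(len(pairs), params.negative), p=noise)
        u = U[centers]  # pairs x dim
        # positive context
        s = 1.0 / (1.0 + np.exp(-np.sum(u * V[contexts], axis=1)))
        gU = (s - 1.0)[:, None] * V[contexts]
        gV_ctx = (s - 1.0)[:, None] * u
        # negatives
        sn = 1.0 / (1.0 + np.exp(-np.einsum("pd,pkd->pk", u, V[neg])))
        gU += np.einsum("pk,pkd->pd", sn, V[neg])
        gV_neg = sn[:, :, None] * u[:, None, :]

        dU = np.zeros_like(U)
        dV = np.zeros_like(V)
        np.add.at(dU, centers, gU)
        np.add.at(dV, contexts, gV_ctx)
        np.add.at(dV, neg.ravel(), gV_neg.reshape(-1, params.dim))
        scale = lr / len(pairs)
        U -= scale * dU
        V -= scale * dV
    if not np.isfinite(U).all():
        raise FloatingPointError("non-finite Node2Vec embeddings")
    meta = {
        "iterations": params.iterations,
        "seed": params.seed,
        "walks": len(walks),
        "pairs": int(len(pairs)),
        "walk_length": params.walk_length,
        "walks_per_node": params.walks_per_node,
        "p": params.p,
        "q": params.q,
        "window": params.window,
    }
    return NodeEmbedding(nodes=graph.nodes, coords=U, training_meta=meta)


def position_matrix(
    emb: NodeEmbedding, ligands: Sequence[str], receptors: Sequence[str]
) -> PositionMatrix:
    """Gram sub-matrix of embeddings: ``P[l, r] = <coords[l], coords[r]>``."""
    index = {s: i for i, s in enumerate(emb.nodes)}
    for s in list(ligands) + list(receptors):
        if normalize_symbol(s) not in index:
            raise KeyError(f"symbol not embedded: {s}")
    L = emb.coords[[index[normalize_symbol(s)] for s in ligands]]
    R = emb.coords[[index[normalize_symbol(s)] for s in receptors]]
    P = pd.DataFrame(L @ R.T, index=[normalize_symbol(s) for s in ligands],
                     columns=[normalize_symbol(s) for s in receptors])
    return PositionMatrix(P=P)
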