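"""Expression ingestion, normalisation, cell graph and Leiden clustering.

The clustering stage mirrors the standard single-cell recipe: per-cell
total-count scaling to a common target followed by log1p, PCA to a small
number of components, an exact symmetrised k-nearest-neighbour graph, and
Leiden community detection optimising the resolution-parameterised
configuration-model quality

    theta = (1 / 2J) * sum_c [ e_c - gamma * K_c^2 / (2J) ]

with J the total edge count, e_c the within-community adjacency sum and
K_c the community degree sum.  The quality of the returned partition is
re-evaluated directly from this formula rather than trusted from the
optimiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path


import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .prior import PriorBundle, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionData",
    "ClusterAssignment",
    "ClusterProfile",
    "CellGraph",
    "load_expression",
    "filter_expression",
    "normalize",
    "build_cell_graph",
    "partition_quality",
    "leiden_cluster",
    "cluster_profiles",
]


@dataclass
class ExpressionData:
    """A genes x cells expression matrix with optional normalised layer."""

    gene_names: list[str]
    cell_names: list[str]
    counts: np.ndarray  # genes x cells, non-negative
    norm: np.ndarray | None = None
    spatial: pd.DataFrame | None = None  # index: cell_name, columns x, y[, z]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_names), len(self.cell_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_names)} cells"
            )
        if (self.counts < 0).any():
            raise ValueError("counts contain negative entries")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names are not unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_names)


@dataclass(frozen=True)
class CellGraph:
    """Symmetric unweighted kNN adjacency plus the reduced coordinates."""

    adjacency: sp.csr_matrix  # cells x cells, 0/1, no self-loops
    coords: np.ndarray  # cells x n_pcs


@dataclass(frozen=True)
class ClusterAssignment:
    labels: np.ndarray  # cell -> cluster id in 0..K-1
    K: int
    resolution: float
    quality: float


@dataclass(frozen=True)
class ClusterProfile:
    """Per-cluster mean normalised expression and expressed-LR sets."""

    mean_expr: pd.DataFrame  # K x genes
    expressed_lr: dict[int, set[str]]
    tau: float
    cluster_sizes: np.ndarray  # cells per cluster, aligned with mean_expr rows

    @property
    def overall_mean(self) -> pd.Series:
        """Mean normalised expression across all cells (size-weighted)."""
        w = self.cluster_sizes / self.cluster_sizes.sum()
        return pd.Series(w @ self.mean_expr.to_numpy(), index=self.mean_expr.columns)


def load_expression(
    path: str | Path,
    fmt: str = "mtx_triplet",
    cells_in_rows: bool = False,
    genes_file: str = "genes.tsv",
    barcodes_file: str = "barcodes.tsv",
    spatial_path: str | Path | None = None,
) -> ExpressionData:
    """Load a genes x cells matrix from Matrix Market or dense CSV.

    ``mtx_triplet``: *path* is a directory holding ``matrix.mtx`` plus
    one-column ``genes.tsv`` / ``barcodes.tsv``.  ``dense_csv``: *path* is
    a CSV with gene names in the first column and cell names in the
    header.  Set ``cells_in_rows`` if the stored orientation is
    cells x genes.
    """
    path = Path(path)
    if fmt == "mtx_triplet":
        mtx = path / "matrix.mtx" if path.is_dir() else path
        base = mtx.parent
        counts = np.asarray(scipy.io.mmread(mtx).todense(), dtype=float)
        genes = pd.read_csv(base / genes_file, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(base / barcodes_file, sep="\t", header=None)[0].tolist()
    elif fmt == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy(dtype=float)
        genes = df.index.tolist()
        cells = df.columns.tolist()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if cells_in_rows:
        counts = counts.T
        genes, cells = cells, genes
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match {len(genes)} gene "
            f"names and {len(cells)} cell names"
        )
    genes = [normalize_symbol(g) for g in genes]
    spatial = None
    if spatial_path is not None:
        spatial = pd.read_csv(spatial_path).set_index("cell_id")
        missing = [c for c in cells if c not in spatial.index]
        if missing:
            raise ValueError(f"spatial table missing {len(missing)} cells, e.g. {missing[:3]}")
        spatial = spatial.loc[cells]
    return ExpressionData(gene_names=genes, cell_names=[str(c) for c in cells],
                          counts=counts, spatial=spatial)


def filter_expression(
    data: ExpressionData,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> ExpressionData:
    """Drop cells expressing too few genes and genes seen in too few cells."""
    cell_ok = (data.counts > 0).sum(axis=0) >= min_genes_per_cell
    gene_ok = (data.counts[:, cell_ok] > 0).sum(axis=1) >= min_cells_per_gene
    if not cell_ok.any() or not gene_ok.any():
        raise ValueError(
            f"filtering removed everything ({int(cell_ok.sum())} cells, "
            f"{int(gene_ok.sum())} genes left)"
        )
    spatial = data.spatial
    kept_cells = [c for c, ok in zip(data.cell_names, cell_ok) if ok]
    if spatial is not None:
        spatial = spatial.loc[kept_cells]
    return ExpressionData(
        gene_names=[g for g, ok in zip(data.gene_names, gene_ok) if ok],
        cell_names=kept_cells,
        counts=data.counts[np.ix_(gene_ok, cell_ok)],
        spatial=spatial,
    )


def normalize(
    data: ExpressionData, target_sum: float | None = 1e4, log: bool = True
) -> ExpressionData:
    """Scale each cell's counts to ``target_sum``, then optionally log1p.

    ``target_sum=None`` scales to the median per-cell total (the scanpy
    convention), which keeps the post-log dynamic range sensible for
    small gene panels.  All-zero cells are left as zeros (with a warning)
    rather than producing NaNs.  The raw counts layer is retained
    unchanged.
    """
    totals = data.counts.sum(axis=0)
    if target_sum is None:
        nonzero = totals[totals > 0]
        target_sum = float(np.median(nonzero)) if nonzero.size else 1.0
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero cell(s) left unnormalised", int(zero.sum()))
    scale = np.where(zero, 0.0, target_sum / np.where(zero, 1.0, totals))
    norm = data.counts * scale[np.newaxis, :]
    if log:
        norm = np.log1p(norm)
    out = replace(data)
    out.norm = norm
    return out


def build_cell_graph(
    data: ExpressionData, n_neighbors: int = 15, n_pcs: int = 30
) -> CellGraph:
    """Exact kNN graph on PCA coordinates, symmetrised by union.

    PCA is computed with the deterministic full SVD solver; the number of
    components is capped at min(genes, cells) - 1.
    """
    if data.norm is None:
        raise ValueError("normalize() must be called before build_cell_graph()")
    n_cells = data.n_cells
    if n_neighbors >= n_cells:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n_cells}")
    n_pcs = min(n_pcs, data.n_genes - 1, n_cells - 1)
    X = data.norm.T  # cells x genes
    coords = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, algorithm="brute").fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n_cells), n_neighbors)
    cols = idx[:, 1:].ravel()  # drop self (first neighbour)
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_cells, n_cells)
    )
    adj = ((adj + adj.T) > 0).astype(float)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return CellGraph(adjacency=adj.tocsr(), coords=coords)


def partition_quality(
    adjacency: sp.spmatrix, labels: np.ndarray, resolution: float
) -> float:
    """Direct evaluation of the clustering quality on a given partition.

    ``e_c`` is the within-community adjacency sum (twice the internal edge
    count of an undirected simple graph) and ``K_c`` the summed degree.
    """
    A = sp.csr_matrix(adjacency)
    two_j = A.sum()
    if two_j == 0:
        raise ValueError("graph has no edges")
    degrees = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        e_c = A[np.ix_(members, members)].sum()
        k_c = degrees[members].sum()
        q += e_c - resolution * k_c**2 / two_j
    return float(q / two_j)


def leiden_cluster(
    adjacency: sp.spmatrix, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Leiden partition of the cell graph at resolution ``gamma``.

    The stored ``quality`` is re-computed from the returned partition with
    :func:`partition_quality`, independent of the optimiser's bookkeeping.
    """
    A = sp.coo_matrix(adjacency)
    if A.shape[0] == 0 or A.nnz == 0:
        raise ValueError("empty graph")
    mask = A.row < A.col  # undirected simple graph: each edge once
    edges = list(zip(A.row[mask].tolist(), A.col[mask].tolist()))
    g = ig.Graph(n=A.shape[0], edges=edges, directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership, dtype=int)
    # relabel by first occurrence so ids are stable 0..K-1
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels], dtype=int)
    return ClusterAssignment(
        labels=labels,
        K=len(order),
        resolution=resolution,
        quality=partition_quality(adjacency, labels, resolution),
    )


def cluster_profiles(
    data: ExpressionData,
    clusters: ClusterAssignment,
    bundle: PriorBundle,
    tau: float = 0.0,
) -> ClusterProfile:
    """Within-cluster mean expression and per-cluster expressed LR genes.

    A ligand/receptor gene is "expressed" in a cluster when its mean
    normalised expression there exceeds ``tau`` (strict), so genes never
    detected in a cluster cannot enter the communication graph.
    """
    if data.norm is None:
        raise ValueError("normalize() must be called before cluster_profiles()")
    K = clusters.K
    means = np.zeros((K, data.n_genes))
    sizes = np.zeros(K)
    for c in range(K):
        members = clusters.labels == c
        sizes[c] = members.sum()
        means[c] = data.norm[:, members].mean(axis=1)
    mean_expr = pd.DataFrame(means, index=range(K), columns=data.gene_names)
    lr_genes = {g for g in data.gene_names if g in (bundle.ligands | bundle.receptors)}
    expressed = {
        c: {g for g in lr_genes if mean_expr.at[c, g] > tau} for c in range(K)
    }
    return ClusterProfile(
        mean_expr=mean_expr, expressed_lr=expressed, tau=tau, cluster_sizes=sizes
    )
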