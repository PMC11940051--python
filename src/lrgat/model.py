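"""Model/Results interface over the full communication-inference pipeline.

``CellCommunication`` is built from an expression matrix and a prior
bundle (plus optional spatial coordinates); ``fit()`` executes the whole
pipeline -- normalisation, Leiden clustering, prior graph, Node2Vec,
inference graph, GATv2 link scoring -- and returns a
``CommunicationResults`` object carrying the ranked interactions, the
validation metrics, the training diagnostics and a ``summary()`` table.

Held-out evaluation (``fit(holdout_pairs=...)``) removes the named LR
pairs from supervision, mirroring a train/validation split of the
curated interaction database; ``holdout_edges=True`` additionally strips
them from the graphs so they are scored as completely unseen candidates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import evaluation, preprocessing, prior_graph as pg
from .config import RunConfig
from .gat import TrainResult, train_link_scorer
from .inference import (
    CommunicationResult,
    InferenceGraph,
    build_inference_graph,
    communication_probabilities,
    top_k,
)
from .preprocessing import ClusterAssignment, ClusterProfile, ExpressionData
from .prior import PriorBundle, normalize_symbol
from .spatial import SpatialMap, proximity_of_topk

logger = logging.getLogger(__name__)

__all__ = ["CellCommunication", "CommunicationResults"]


@dataclass
class CommunicationResults:
    """Fitted results: ranked LR communication plus diagnostics."""

    result: CommunicationResult
    clusters: ClusterAssignment
    profiles: ClusterProfile
    prior: pg.PriorGraph
    position: pg.PositionMatrix
    graph: InferenceGraph
    labeled: evaluation.LabeledPairs
    metrics: dict
    loss_history: np.ndarray
    config: RunConfig
    seed: int
    holdout: tuple[tuple[str, str], ...]
    spatial_map: SpatialMap | None = None
    timings: dict = field(default_factory=dict)

    @property
    def ranking(self) -> pd.DataFrame:
        return self.result.ranking

    @property
    def scores(self) -> pd.DataFrame:
        return self.result.scores

    def top(self, k: int | None = None) -> pd.DataFrame:
        return top_k(self.result, self.config.k_top if k is None else k)

    def proximity(self, k: int | None = None) -> dict:
        if self.spatial_map is None:
            raise ValueError("no spatial coordinates were provided")
        return proximity_of_topk(
            self.result, self.spatial_map, self.config.k_top if k is None else k
        )

    def holdout_metrics(self, n_neg: int = 10, seed: int | None = None) -> dict:
        """Score held-out pairs against fresh shuffled negatives."""
        if not self.holdout:
            raise ValueError("model was fitted without holdout pairs")
        neg = evaluation.make_negatives(
            positives=set(self.prior.edges) | set(self.holdout),
            n_neg=n_neg,
            seed=(self.seed if seed is None else seed) + 9901,
            universe={(l, r) for l in self.graph.ligands for r in self.graph.receptors},
        )
        labeled = evaluation.split_pairs(self.holdout, neg, 0.0, seed=0)
        return evaluation.score_ranking(self.ranking, labeled, threshold=0.0)

    def summary(self) -> str:
        lines = [
            "Cell-cell communication (GATv2 link scorer)",
            "=" * 55,
            f"clusters:            {self.clusters.K} (resolution {self.clusters.resolution}, "
            f"quality {self.clusters.quality:.4f})",
            f"prior LR edges:      {len(self.prior.edges)} over {len(self.prior.nodes)} genes",
            f"candidate pairs:     {len(self.ranking)}",
            f"held-out pairs:      {len(self.holdout)}",
            f"training loss:       {self.loss_history[0]:.4f} -> {self.loss_history[-1]:.4f}"
            f" ({len(self.loss_history) - 1} epochs)",
            f"validation ACC:      {self.metrics['acc']:.3f} "
            f"(threshold {self.metrics['threshold']:.3f})",
            f"validation AUC:      {self.metrics['auc']:.3f} "
            f"({self.metrics['n_pos']} pos / {self.metrics['n_neg']} neg)",
            "",
            f"top {min(self.config.k_top, len(self.ranking))} interactions:",
            self.top().to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        self.ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        self.scores.to_csv(outdir / "scores.tsv", sep="\t")
        pd.DataFrame(
            {"cell_id": range(len(self.clusters.labels)), "cluster": self.clusters.labels}
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(self.metrics, fh, indent=2, sort_keys=True)
        with open(outdir / "config.json", "w") as fh:
            json.dump(
                {"seed": self.seed, **self.config.to_dict()},
                fh, indent=2, sort_keys=True, default=str,
            )
        pd.DataFrame({"epoch": range(len(self.loss_history)), "loss": self.loss_history}
                     ).to_csv(outdir / "loss.tsv", sep="\t", index=False)
        self.result.embeddings.to_csv(outdir / "embeddings.tsv", sep="\t")
        for name in ("ranking", "scores", "clusters", "metrics", "config", "loss",
                     "embeddings"):
            suffix = "json" if name in ("metrics", "config") else "tsv"
            paths[name] = outdir / f"{name}.{suffix}"
        return paths


class CellCommunication:
    """Ligand-receptor communication model for one scRNA-seq dataset.

    Parameters
    ----------
    data
        genes x cells counts (optionally with spatial coordinates).
    bundle
        The prior-knowledge bundle (LR pairs, PPIs, complexes, pathways).
    config
        All pipeline tunables; ``RunConfig.small()`` suits tiny inputs.
    """

    def __init__(
        self,
        data: ExpressionData,
        bundle: PriorBundle,
        config: RunConfig | None = None,
    ):
        self.data = data
        self.bundle = bundle
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        lr_path: str | Path,
        ppi_path: str | Path,
        complexes_path: str | Path,
        pathways_path: str | Path,
        fmt: str = "mtx_triplet",
        spatial_path: str | Path | None = None,
        config: RunConfig | None = None,
        cells_in_rows: bool = False,
    ) -> "CellCommunication":
        from .prior import load_prior_bundle

        data = preprocessing.load_expression(
            expression_path, fmt=fmt, cells_in_rows=cells_in_rows,
            spatial_path=spatial_path,
        )
        bundle = load_prior_bundle(lr_path, ppi_path, complexes_path, pathways_path)
        return cls(data, bundle, config)

    def fit(
        self,
        seed: int | None = None,
        holdout_pairs: Iterable[tuple[str, str]] = (),
        holdout_edges: bool = False,
    ) -> CommunicationResults:
        """Run the full pipeline and return fitted results.

        ``holdout_pairs`` are excluded from the supervision (they are
        neither positives nor allowed as sampled negatives), mirroring a
        train/validation split of the curated interaction database.
        With ``holdout_edges=True`` they are additionally removed from
        the prior graph and from message passing, the strict
        link-prediction protocol in which held-out pairs are completely
        unseen candidates.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        holdout = tuple(
            (normalize_symbol(l), normalize_symbol(r)) for l, r in holdout_pairs
        )
        timings: dict[str, float] = {}

        def stage(name: str):
            timings[name] = time.perf_counter()
            logger.info("stage: %s", name)

        stage("preprocess")
        data = preprocessing.filter_expression(
            self.data, cfg.min_genes_per_cell, cfg.min_cells_per_gene
        )
        data = preprocessing.normalize(data, cfg.target_sum, cfg.log_transform)

        stage("cluster")
        cell_graph = preprocessing.build_cell_graph(data, cfg.n_neighbors, cfg.n_pcs)
        clusters = preprocessing.leiden_cluster(
            cell_graph.adjacency, cfg.resolution, seed
        )
        profiles = preprocessing.cluster_profiles(data, clusters, self.bundle, cfg.tau)

        stage("prior_graph")
        full_prior = pg.build_prior_graph(data.gene_names, self.bundle)
        supervised_edges = tuple(e for e in full_prior.edges if e not in set(holdout))
        if not supervised_edges:
            raise ValueError("holdout removed every prior LR edge")
        if holdout_edges:
            prior = pg.PriorGraph(
                nodes=full_prior.nodes, edges=supervised_edges, W=full_prior.W
            )
        else:
            prior = full_prior
        n2v = replace(cfg.node2vec, seed=seed)
        embedding = pg.node2vec_embed(prior, n2v)
        all_ligands = sorted({l for l, _ in full_prior.edges})
        all_receptors = sorted({r for _, r in full_prior.edges})
        position = pg.position_matrix(embedding, all_ligands, all_receptors)

        stage("inference_graph")
        spatial_map = None
        if data.spatial is not None:
            spatial_map = SpatialMap(
                coords=data.spatial,
                labels=pd.Series(clusters.labels, index=data.cell_names),
            )
        graph = build_inference_graph(
            profiles,
            prior,
            position,
            spatial=spatial_map,
            feature_dim=cfg.gat.feature_dim,
            a_source=cfg.a_source,
            ligands=all_ligands,
            receptors=all_receptors,
        )

        stage("supervision")
        positives = list(supervised_edges)
        n_neg = max(1, int(round(cfg.negative_ratio * len(positives))))
        universe = {(l, r) for l in all_ligands for r in all_receptors}
        negatives = evaluation.make_negatives(
            positives=set(full_prior.edges) | set(holdout),
            n_neg=n_neg,
            seed=seed + 2,
            universe=universe,
        )
        labeled = evaluation.split_pairs(
            positives, negatives, cfg.validation_fraction, seed=seed + 3
        )
        idx = graph.index
        train_pos = [ (idx[l], idx[r]) for l, r in sorted(labeled.subset("train", 1)) ]
        train_neg = [ (idx[l], idx[r]) for l, r in sorted(labeled.subset("train", 0)) ]

        stage("gat")
        gat_cfg = replace(cfg.gat, seed=seed + 1)
        trained: TrainResult = train_link_scorer(
            graph.node_features, graph.edges, train_pos, train_neg, gat_cfg
        )

        stage("rank")
        result = communication_probabilities(trained.embeddings, graph)
        metrics = evaluation.evaluate_split(result.ranking, labeled)

        t_keys = list(timings)
        now = time.perf_counter()
        durations = {
            k: (timings[t_keys[i + 1]] if i + 1 < len(t_keys) else now) - timings[k]
            for i, k in enumerate(t_keys)
        }
        for name, dt in durations.items():
            logger.info("stage %-16s %.2fs", name, dt)
        return CommunicationResults(
            result=result,
            clusters=clusters,
            profiles=profiles,
            prior=prior,
            position=position,
            graph=graph,
            labeled=labeled,
            metrics=metrics,
            loss_history=trained.loss_history,
            config=cfg,
            seed=seed,
            holdout=holdout,
            spatial_map=spatial_map,
            timings=durations,
        )
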