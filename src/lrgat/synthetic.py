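"""Self-contained synthetic worlds: expression, prior bundle, ground truth.

The generator emulates what a clustered scRNA-seq experiment plus an
OmniPath-style prior export provide, without any download: negative
binomial counts with cluster-specific means (overdispersion is the norm
in droplet data), a curated LR table in which a subset of pairs is
"planted" -- the ligand's mean is elevated ``effect_size``-fold in a
source cluster and the receptor's in a destination cluster -- and
complexes/pathways whose co-membership is enriched for planted pairs.
Optional spatial coordinates place each generative cluster as a Gaussian
blob so planted source/destination clusters are spatially coherent.

Everything is deterministic under the spec seed, and the writers emit the
same on-disk formats the loaders read, so fixtures double as round-trip
tests of all readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .preprocessing import ExpressionData
from .prior import PriorBundle

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "fixture_small", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic world."""

    n_genes: int = 60
    n_cells: int = 240
    n_clusters: int = 3
    n_lr_pairs: int = 6
    n_planted: int = 2
    effect_size: float = 8.0
    nb_mean: float = 1.0          # baseline per-gene per-cell mean count
    nb_dispersion: float = 0.5    # var = mu + dispersion * mu^2
    cluster_lognorm_sigma: float = 0.5  # per-(gene, cluster) mean heterogeneity
    n_ppi: int = 20
    n_complexes: int = 12
    n_pathways: int = 8
    co_membership_enrichment: float = 0.0
    background_co_membership: float = 0.0
    spatial: bool = False
    spatial_radius: float = 10.0
    spatial_spread: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_clusters, self.n_lr_pairs) < 1:
            raise ValueError("all counts must be positive")
        if self.n_planted > self.n_lr_pairs:
            raise ValueError("n_planted cannot exceed n_lr_pairs")
        if 2 * self.n_lr_pairs > self.n_genes:
            raise ValueError(
                f"{self.n_lr_pairs} LR pairs need {2 * self.n_lr_pairs} distinct "
                f"genes but only {self.n_genes} exist"
            )
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.n_cells < self.n_clusters:
            raise ValueError("need at least one cell per cluster")


@dataclass(frozen=True)
class Fixture:
    data: ExpressionData
    bundle: PriorBundle
    truth: pd.DataFrame  # ligand, receptor, source_cluster, dest_cluster
    true_labels: np.ndarray  # generative cluster of each cell
    spec: FixtureSpec

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.truth["ligand"], self.truth["receptor"]))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate one deterministic synthetic world from its spec."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:03d}" for i in range(spec.n_genes)]
    ligands = genes[: spec.n_lr_pairs]
    receptors = genes[spec.n_lr_pairs : 2 * spec.n_lr_pairs]
    lr_pairs = list(zip(ligands, receptors))
    planted = lr_pairs[: spec.n_planted]
    src_dst = [
        (k % spec.n_clusters, (k + 1) % spec.n_clusters) for k in range(spec.n_planted)
    ]

    # cluster-specific NB means
    base = spec.nb_mean * rng.lognormal(0.0, 0.25, size=spec.n_genes)
    mu = base[:, None] * rng.lognormal(
        0.0, spec.cluster_lognorm_sigma, size=(spec.n_genes, spec.n_clusters)
    )
    gidx = {g: i for i, g in enumerate(genes)}
    for (lig, rec), (src, dst) in zip(planted, src_dst):
        mu[gidx[lig], src] *= spec.effect_size
        mu[gidx[rec], dst] *= spec.effect_size

    sizes = np.full(spec.n_clusters, spec.n_cells // spec.n_clusters)
    sizes[: spec.n_cells % spec.n_clusters] += 1
    labels = np.repeat(np.arange(spec.n_clusters), sizes)
    counts = _nb_counts(rng, mu[:, labels], spec.nb_dispersion)
    cells = [f"cell_{i + 1:04d}" for i in range(spec.n_cells)]

    spatial = None
    if spec.spatial:
        angles = 2 * np.pi * np.arange(spec.n_clusters) / spec.n_clusters
        centers = spec.spatial_radius * np.c_[np.cos(angles), np.sin(angles)]
        xy = centers[labels] + rng.normal(0.0, spec.spatial_spread, size=(spec.n_cells, 2))
        spatial = pd.DataFrame(xy, index=cells, columns=["x", "y"])
        spatial.index.name = "cell_id"

    data = ExpressionData(
        gene_names=genes, cell_names=cells, counts=counts, spatial=spatial
    )

    ppi: set[tuple[str, str]] = set()
    while len(ppi) < spec.n_ppi:
        a, b = rng.choice(spec.n_genes, size=2, replace=False)
        ppi.add(tuple(sorted((genes[a], genes[b]))))

    complexes: dict[str, frozenset[str]] = {}
    pathways: dict[str, frozenset[str]] = {}
    for k in range(spec.n_complexes):
        size = rng.integers(2, 5)
        members = rng.choice(spec.n_genes, size=size, replace=False)
        complexes[f"CPX{k + 1:03d}"] = frozenset(genes[i] for i in members)
    for k in range(spec.n_pathways):
        size = rng.integers(3, 9)
        members = rng.choice(spec.n_genes, size=size, replace=False)
        pathways[f"PW{k + 1:03d}"] = frozenset(genes[i] for i in members)
    # co-membership enrichment: planted pairs share a complex/pathway more
    # often than background pairs
    for i, (lig, rec) in enumerate(lr_pairs):
        p = spec.co_membership_enrichment if i < spec.n_planted else spec.background_co_membership
        if rng.random() < p:
            extra = genes[int(rng.integers(spec.n_genes))]
            complexes[f"CPX_LR{i + 1:02d}"] = frozenset({lig, rec, extra})
        if rng.random() < p:
            extra = genes[int(rng.integers(spec.n_genes))]
            pathways[f"PW_LR{i + 1:02d}"] = frozenset({lig, rec, extra})

    bundle = PriorBundle(
        lr_pairs=frozenset(lr_pairs),
        ppi_pairs=frozenset(ppi),  # type: ignore[arg-type]
        complexes=complexes,
        pathways=pathways,
    )
    truth = pd.DataFrame(
        {
            "ligand": [l for l, _ in planted],
            "receptor": [r for _, r in planted],
            "source_cluster": [s for s, _ in src_dst],
            "dest_cluster": [d for _, d in src_dst],
        }
    )
    return Fixture(data=data, bundle=bundle, truth=truth, true_labels=labels, spec=spec)


def fixture_small(seed: int = 0, effect_size: float = 8.0, spatial: bool = False) -> Fixture:
    """Canned tiny world: 20 genes, 60 cells, 3 clusters, 6 LR pairs, 2 planted."""
    return generate_fixture(
        FixtureSpec(
            n_genes=20,
            n_cells=60,
            n_clusters=3,
            n_lr_pairs=6,
            n_planted=2,
            effect_size=effect_size,
            n_ppi=10,
            n_complexes=6,
            n_pathways=4,
            spatial=spatial,
            seed=seed,
        )
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the exact formats the package loaders read."""
    from .prior import save_prior_bundle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mtx = outdir / "matrix.mtx"
    scipy.io.mmwrite(mtx, sp.coo_matrix(fixture.data.counts.astype(int)))
    paths["matrix"] = mtx
    pd.Series(fixture.data.gene_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(fixture.data.cell_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    paths.update(save_prior_bundle(fixture.bundle, outdir))
    if fixture.data.spatial is not None:
        sp_path = outdir / "spatial.csv"
        fixture.data.spatial.to_csv(sp_path)
        paths["spatial"] = sp_path
    truth_path = outdir / "truth.tsv"
    fixture.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    labels_path = outdir / "true_labels.tsv"
    pd.DataFrame(
        {"cell_id": fixture.data.cell_names, "cluster": fixture.true_labels}
    ).to_csv(labels_path, sep="\t", index=False)
    paths["true_labels"] = labels_path
    return paths
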