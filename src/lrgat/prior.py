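"""Prior-knowledge bundle: ligand-receptor pairs, PPIs, complexes, pathways.

The bundle plays two roles. It is the supervision source for the link
scorer (curated ligand->receptor interactions are the positive class) and
the annotation source for the pairwise feature matrices: for two gene
products *m* and *n* the annotation ``W[m, n] = z(m, n) + a(m, n)`` counts
the protein complexes and the pathways in which both are members.

Gene/protein identifiers are HGNC-style symbols; "related" between a gene
and a protein means identifier equality after normalisation (upper-case,
whitespace-trimmed).  No alias or orthology resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PriorBundle",
    "GeneProteinMap",
    "SchemaError",
    "normalize_symbol",
    "load_prior_bundle",
    "save_prior_bundle",
    "build_gene_protein_map",
    "complex_comembership",
    "pathway_comembership",
]


class SchemaError(ValueError):
    """A prior table is missing a required column or is unusable."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene/protein symbol: trimmed, upper-cased."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class PriorBundle:
    """Curated prior knowledge keyed by normalised gene symbols.

    Attributes
    ----------
    lr_pairs
        Ordered (ligand, receptor) interactions, deduplicated, no
        self-pairs.
    ppi_pairs
        Unordered protein-protein interactions stored canonically as
        lexicographically sorted tuples.
    complexes
        complex_id -> set of member symbols (flat membership).
    pathways
        pathway_id -> set of member symbols.
    """

    lr_pairs: frozenset[tuple[str, str]]
    ppi_pairs: frozenset[tuple[str, str]]
    complexes: Mapping[str, frozenset[str]]
    pathways: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for lig, rec in self.lr_pairs:
            if lig == rec:
                raise ValueError(f"self-pair in lr_pairs: {lig}")
        for cid, members in {**dict(self.complexes), **dict(self.pathways)}.items():
            if not members:
                raise ValueError(f"empty member set for {cid!r}")

    @property
    def ligands(self) -> set[str]:
        return {l for l, _ in self.lr_pairs}

    @property
    def receptors(self) -> set[str]:
        return {r for _, r in self.lr_pairs}

    @property
    def symbols(self) -> set[str]:
        """Every symbol appearing anywhere in the bundle."""
        out: set[str] = set()
        for l, r in self.lr_pairs:
            out.add(l)
            out.add(r)
        for a, b in self.ppi_pairs:
            out.add(a)
            out.add(b)
        for members in self.complexes.values():
            out |= members
        for members in self.pathways.values():
            out |= members
        return out


@dataclass(frozen=True)
class GeneProteinMap:
    """Binary association matrix between dataset genes and bundle proteins.

    ``D[i, j] == 1`` iff gene ``genes[i]`` and protein ``proteins[j]`` have
    the same normalised identifier.
    """

    genes: tuple[str, ...]
    proteins: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        if self.D.shape != (len(self.genes), len(self.proteins)):
            raise ValueError(
                f"D shape {self.D.shape} does not match "
                f"{len(self.genes)} genes x {len(self.proteins)} proteins"
            )


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df.dropna(subset=list(required)).drop_duplicates()
    for c in required:
        df[c] = df[c].map(normalize_symbol)
    return df


def load_prior_bundle(
    lr_path: str | Path,
    ppi_path: str | Path,
    complexes_path: str | Path,
    pathways_path: str | Path,
) -> PriorBundle:
    """Load and validate the four-table prior bundle.

    Tables are UTF-8 TSVs with headers (``ligand/receptor``,
    ``partner_a/partner_b``, ``complex_id/member``, ``pathway_id/member``);
    lines starting with ``#`` are ignored.  Duplicate rows and duplicate
    LR pairs are dropped; LR rows whose ligand equals their receptor after
    normalisation are dropped with a warning.
    """
    lr = _read_table(lr_path, ["ligand", "receptor"])
    if lr.empty:
        raise SchemaError(f"{lr_path}: ligand-receptor table is empty")
    lr_pairs: set[tuple[str, str]] = set()
    for lig, rec in zip(lr["ligand"], lr["receptor"]):
        if lig == rec:
            logger.warning("dropping self-pair ligand==receptor: %s", lig)
            continue
        lr_pairs.add((lig, rec))
    if not lr_pairs:
        raise SchemaError(f"{lr_path}: no valid ligand-receptor pairs after filtering")

    ppi = _read_table(ppi_path, ["partner_a", "partner_b"])
    ppi_pairs = {
        tuple(sorted((a, b)))
        for a, b in zip(ppi["partner_a"], ppi["partner_b"])
        if a != b
    }

    cx = _read_table(complexes_path, ["complex_id", "member"])
    complexes = {
        cid: frozenset(grp["member"]) for cid, grp in cx.groupby("complex_id")
    }
    pw = _read_table(pathways_path, ["pathway_id", "member"])
    pathways = {
        pid: frozenset(grp["member"]) for pid, grp in pw.groupby("pathway_id")
    }
    return PriorBundle(
        lr_pairs=frozenset(lr_pairs),
        ppi_pairs=frozenset(ppi_pairs),  # type: ignore[arg-type]
        complexes=complexes,
        pathways=pathways,
    )


def save_prior_bundle(bundle: PriorBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables back to ``outdir``; inverse of the loader."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lr": outdir / "lr.tsv",
        "ppi": outdir / "ppi.tsv",
        "complexes": outdir / "complexes.tsv",
        "pathways": outdir / "pathways.tsv",
    }
    pd.DataFrame(sorted(bundle.lr_pairs), columns=["ligand", "receptor"]).to_csv(
        paths["lr"], sep="\t", index=False
    )
    pd.DataFrame(sorted(bundle.ppi_pairs), columns=["partner_a", "partner_b"]).to_csv(
        paths["ppi"], sep="\t", index=False
    )
    cx_rows = [
        (cid, m) for cid in sorted(bundle.complexes) for m in sorted(bundle.complexes[cid])
    ]
    pd.DataFrame(cx_rows, columns=["complex_id", "member"]).to_csv(
        paths["complexes"], sep="\t", index=False
    )
    pw_rows = [
        (pid, m) for pid in sorted(bundle.pathways) for m in sorted(bundle.pathways[pid])
    ]
    pd.DataFrame(pw_rows, columns=["pathway_id", "member"]).to_csv(
        paths["pathways"], sep="\t", index=False
    )
    return paths


def build_gene_protein_map(
    genes: Sequence[str], bundle: PriorBundle
) -> GeneProteinMap:
    """Binary gene<->protein association by identifier equality.

    Proteins are the sorted union of all symbols in the bundle.  An empty
    gene list is a precondition violation; a gene matching nothing simply
    yields an all-zero row.
    """
    if len(genes) == 0:
        raise ValueError("genes must be nonempty")
    norm_genes = tuple(normalize_symbol(g) for g in genes)
    proteins = tuple(sorted(bundle.symbols))
    protein_index = {p: j for j, p in enumerate(proteins)}
    D = np.zeros((len(norm_genes), len(proteins)), dtype=np.uint8)
    for i, g in enumerate(norm_genes):
        j = protein_index.get(g)
        if j is not None:
            D[i, j] = 1
    return GeneProteinMap(genes=norm_genes, proteins=proteins, D=D)


def _comembership(groups: Mapping[str, frozenset[str]], m: str, n: str) -> int:
    m, n = normalize_symbol(m), normalize_symbol(n)
    return sum(1 for members in groups.values() if m in members and n in members)


def complex_comembership(bundle: PriorBundle, m: str, n: str) -> int:
    """Number of complexes containing both *m* and *n* (symmetric).

    For ``m == n`` this degenerates to the number of complexes containing
    the single symbol.  Unknown symbols count zero.
    """
    return _comembership(bundle.complexes, m, n)


def pathway_comembership(bundle: PriorBundle, m: str, n: str) -> int:
    """Number of pathways containing both *m* and *n* (symmetric)."""
    return _comembership(bundle.pathways, m, n)
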