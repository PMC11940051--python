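"""Declarative run configuration with YAML round-trip.

One document holds every tunable of the pipeline so a run can be
reproduced from its echoed config alone.  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .gat import GATConfig
from .prior_graph import Node2VecParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # normalisation; None scales to the median per-cell total
    target_sum: float | None = 1e4
    log_transform: bool = True
    # QC filtering
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    # cell graph / clustering
    n_neighbors: int = 15
    n_pcs: int = 30
    resolution: float = 1.0
    # expressed-LR rule: mean normalised expression must exceed tau
    tau: float = 0.0
    # feature matrix
    a_source: str = "position"  # or "annotation"
    # supervision
    negative_ratio: float = 1.0
    validation_fraction: float = 0.2
    # reporting
    k_top: int = 10
    seed: int = 0
    node2vec: Node2VecParams = field(default_factory=Node2VecParams)
    gat: GATConfig = field(default_factory=GATConfig)

    @classmethod
    def small(cls, **overrides) -> "RunConfig":
        """Defaults suited to tiny (tens of genes/cells) datasets."""
        cfg = cls(
            target_sum=None,  # median per-cell total: sane for small panels
            min_genes_per_cell=1,
            min_cells_per_gene=1,
            n_neighbors=10,
            n_pcs=10,
        )
        return replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, sub_cls in (("node2vec", Node2VecParams), ("gat", GATConfig)):
            if key in doc and isinstance(doc[key], dict):
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(doc[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown config key(s) under {key}: {sorted(sub_unknown)}"
                    )
                doc[key] = sub_cls(**doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
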