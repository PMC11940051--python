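"""Spatial proximity of cell types and of top-ranked predictions.

When per-cell coordinates exist (Visium-style 2-D spots; a ``z`` column
is accepted for 3-D), the distance between two cell types is the minimum
Euclidean distance over all cross-type cell pairs.  Smaller values mean
closer types; the raw distance is used, not a transformed similarity.
Summarising these distances over the top-k predicted interactions gives
the spatial-proximity score of a ranking: methods that prioritise
communication between adjacent cell types show a lower mean and variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Hashable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .inference import CommunicationResult

logger = logging.getLogger(__name__)

__all__ = ["SpatialMap", "min_type_distance", "proximity_of_topk"]


@dataclass(frozen=True)
class SpatialMap:
    """Cell coordinates plus per-cell type/cluster labels."""

    coords: pd.DataFrame  # index: cell id; columns x, y[, z]
    labels: pd.Series  # index: cell id; value: type/cluster label

    def __post_init__(self) -> None:
        missing = self.labels.index.difference(self.coords.index)
        if len(missing):
            raise ValueError(f"labelled cells without coordinates: {list(missing)[:3]}")
        if not np.isfinite(self.coords.to_numpy(float)).all():
            raise ValueError("non-finite coordinates")

    def points_of(self, label: Hashable) -> np.ndarray:
        cells = self.labels.index[self.labels == label]
        if len(cells) == 0:
            raise KeyError(f"no cells with type {label!r}")
        return self.coords.loc[cells].to_numpy(float)


def min_type_distance(spatial: SpatialMap, m: Hashable, n: Hashable) -> float:
    """Minimum Euclidean distance between cells of type m and type n."""
    pm, pn = spatial.points_of(m), spatial.points_of(n)
    return float(cdist(pm, pn).min())


def proximity_of_topk(
    result: "CommunicationResult", spatial: SpatialMap, k: int = 10
) -> dict:
    """Spatial proximity summary of the top-k predicted interactions.

    For each of the top-k ranked pairs the distance between its source
    and destination cluster is computed; pairs whose clusters are absent
    from the spatial labels are skipped with a warning.  Variance is the
    population variance over the pairs actually used.
    """
    top = result.ranking.head(k)
    distances: list[float] = []
    rows: list[dict] = []
    n_skipped = 0
    for _, row in top.iterrows():
        try:
            d = min_type_distance(spatial, row["source_cluster"], row["dest_cluster"])
        except KeyError as exc:
            logger.warning("skipping pair (%s, %s): %s", row["ligand"], row["receptor"], exc)
            n_skipped += 1
            continue
        distances.append(d)
        rows.append(
            {
                "ligand": row["ligand"],
                "receptor": row["receptor"],
                "source_cluster": row["source_cluster"],
                "dest_cluster": row["dest_cluster"],
                "distance": d,
            }
        )
    arr = np.array(distances)
    return {
        "mean": float(arr.mean()) if arr.size else float("nan"),
        "variance": float(arr.var()) if arr.size else float("nan"),
        "distances": pd.DataFrame(rows),
        "n_used": int(arr.size),
        "n_skipped": n_skipped,
    }
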