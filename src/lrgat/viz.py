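"""Chord/Sankey data exports of the top-ranked interactions.

The canonical visualisation artifact is the data export, keeping the
core headless: a chord document (clusters + genes as nodes, one weighted
ligand->receptor link per top-k edge) and a Sankey document in which each
top-k edge becomes a source-cluster -> ligand -> receptor -> dest-cluster
flow with the communication score as weight, so every intermediate node
conserves flow.  Exports are canonical JSON (sorted keys, fixed indent):
re-exporting the same result is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from .inference import CommunicationResult, top_k

__all__ = ["chord_data", "sankey_data", "export_viz"]


def chord_data(result: CommunicationResult, k: int = 10) -> dict:
    top = top_k(result, k)
    clusters = sorted(
        set(top["source_cluster"]) | set(top["dest_cluster"])
    )
    genes = sorted(set(top["ligand"]) | set(top["receptor"]))
    nodes = [{"id": f"cluster_{c}", "type": "cluster"} for c in clusters] + [
        {"id": g, "type": "gene"} for g in genes
    ]
    links = [
        {
            "source": row["ligand"],
            "target": row["receptor"],
            "weight": float(row["score"]),
            "source_cluster": f"cluster_{row['source_cluster']}",
            "dest_cluster": f"cluster_{row['dest_cluster']}",
        }
        for _, row in top.iterrows()
    ]
    return {"format": "chord", "nodes": nodes, "links": links}


def sankey_data(result: CommunicationResult, k: int = 10) -> dict:
    top = top_k(result, k)
    nodes: list[dict] = []
    seen: set[str] = set()

    def add(node_id: str, stage: str) -> str:
        if node_id not in seen:
            seen.add(node_id)
            nodes.append({"id": node_id, "stage": stage})
        return node_id

    links = []
    for _, row in top.iterrows():
        w = float(row["score"])
        src = add(f"source:cluster_{row['source_cluster']}", "source_cluster")
        lig = add(f"ligand:{row['ligand']}", "ligand")
        rec = add(f"receptor:{row['receptor']}", "receptor")
        dst = add(f"dest:cluster_{row['dest_cluster']}", "dest_cluster")
        links.append({"source": src, "target": lig, "weight": w})
        links.append({"source": lig, "target": rec, "weight": w})
        links.append({"source": rec, "target": dst, "weight": w})
    return {"format": "sankey", "nodes": nodes, "links": links}


def export_viz(
    result: CommunicationResult,
    path: str | Path,
    k: int = 10,
    fmt: str = "chord_json",
) -> Path:
    """Write a schema-stable JSON export; returns the path written."""
    if fmt == "chord_json":
        doc = chord_data(result, k)
    elif fmt == "sankey_json":
        doc = sankey_data(result, k)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
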