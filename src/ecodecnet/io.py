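"""File I/O: edge-list/node CSV, network JSON, GraphML, report tables.

CSV dialect: comma-separated, UTF-8, header row required, ``.`` decimal;
weights are written with 9 significant digits.  The JSON network
document is::

    {"nodes": [{"id", "label", "layer"}],
     "links": [{"source", "target", "weight"}],
     "meta": {"name", "created", "layered": bool}}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .core import (
    Link,
    NodeSpec,
    WeightedDigraph,
    build_network,
)
from .indices import IndexReport

__all__ = [
    "read_node_csv",
    "write_node_csv",
    "read_edge_csv",
    "write_edge_csv",
    "network_to_json",
    "network_from_json",
    "write_network_json",
    "read_network_json",
    "write_graphml",
    "write_report",
    "write_ensemble_csv",
    "read_ensemble_csv",
]


def _fmt_weight(w: float) -> str:
    return format(float(w), ".9g")


def read_node_csv(path: str | Path) -> list[NodeSpec]:
    """Read a node table ``id,label,layer`` (layer may be empty)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"id", "label", "layer"} - set(df.columns)
    if missing:
        raise ValueError(f"node CSV missing column(s): {sorted(missing)}")
    return [
        NodeSpec(r.id, r.label, r.layer or None) for r in df.itertuples(index=False)
    ]


def write_node_csv(nodes: Sequence[NodeSpec], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"id": n.id, "label": n.label, "layer": n.layer or ""} for n in nodes]
    )
    df.to_csv(path, index=False)


def read_edge_csv(path: str | Path) -> list[Link]:
    """Read an edge list ``source,target,weight[,link_type]``."""
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    missing = {"source", "target", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"edge CSV missing column(s): {sorted(missing)}")
    return [
        Link(r.source, r.target, float(r.weight))
        for r in df.itertuples(index=False)
    ]


def write_edge_csv(net: WeightedDigraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source,target,weight\n")
        for link in net.links:
            fh.write(f"{link.source},{link.target},{_fmt_weight(link.weight)}\n")


def network_to_json(
    net: WeightedDigraph, name: str = "", created: str | None = None
) -> dict:
    return {
        "nodes": [
            {"id": n.id, "label": n.label, "layer": n.layer} for n in net.nodes
        ],
        "links": [
            {"source": l.source, "target": l.target, "weight": l.weight}
            for l in net.links
        ],
        "meta": {"name": name, "created": created, "layered": net.layered},
    }


def network_from_json(doc: dict) -> WeightedDigraph:
    nodes = [
        NodeSpec(d["id"], d.get("label", "") or "", d.get("layer") or None)
        for d in doc["nodes"]
    ]
    links = [Link(d["source"], d["target"], float(d["weight"])) for d in doc["links"]]
    layered = bool(doc.get("meta", {}).get("layered", False))
    return build_network(nodes, links, layered=layered)


def write_network_json(
    net: WeightedDigraph,
    path: str | Path,
    name: str = "",
    created: str | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(network_to_json(net, name=name, created=created), fh, indent=2)
        fh.write("\n")


def read_network_json(path: str | Path) -> WeightedDigraph:
    with open(path, encoding="utf-8") as fh:
        return network_from_json(json.load(fh))


def load_network(path: str | Path, layered: bool | None = None) -> WeightedDigraph:
    """Load a network from `.json` (full document) or `.csv` (edge list).

    Edge lists carry no layer information, so CSV input yields a general
    digraph unless node specs are supplied separately (see the CLI).
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        net = read_network_json(p)
    else:
        links = read_edge_csv(p)
        ids = sorted({l.source for l in links} | {l.target for l in links})
        net = build_network([NodeSpec(i) for i in ids], links)
    if layered and not net.layered:
        raise ValueError(f"{path}: expected a layered network document")
    return net


def write_graphml(net: WeightedDigraph, path: str | Path) -> None:
    """GraphML export for graph viewers (labels and layers as attributes)."""
    nx.write_graphml(net.to_networkx(), str(path))


def write_report(report: IndexReport, path: str | Path, fmt: str = "json") -> None:
    """Write an index report as ``json`` or single-row ``tsv``."""
    text = report.to_json() + "\n" if fmt == "json" else report.to_tsv()
    if fmt not in ("json", "tsv"):
        raise ValueError(f"unknown report format: {fmt!r}")
    Path(path).write_text(text, encoding="utf-8")


def write_ensemble_csv(
    df: pd.DataFrame, path: str | Path, seed: int | None = None
) -> None:
    """Write an ensemble table; the seed is recorded in a header comment."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_ensemble_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
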