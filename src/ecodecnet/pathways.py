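"""Decision-pathway enumeration, scoring, ranking, and trade-off tables.

A decision pathway is a directed route from an action category through a
service to a well-being domain and optionally on to the HWBI node.  Its
aggregate weight summarizes the cumulative influence of the action along
that route; by default weights multiply along the path (influence
attenuates link by link and stays in [0, 1]), with additive and
bottleneck (min) aggregation available.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Sequence

import pandas as pd

from .core import LayeredNetwork

__all__ = [
    "DecisionPath",
    "AGGREGATORS",
    "path_weight",
    "enumerate_paths",
    "rank_paths",
    "tradeoff_table",
]

AGGREGATORS = ("product", "sum", "min")


@dataclass(frozen=True)
class DecisionPath:
    """One route through the network with its per-link and aggregate weights."""

    nodes: tuple[str, ...]
    link_weights: tuple[float, ...]
    aggregator: str
    weight: float


def path_weight(weights: Sequence[float], aggregator: str = "product") -> float:
    """Aggregate per-link weights into one path score.

    ``product`` (default) multiplies, ``sum`` adds, ``min`` takes the
    bottleneck link.
    """
    if aggregator == "product":
        return float(prod(weights))
    if aggregator == "sum":
        return float(sum(weights))
    if aggregator == "min":
        return float(min(weights))
    raise ValueError(f"unknown aggregator: {aggregator!r}; expected one of {AGGREGATORS}")


def enumerate_paths(
    net: LayeredNetwork,
    action: str,
    terminus: str = "HWBI",
    aggregator: str = "product",
) -> list[DecisionPath]:
    """All simple directed paths from an action to a domain or to HWBI.

    Only positive-weight links are traversed.  Paths to a domain node end
    there (the D->HWBI link is not included); paths to HWBI include it.
    The enumeration is exhaustive; with no outgoing links the list is
    empty.
    """
    if not net.has_node(action):
        raise KeyError(f"unknown node: {action!r}")
    if net.node(action).layer != "AC":
        raise ValueError(f"not an action category: {action!r}")
    if not net.has_node(terminus):
        raise KeyError(f"unknown node: {terminus!r}")
    if net.node(terminus).layer not in ("D", "HWBI"):
        raise ValueError(f"terminus must be a domain or HWBI, got {terminus!r}")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator: {aggregator!r}")

    paths: list[DecisionPath] = []

    def _dfs(node: str, trail: list[str], weights: list[float]) -> None:
        if node == terminus:
            paths.append(
                DecisionPath(
                    nodes=tuple(trail),
                    link_weights=tuple(weights),
                    aggregator=aggregator,
                    weight=path_weight(weights, aggregator),
                )
            )
            return
        for nxt, w in sorted(net.successors(node)):
            _dfs(nxt, trail + [nxt], weights + [w])

    _dfs(action, [action], [])
    return paths


def rank_paths(
    net: LayeredNetwork,
    action: str,
    terminus: str = "HWBI",
    k: int | None = None,
    aggregator: str = "product",
) -> list[DecisionPath]:
    """Top-k paths by aggregate weight, descending.

    Ties are broken lexicographically by the node-id sequence so the
    ranking is deterministic.  ``k=None`` returns every path.
    """
    if k is not None and k < 1:
        raise ValueError("invalid k: must be >= 1")
    paths = enumerate_paths(net, action, terminus, aggregator)
    paths.sort(key=lambda p: (-p.weight, p.nodes))
    return paths if k is None else paths[:k]


def tradeoff_table(
    net: LayeredNetwork,
    actions: Sequence[str] | None = None,
    aggregator: str = "product",
) -> pd.DataFrame:
    """Aggregated influence of each action on each domain and on HWBI.

    Cell (action, domain) sums the aggregate weights of every path from
    the action to that domain; the HWBI column sums paths all the way to
    the index node.  Actions with no paths get all-zero rows.
    """
    if actions is None:
        actions = [n.id for n in net.layer_nodes("AC")]
    else:
        for a in actions:
            if not net.has_node(a):
                raise KeyError(f"unknown node: {a!r}")
            if net.node(a).layer != "AC":
                raise ValueError(f"not an action category: {a!r}")
    domains = [n.id for n in net.layer_nodes("D")]
    hwbi = net.hwbi_node.id
    cols = domains + [hwbi]
    data = []
    for a in actions:
        row = {
            d: sum(p.weight for p in enumerate_paths(net, a, d, aggregator))
            for d in domains
        }
        row[hwbi] = sum(p.weight for p in enumerate_paths(net, a, hwbi, aggregator))
        data.append(row)
    table = pd.DataFrame(data, index=list(actions), columns=cols)
    table.index.name = "action"
    return table
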