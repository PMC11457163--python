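"""Data model for weighted directed influence networks.

An eco-decisional network is a four-layer directed acyclic graph whose
nodes are community action categories (AC), ecosystem/social/economic
services (S), domains of human well-being (D), and a single terminal
node for the composite Human Well-Being Index (HWBI).  Links carry
non-negative influence weights; in layered mode weights are normalized
to [0, 1] and every link must join adjacent layers in the order
AC -> S -> D -> HWBI (no reverse links, no within-layer links).

General :class:`WeightedDigraph` objects (arbitrary topology, weights
>= 0, optional self-links) serve as the substrate for the random
ensemble analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Layer names in flow order.
LAYERS = ("AC", "S", "D", "HWBI")

#: Ordered pairs of layers a link may join in layered mode.
ADJACENT_LAYERS = (("AC", "S"), ("S", "D"), ("D", "HWBI"))

#: link_type labels used in raw score tables, keyed by (source, target) layer.
LINK_TYPE_BY_LAYERS = {("AC", "S"): "AC-S", ("S", "D"): "S-D", ("D", "HWBI"): "D-HWBI"}


class NetworkValidationError(ValueError):
    """Raised when nodes or links violate the network contract."""


class DegenerateNetworkError(ValueError):
    """Raised when an operation requires flow but the network has none."""


@dataclass(frozen=True)
class NodeSpec:
    """A network node: short unique id, free-text label, optional layer."""

    id: str
    label: str = ""
    layer: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be a non-empty string")
        if self.layer is not None and self.layer not in LAYERS:
            raise NetworkValidationError(
                f"unknown layer {self.layer!r} for node {self.id!r}; "
                f"expected one of {LAYERS}"
            )


@dataclass(frozen=True)
class Link:
    """A directed influence link with a non-negative weight."""

    source: str
    target: str
    weight: float

    def __post_init__(self) -> None:
        w = float(self.weight)
        if not math.isfinite(w) or w < 0:
            raise NetworkValidationError(
                f"weight out of range: link {self.source}->{self.target} "
                f"has weight {self.weight!r} (must be finite and >= 0)"
            )
        object.__setattr__(self, "weight", w)


@dataclass(frozen=True)
class LayerSpec:
    """Node counts per layer; the default matches the published taxonomy."""

    n_ac: int = 29
    n_s: int = 22
    n_d: int = 8
    n_hwbi: int = 1

    def __post_init__(self) -> None:
        for name in ("n_ac", "n_s", "n_d", "n_hwbi"):
            if getattr(self, name) < 1:
                raise NetworkValidationError(f"{name} must be >= 1")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_ac, self.n_s, self.n_d, self.n_hwbi)


DEFAULT_LAYER_SPEC = LayerSpec()


class WeightedDigraph:
    """A directed network with non-negative link weights.

    Parameters
    ----------
    nodes
        Node specifications; ids must be unique.
    links
        Links; duplicate ``(source, target)`` pairs are an error (weights
        are consolidated upstream, never summed here).
    allow_self
        Whether self-links are permitted (default True for general
        digraphs; always False in layered mode).
    """

    layered: bool = False

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        links: Sequence[Link],
        *,
        allow_self: bool = True,
    ) -> None:
        node_list = [n if isinstance(n, NodeSpec) else NodeSpec(*n) for n in nodes]
        ids = [n.id for n in node_list]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate node id(s): {dupes}")
        self._nodes: dict[str, NodeSpec] = {n.id: n for n in node_list}
        self._links: dict[tuple[str, str], float] = {}
        self.allow_self = allow_self
        for link in links:
            if not isinstance(link, Link):
                link = Link(*link)
            self._validate_link(link)
            self._links[(link.source, link.target)] = link.weight

    def _validate_link(self, link: Link) -> None:
        for endpoint in (link.source, link.target):
            if endpoint not in self._nodes:
                raise NetworkValidationError(
                    f"dangling link: endpoint {endpoint!r} of "
                    f"{link.source}->{link.target} is not a declared node"
                )
        key = (link.source, link.target)
        if key in self._links:
            raise NetworkValidationError(
                f"duplicate link: {link.source}->{link.target}"
            )
        if link.source == link.target and not self.allow_self:
            raise NetworkValidationError(
                f"forbidden link direction/type: self-link {link.source}->{link.target}"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple[NodeSpec, ...]:
        return tuple(self._nodes.values())

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def n(self) -> int:
        """Node count."""
        return len(self._nodes)

    @property
    def L(self) -> int:
        """Count of links with strictly positive weight."""
        return sum(1 for w in self._links.values() if w > 0)

    @property
    def links(self) -> tuple[Link, ...]:
        return tuple(Link(s, t, w) for (s, t), w in self._links.items())

    def node(self, node_id: str) -> NodeSpec:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown node: {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def link_weight(self, source: str, target: str) -> float:
        return self._links.get((source, target), 0.0)

    def successors(self, node_id: str) -> list[tuple[str, float]]:
        """Positive-weight out-links of ``node_id`` as (target, weight)."""
        return [
            (t, w) for (s, t), w in self._links.items() if s == node_id and w > 0
        ]

    def flows(self) -> Iterator[tuple[str, str, float]]:
        """Iterate over positive-weight links as (source, target, weight)."""
        for (s, t), w in self._links.items():
            if w > 0:
                yield s, t, w

    @property
    def is_degenerate(self) -> bool:
        """True when the network carries no flow (L = 0 or TST = 0)."""
        return self.L == 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = type(self).__name__
        return f"<{kind} n={self.n} L={self.L}>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedDigraph):
            return NotImplemented
        return self._nodes == other._nodes and self._links == other._links

    # -- interoperability ------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Export as a :class:`networkx.DiGraph` (all links, label/layer attrs)."""
        g = nx.DiGraph()
        for node in self._nodes.values():
            g.add_node(node.id, label=node.label, layer=node.layer or "")
        for (s, t), w in self._links.items():
            g.add_edge(s, t, weight=w)
        return g

    def _replace_links(self, links: Sequence[Link]) -> "WeightedDigraph":
        return type(self)(self.nodes, links, allow_self=self.allow_self)


class LayeredNetwork(WeightedDigraph):
    """A :class:`WeightedDigraph` restricted to AC->S->D->HWBI links.

    Every link joins adjacent layers in flow order, carries a weight in
    [0, 1], and the network has exactly one HWBI node.  The structure is
    a four-layer DAG by construction.
    """

    layered = True

    def __init__(self, nodes: Sequence[NodeSpec], links: Sequence[Link]) -> None:
        node_list = [n if isinstance(n, NodeSpec) else NodeSpec(*n) for n in nodes]
        missing = [n.id for n in node_list if n.layer is None]
        if missing:
            raise NetworkValidationError(
                f"layered mode requires a layer for every node; missing: {missing}"
            )
        n_hwbi = sum(1 for n in node_list if n.layer == "HWBI")
        if n_hwbi != 1:
            raise NetworkValidationError(
                f"layered network must have exactly one HWBI node, found {n_hwbi}"
            )
        super().__init__(node_list, links, allow_self=False)
        counts = {layer: 0 for layer in LAYERS}
        for n in node_list:
            counts[n.layer] += 1  # type: ignore[index]
        self.layer_spec = LayerSpec(
            n_ac=max(counts["AC"], 1),
            n_s=max(counts["S"], 1),
            n_d=max(counts["D"], 1),
            n_hwbi=1,
        )

    def _validate_link(self, link: Link) -> None:
        super()._validate_link(link)
        src_layer = self._nodes[link.source].layer
        tgt_layer = self._nodes[link.target].layer
        if (src_layer, tgt_layer) not in set(ADJACENT_LAYERS):
            raise NetworkValidationError(
                "forbidden link direction/type: "
                f"{link.source}({src_layer})->{link.target}({tgt_layer}); "
                "links must join adjacent layers AC->S->D->HWBI"
            )
        if link.weight > 1:
            raise NetworkValidationError(
                f"weight out of range: {link.source}->{link.target} has weight "
                f"{link.weight} > 1 (layered weights are normalized to [0, 1])"
            )

    def layer_nodes(self, layer: str) -> tuple[NodeSpec, ...]:
        """Nodes of one layer, in declaration order."""
        if layer not in LAYERS:
            raise KeyError(f"unknown layer: {layer!r}")
        return tuple(n for n in self._nodes.values() if n.layer == layer)

    @property
    def hwbi_node(self) -> NodeSpec:
        return self.layer_nodes("HWBI")[0]


def build_network(
    nodes: Sequence[NodeSpec],
    links: Sequence[Link],
    *,
    layered: bool = False,
    allow_self: bool = True,
) -> WeightedDigraph:
    """Construct and validate a network.

    In layered mode the result is a :class:`LayeredNetwork` and links are
    checked against the AC->S->D->HWBI layer order with weights in [0, 1].
    """
    if layered:
        return LayeredNetwork(nodes, links)
    return WeightedDigraph(nodes, links, allow_self=allow_self)


def max_permissible_links(spec: LayerSpec = DEFAULT_LAYER_SPEC) -> int:
    """Number of distinct adjacent-layer ordered pairs.

    For the default taxonomy (29 AC, 22 S, 8 D, 1 HWBI) this is
    29*22 + 22*8 + 8*1 = 822.
    """
    return spec.n_ac * spec.n_s + spec.n_s * spec.n_d + spec.n_d * spec.n_hwbi


def prune_zero_links(
    net: WeightedDigraph, epsilon: float = 0.0
) -> WeightedDigraph:
    """Remove links with weight <= ``epsilon``; nodes are retained.

    The default epsilon of 0 removes exact zeros only, matching the
    convention that influence disappears when a weight falls to zero.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    kept = [l for l in net.links if l.weight > epsilon]
    pruned = net._replace_links(kept)
    if pruned.is_degenerate:
        logger.warning("pruning left a degenerate network (no positive links)")
    return pruned


# ---------------------------------------------------------------------------
# Default node taxonomy: 29 action categories, 22 services, 8 well-being
# domains, 1 composite index node.

_ACTION_LABELS = (
    "Access to natural resources",
    "Preserve existence value",
    "Preserve sense of identity/place",
    "Access to arts/music",
    "Access to children's programs",
    "Diversity of population",
    "Access to food and cuisine",
    "Access to government (input)",
    "Knowledge of history",
    "Options for philanthropy",
    "Access to education",
    "Diversity of education content",
    "Increase non-traditional options",
    "Access to healthcare",
    "Focus on youth education",
    "Access health education",
    "Support active lifestyle",
    "Access to basic standard of living",
    "Preserve/promote local culture",
    "Support urban revitalization",
    "Support agriculture",
    "Diversity of jobs",
    "Support economic development",
    "Healthy natural and built environment",
    "Access to housing/lifestyle options",
    "Promote community atmosphere",
    "Support faith institutions",
    "Support population stability/retention",
    "Access to transportation options",
)

_SERVICE_LABELS = (
    "Capital Investment",
    "Production",
    "Innovation",
    "Employment",
    "Re-Distribution",
    "Consumption",
    "Finance",
    "Greenspace",
    "Air Quality",
    "Water Quality",
    "Food, Fiber and Fuel Provisioning",
    "Water Quantity",
    "Activism",
    "Emergency Preparedness",
    "Public works",
    "Communication",
    "Community and Faith-based Initiatives",
    "Education Services",
    "Labor",
    "Healthcare",
    "Justice",
    "Family Services",
)

_DOMAIN_LABELS = (
    "Connection to nature",
    "Cultural fulfillment",
    "Education",
    "Health",
    "Leisure time",
    "Living standards",
    "Safety and security",
    "Social cohesion",
)


def default_node_registry() -> list[NodeSpec]:
    """The 60-node registry: 29 AC, 22 S, 8 D, and the HWBI node.

    Ids are zero-padded (AC01..AC29, S01..S22, D1..D8, HWBI) so plain
    string sorting gives a stable, deterministic order.
    """
    nodes = [
        NodeSpec(f"AC{i + 1:02d}", label, "AC")
        for i, label in enumerate(_ACTION_LABELS)
    ]
    nodes += [
        NodeSpec(f"S{i + 1:02d}", label, "S")
        for i, label in enumerate(_SERVICE_LABELS)
    ]
    nodes += [
        NodeSpec(f"D{i + 1}", label, "D") for i, label in enumerate(_DOMAIN_LABELS)
    ]
    nodes.append(NodeSpec("HWBI", "Human Well-Being Index", "HWBI"))
    return nodes


def iter_permissible_links(nodes: Iterable[NodeSpec]) -> Iterator[tuple[str, str]]:
    """All ordered adjacent-layer node pairs for a layered node set."""
    by_layer: dict[str, list[str]] = {layer: [] for layer in LAYERS}
    for node in nodes:
        if node.layer is None:
            raise NetworkValidationError(
                f"node {node.id!r} has no layer; cannot enumerate layered links"
            )
        by_layer[node.layer].append(node.id)
    for src_layer, tgt_layer in ADJACENT_LAYERS:
        for s in by_layer[src_layer]:
            for t in by_layer[tgt_layer]:
                yield (s, t)
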