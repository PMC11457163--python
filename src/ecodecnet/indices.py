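"""Information-theoretic indices of weighted network organization.

The link weights T_ij of a network are treated as a flow distribution:
with TST = sum(T_ij) and joint probabilities p_ij = T_ij / TST, the
indices are (logs base 2, zero-weight links contribute nothing):

==========================  ==================================================
total system throughput     TST = sum T_ij                    (influence units)
flow entropy                H = -sum p_ij log2 p_ij                      (bits)
average mutual information  AMI = sum p_ij log2(p_ij / (p_i. p_.j))      (bits)
ascendancy                  A = TST * AMI                      (influence*bits)
capacity / overhead         Cap = TST * H;  Phi = Cap - A      (influence*bits)
mean connectivity           C = 2 * TST / n    (weighted links per node)
realized roles              R = 2^AMI          (effective pathway count)
effective link density      c_eff = 2^(H/2)
==========================  ==================================================

AMI measures how much the source of a unit of influence tells us about
its destination; ascendancy scales that constraint by total activity and
is bounded above by capacity.  Realized roles count the effective number
of distinct influence pathways; mean connectivity averages weighted
degree (each link accrues to both endpoints).  The window of vitality is
the region of (c_eff or C, R) space occupied by real ecological flow
networks, approximated here by the inclusive rectangle
[1, 3.01] x [2, 4.5].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .core import DegenerateNetworkError, WeightedDigraph

__all__ = [
    "IndexReport",
    "WOVPolygon",
    "DEFAULT_WOV",
    "total_system_throughput",
    "flow_entropy",
    "average_mutual_information",
    "ascendancy",
    "capacity_and_overhead",
    "mean_connectivity",
    "realized_roles",
    "effective_link_density",
    "index_report",
    "in_window_of_vitality",
]

#: Serialization field order for reports (TSV columns / JSON keys).
REPORT_FIELDS = (
    "tst",
    "h",
    "ami",
    "ascendancy",
    "capacity",
    "overhead",
    "mean_connectivity",
    "realized_roles",
    "effective_link_density",
    "n",
    "links",
)


@dataclass(frozen=True)
class IndexReport:
    """All indices of one network, computed consistently in one pass."""

    tst: float
    h: float
    ami: float
    ascendancy: float
    capacity: float
    overhead: float
    mean_connectivity: float
    realized_roles: float
    effective_link_density: float
    n: int
    links: int

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in REPORT_FIELDS}

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        """Single data row with a header row, tab-separated."""
        header = "\t".join(REPORT_FIELDS)
        vals = self.to_dict()
        row = "\t".join(
            str(vals[k]) if k in ("n", "links") else format(vals[k], ".9g")
            for k in REPORT_FIELDS
        )
        return f"{header}\n{row}\n"


@dataclass(frozen=True)
class WOVPolygon:
    """Rectangular approximation of the window of vitality."""

    c_min: float = 1.0
    c_max: float = 3.01
    r_min: float = 2.0
    r_max: float = 4.5


DEFAULT_WOV = WOVPolygon()


def _flow_distribution(net: WeightedDigraph):
    """Positive flows as (source idx, target idx, p_ij, TST).

    Raises
    ------
    DegenerateNetworkError
        If the network has no positive-weight links.
    """
    flows = list(net.flows())
    if not flows:
        raise DegenerateNetworkError("degenerate network (no flow)")
    ids = {nid: i for i, nid in enumerate(net.node_ids)}
    src = np.array([ids[s] for s, _, _ in flows], dtype=np.intp)
    tgt = np.array([ids[t] for _, t, _ in flows], dtype=np.intp)
    w = np.array([w for _, _, w in flows], dtype=float)
    tst = float(w.sum())
    if tst <= 0:
        raise DegenerateNetworkError("degenerate network (no flow)")
    return src, tgt, w / tst, tst


def total_system_throughput(net: WeightedDigraph) -> float:
    """TST: the sum of all link weights."""
    _, _, _, tst = _flow_distribution(net)
    return tst


def flow_entropy(net: WeightedDigraph) -> float:
    """Shannon entropy of the flow distribution, in bits."""
    _, _, p, _ = _flow_distribution(net)
    return float(-(p * np.log2(p)).sum())


def average_mutual_information(net: WeightedDigraph) -> float:
    """AMI: information a flow's source carries about its destination."""
    src, tgt, p, _ = _flow_distribution(net)
    n = net.n
    row = np.bincount(src, weights=p, minlength=n)
    col = np.bincount(tgt, weights=p, minlength=n)
    ami = float((p * np.log2(p / (row[src] * col[tgt]))).sum())
    # clip tiny negative rounding residue; AMI >= 0 analytically
    return max(ami, 0.0)


def ascendancy(net: WeightedDigraph) -> float:
    """A = TST * AMI, the scaled mutual constraint of the network."""
    return total_system_throughput(net) * average_mutual_information(net)


def capacity_and_overhead(net: WeightedDigraph) -> tuple[float, float]:
    """(Cap, Phi): capacity TST*H and overhead Cap - A (both >= 0)."""
    tst = total_system_throughput(net)
    cap = tst * flow_entropy(net)
    phi = cap - ascendancy(net)
    return cap, max(phi, 0.0)


def mean_connectivity(net: WeightedDigraph) -> float:
    """C = 2*TST/n: mean weighted links per node.

    Each link's weight accrues to both of its endpoints, so C is the
    average total weighted degree.
    """
    return 2.0 * total_system_throughput(net) / net.n


def realized_roles(net: WeightedDigraph) -> float:
    """R = 2^AMI: the effective number of distinct influence pathways."""
    return 2.0 ** average_mutual_information(net)


def effective_link_density(net: WeightedDigraph) -> float:
    """c_eff = 2^(H/2), the entropy-based link density of the flow web."""
    return 2.0 ** (flow_entropy(net) / 2.0)


def index_report(net: WeightedDigraph) -> IndexReport:
    """Compute every index from a single pass over the flow distribution."""
    src, tgt, p, tst = _flow_distribution(net)
    n = net.n
    h = float(-(p * np.log2(p)).sum())
    row = np.bincount(src, weights=p, minlength=n)
    col = np.bincount(tgt, weights=p, minlength=n)
    ami = max(float((p * np.log2(p / (row[src] * col[tgt]))).sum()), 0.0)
    a = tst * ami
    cap = tst * h
    return IndexReport(
        tst=tst,
        h=h,
        ami=ami,
        ascendancy=a,
        capacity=cap,
        overhead=max(cap - a, 0.0),
        mean_connectivity=2.0 * tst / n,
        realized_roles=2.0 ** ami,
        effective_link_density=2.0 ** (h / 2.0),
        n=n,
        links=net.L,
    )


def in_window_of_vitality(
    c_eff: float, roles: float, polygon: WOVPolygon = DEFAULT_WOV
) -> bool:
    """Whether (c_eff, R) lies inside the WOV rectangle (bounds inclusive)."""
    if c_eff < 0 or roles < 0 or not (math.isfinite(c_eff) and math.isfinite(roles)):
        raise ValueError("c_eff and roles must be finite and >= 0")
    return (
        polygon.c_min <= c_eff <= polygon.c_max
        and polygon.r_min <= roles <= polygon.r_max
    )
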