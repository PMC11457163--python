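"""Random-network ensembles and the fits used to summarize them.

Three constraint levels mirror the study design:

1. ``uniform_count`` — fully random digraphs: link count uniform on
   {0, ..., n*n} (or n*(n-1) without self-links), link placement uniform
   without replacement, weights Uniform(0, 1).
2. layer-constrained — random weights on all permissible adjacent-layer
   links of a layered taxonomy (822 for the default 29/22/8/1 spec).
3. fixed topology — random weights on a prescribed link set (e.g. the
   287 community-identified links).

Summaries: an OLS power-law fit of realized roles against mean
connectivity on log-log axes, and the location of the ascendancy
maximum along the connectivity axis (downward parabola fit near the
peak, or a smoothed binned argmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_LAYER_SPEC,
    LayerSpec,
    LayeredNetwork,
    Link,
    NetworkValidationError,
    NodeSpec,
    WeightedDigraph,
    iter_permissible_links,
    max_permissible_links,
)
from .indices import REPORT_FIELDS, index_report

__all__ = [
    "EnsembleConfig",
    "PowerLawFit",
    "PeakEstimate",
    "sample_random_network",
    "sample_layer_constrained",
    "run_size_sweep",
    "run_constrained_sweep",
    "fit_power_law",
    "locate_ascendancy_peak",
    "ENSEMBLE_COLUMNS",
]

#: Column order of ensemble result tables.
ENSEMBLE_COLUMNS = ("size", "rep", "links") + tuple(
    f for f in REPORT_FIELDS if f not in ("n", "links")
)


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of a random-network sweep.

    The defaults reproduce the reference design: five size groups of 100
    replicates each, 500 networks in total, sizes 20-100.
    """

    sizes: tuple[int, ...] = (20, 40, 60, 80, 100)
    reps: int = 100
    link_rule: str = "uniform_count"
    allow_self: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sizes or any(s < 2 for s in self.sizes):
            raise ValueError("sizes must be a non-empty list of counts >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.link_rule not in ("uniform_count", "fixed_topology", "layer_constrained"):
            raise ValueError(f"unknown link_rule: {self.link_rule!r}")


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of R = a * C^b on log-log axes."""

    exponent: float
    prefactor: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PeakEstimate:
    """Connectivity at which ascendancy is maximal."""

    c_at_max: float
    method: str


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Per-replicate stream derived from one root seed by counter keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def sample_random_network(
    n: int,
    rng: np.random.Generator,
    *,
    allow_self: bool = True,
) -> WeightedDigraph:
    """Draw one fully random weighted digraph on ``n`` nodes.

    The link count L is uniform on {0, ..., n*n} (n*(n-1) without
    self-links); the L ordered pairs are uniform without replacement and
    each weight is Uniform(0, 1).  L = 0 yields a valid but degenerate
    network.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    m = n * n if allow_self else n * (n - 1)
    L = int(rng.integers(0, m + 1))
    idx = rng.choice(m, size=L, replace=False)
    if allow_self:
        src = idx // n
        tgt = idx % n
    else:
        src = idx // (n - 1)
        rem = idx % (n - 1)
        tgt = rem + (rem >= src)  # skip the diagonal
    weights = rng.uniform(0.0, 1.0, size=L)
    width = len(str(n - 1))
    nodes = [NodeSpec(f"v{i:0{width}d}") for i in range(n)]
    links = [
        Link(nodes[s].id, nodes[t].id, float(w))
        for s, t, w in zip(src, tgt, weights)
    ]
    return WeightedDigraph(nodes, links, allow_self=allow_self)


def _layered_nodes(spec: LayerSpec) -> list[NodeSpec]:
    nodes = [NodeSpec(f"AC{i + 1:02d}", layer="AC") for i in range(spec.n_ac)]
    nodes += [NodeSpec(f"S{i + 1:02d}", layer="S") for i in range(spec.n_s)]
    nodes += [NodeSpec(f"D{i + 1}", layer="D") for i in range(spec.n_d)]
    nodes += [NodeSpec("HWBI", layer="HWBI")]
    return nodes


def sample_layer_constrained(
    rng: np.random.Generator,
    spec: LayerSpec = DEFAULT_LAYER_SPEC,
    topology: Iterable[tuple[str, str]] | None = None,
    nodes: Sequence[NodeSpec] | None = None,
) -> LayeredNetwork:
    """Random weights on a layered link set.

    With ``topology=None`` every permissible adjacent-layer link gets a
    Uniform(0, 1) weight (822 links for the default spec).  With a
    topology, exactly those links are weighted; links outside the
    permissible set raise ``forbidden link``.
    """
    if nodes is None:
        nodes = _layered_nodes(spec)
    permissible = list(iter_permissible_links(nodes))
    if topology is None:
        pairs = permissible
    else:
        pairs = [(s, t) for s, t in topology]
        bad = set(pairs) - set(permissible)
        if bad:
            raise NetworkValidationError(
                f"forbidden link(s) in topology: {sorted(bad)[:5]}"
            )
    weights = rng.uniform(0.0, 1.0, size=len(pairs))
    links = [Link(s, t, float(w)) for (s, t), w in zip(pairs, weights)]
    return LayeredNetwork(nodes, links)


_NULL_ROW = {f: np.nan for f in ENSEMBLE_COLUMNS if f not in ("size", "rep", "links")}


def _record(size: int, rep: int, net: WeightedDigraph) -> dict:
    row: dict = {"size": size, "rep": rep, "links": net.L}
    if net.is_degenerate:
        row.update(_NULL_ROW)  # kept so record counts match reps exactly
        return row
    report = index_report(net).to_dict()
    for f in ENSEMBLE_COLUMNS[3:]:
        row[f] = report[f]
    return row


def run_size_sweep(config: EnsembleConfig) -> pd.DataFrame:
    """Random-network sweep over size groups; one row per replicate.

    Degenerate replicates (L = 0) are recorded with null indices so the
    record count equals ``len(sizes) * reps``; fits exclude them.
    Reproducible: replicate streams are derived from ``config.seed`` by
    (size index, replicate) counters, so results do not depend on
    execution order.
    """
    rows = []
    for si, size in enumerate(config.sizes):
        for rep in range(config.reps):
            rng = _child_rng(config.seed, si, rep)
            net = sample_random_network(size, rng, allow_self=config.allow_self)
            rows.append(_record(size, rep, net))
    return pd.DataFrame(rows, columns=list(ENSEMBLE_COLUMNS))


def run_constrained_sweep(
    reps: int,
    seed: int = 0,
    spec: LayerSpec = DEFAULT_LAYER_SPEC,
    topology: Iterable[tuple[str, str]] | None = None,
    nodes: Sequence[NodeSpec] | None = None,
) -> pd.DataFrame:
    """Layer-constrained random sweep (random weights, fixed link space)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    topo = list(topology) if topology is not None else None
    rows = []
    size = (len(nodes) if nodes is not None
            else spec.n_ac + spec.n_s + spec.n_d + spec.n_hwbi)
    for rep in range(reps):
        rng = _child_rng(seed, 0, rep)
        net = sample_layer_constrained(rng, spec=spec, topology=topo, nodes=nodes)
        rows.append(_record(size, rep, net))
    return pd.DataFrame(rows, columns=list(ENSEMBLE_COLUMNS))


def fit_power_law(
    c: Sequence[float], r: Sequence[float]
) -> PowerLawFit:
    """Fit R = a * C^b by OLS on (log2 C, log2 R).

    Points with C <= 0 or R <= 0 are dropped; fewer than 3 valid points
    raise ``insufficient data``.
    """
    c_arr = np.asarray(c, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    mask = np.isfinite(c_arr) & np.isfinite(r_arr) & (c_arr > 0) & (r_arr > 0)
    if mask.sum() < 3:
        raise ValueError("insufficient data: need >= 3 points with C > 0 and R > 0")
    res = stats.linregress(np.log2(c_arr[mask]), np.log2(r_arr[mask]))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(2.0 ** res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


def locate_ascendancy_peak(
    c: Sequence[float],
    a: Sequence[float],
    method: str = "quadratic_fit",
    *,
    peak_fraction: float = 0.5,
    bins: int = 25,
) -> PeakEstimate:
    """Locate the connectivity at which ascendancy peaks.

    ``quadratic_fit`` (default): least-squares downward parabola over the
    points with A >= peak_fraction * max(A); the peak is -b/(2a).  A
    non-negative leading coefficient raises ``no interior maximum``.
    ``smoothed_argmax``: mean A in equal-width C bins, 3-bin moving
    average, argmax bin center; exact ties return the midpoint of the
    tied centers.
    """
    c_arr = np.asarray(c, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    mask = np.isfinite(c_arr) & np.isfinite(a_arr)
    c_arr, a_arr = c_arr[mask], a_arr[mask]
    if c_arr.size < 5:
        raise ValueError("insufficient data: need >= 5 points spanning a maximum")

    if method == "quadratic_fit":
        keep = a_arr >= peak_fraction * a_arr.max()
        if keep.sum() < 3:
            keep = np.ones_like(a_arr, dtype=bool)
        coeffs = np.polyfit(c_arr[keep], a_arr[keep], 2)
        if coeffs[0] >= 0:
            raise ValueError("no interior maximum: fitted parabola is not downward")
        peak = float(-coeffs[1] / (2.0 * coeffs[0]))
        lo, hi = float(c_arr.min()), float(c_arr.max())
        if not (lo <= peak <= hi):
            raise ValueError("no interior maximum: fitted peak outside observed range")
        return PeakEstimate(c_at_max=peak, method=method)

    if method == "smoothed_argmax":
        edges = np.linspace(c_arr.min(), c_arr.max(), bins + 1)
        centers, means = [], []
        for i in range(bins):
            hi_edge = edges[i + 1]
            in_bin = (c_arr >= edges[i]) & (
                (c_arr <= hi_edge) if i == bins - 1 else (c_arr < hi_edge)
            )
            if in_bin.any():
                centers.append(0.5 * (edges[i] + hi_edge))
                means.append(a_arr[in_bin].mean())
        centers_a = np.array(centers)
        means_a = np.array(means)
        # centered 3-bin moving average, shrinking at the ends
        smooth = np.array(
            [means_a[max(0, i - 1): i + 2].mean() for i in range(means_a.size)]
        )
        best = smooth.max()
        tied = centers_a[np.isclose(smooth, best)]
        return PeakEstimate(c_at_max=float(tied.mean()), method=method)

    raise ValueError(f"unknown method: {method!r}")
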