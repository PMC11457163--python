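"""Assembly of community-specific networks from raw engagement scores.

The weight pipeline mirrors how communities score their networks:
stakeholder workshops produce prioritization votes and mapping
exercises, and planning-document keyword counts provide mention
frequencies.  Raw scores are normalized 0-1 within each
(link type, data source) group by dividing by the group maximum,
S-D scores may be standardized by factors from a national
services-to-domains regression (consumed as an input table), and the
normalized scores are consolidated across data sources into one weight
per link (unweighted arithmetic mean over the sources that mention it).

Raw score tables are pandas DataFrames with columns
``source, target, link_type, data_source, raw_score``; standardization
tables have ``source, target, factor``; consolidated weight tables have
``source, target, weight``.

A synthetic fixture generator emulates the engagement tables (two data
sources, 287 links, mean weight about 0.70 over the 60-node taxonomy)
so the full pipeline can be exercised without the original workshop
data.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    LINK_TYPE_BY_LAYERS,
    LayeredNetwork,
    Link,
    NetworkValidationError,
    NodeSpec,
    build_network,
    default_node_registry,
    max_permissible_links,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RAW_SCORE_COLUMNS",
    "normalize_scores",
    "apply_standardization",
    "consolidate_sources",
    "assemble_community_network",
    "generate_synthetic_community",
]

RAW_SCORE_COLUMNS = ("source", "target", "link_type", "data_source", "raw_score")
LINK_TYPES = ("AC-S", "S-D", "D-HWBI")

# per-source, per-type raw-score scales for the synthetic fixture: votes are
# workshop tallies, keyword counts are document mention frequencies
_FIXTURE_SCALES = {
    "workshop_votes": {"AC-S": 45.0, "S-D": 30.0, "D-HWBI": 9.0},
    "keyword_counts": {"AC-S": 120.0, "S-D": 60.0, "D-HWBI": 15.0},
}


def _check_raw_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(RAW_SCORE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"raw score table missing column(s): {sorted(missing)}")
    bad_type = set(table["link_type"]) - set(LINK_TYPES)
    if bad_type:
        raise ValueError(f"unknown link_type value(s): {sorted(bad_type)}")
    scores = pd.to_numeric(table["raw_score"])
    if (scores < 0).any() or not np.isfinite(scores).all():
        rows = table.index[(scores < 0) | ~np.isfinite(scores)].tolist()
        raise ValueError(f"invalid raw score (negative or non-finite) at rows {rows}")
    out = table.copy()
    out["raw_score"] = scores.astype(float)
    return out


def normalize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw scores 0-1 within each (link_type, data_source) group.

    Every score is divided by its group maximum, so each non-degenerate
    group has maximum exactly 1.  All-zero groups stay zero (with a
    warning); negative scores are an error.
    """
    out = _check_raw_table(table)
    for (ltype, dsource), idx in out.groupby(
        ["link_type", "data_source"], sort=False
    ).groups.items():
        gmax = out.loc[idx, "raw_score"].max()
        if gmax > 0:
            out.loc[idx, "raw_score"] = out.loc[idx, "raw_score"] / gmax
        else:
            logger.warning(
                "all-zero score group (link_type=%s, data_source=%s); left as zeros",
                ltype,
                dsource,
            )
    return out


def apply_standardization(
    table: pd.DataFrame, std: pd.DataFrame | None
) -> pd.DataFrame:
    """Multiply S-D scores by national-regression factors, then re-normalize.

    ``std`` has columns ``source, target, factor``; S-D links it does not
    cover get factor 1 (with a warning).  After multiplication, S-D
    scores are re-normalized to their group maximum within each data
    source.  Other link types are untouched.
    """
    out = _check_raw_table(table)
    if std is None or len(std) == 0:
        logger.warning("empty standardization table; S-D scores unchanged")
        return out
    if (pd.to_numeric(std["factor"]) < 0).any():
        raise ValueError("standardization factors must be >= 0")
    factors = {
        (r.source, r.target): float(r.factor) for r in std.itertuples(index=False)
    }
    sd = out["link_type"] == "S-D"
    uncovered = {
        (s, t)
        for s, t in zip(out.loc[sd, "source"], out.loc[sd, "target"])
        if (s, t) not in factors
    }
    if uncovered:
        logger.warning(
            "%d S-D link(s) missing from standardization table; factor 1 assumed",
            len(uncovered),
        )
    out.loc[sd, "raw_score"] = [
        score * factors.get((s, t), 1.0)
        for s, t, score in zip(
            out.loc[sd, "source"], out.loc[sd, "target"], out.loc[sd, "raw_score"]
        )
    ]
    for (_, _), idx in out.loc[sd].groupby(
        ["link_type", "data_source"], sort=False
    ).groups.items():
        gmax = out.loc[idx, "raw_score"].max()
        if gmax > 0:
            out.loc[idx, "raw_score"] = out.loc[idx, "raw_score"] / gmax
    return out


def consolidate_sources(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Mean normalized score per link across the data sources mentioning it.

    Returns a weight table ``source, target, weight`` (links absent from
    every source get no entry).  A link typed inconsistently across rows
    is an error.
    """
    if isinstance(tables, pd.DataFrame):
        merged = tables
    else:
        if not tables:
            raise ValueError("need at least one score table")
        merged = pd.concat(list(tables), ignore_index=True)
    merged = _check_raw_table(merged)
    types_per_link = merged.groupby(["source", "target"])["link_type"].nunique()
    if (types_per_link > 1).any():
        bad = types_per_link[types_per_link > 1].index.tolist()
        raise ValueError(f"inconsistent link typing for pair(s): {bad}")
    # mean over data sources: average per (link, source) first so a source
    # mentioning a link twice still counts once
    per_source = (
        merged.groupby(["source", "target", "data_source"], sort=False)["raw_score"]
        .mean()
        .reset_index()
    )
    weights = (
        per_source.groupby(["source", "target"], sort=False)["raw_score"]
        .mean()
        .reset_index()
        .rename(columns={"raw_score": "weight"})
    )
    return weights.sort_values(["source", "target"], ignore_index=True)


def assemble_community_network(
    nodes: Sequence[NodeSpec], weights: pd.DataFrame
) -> LayeredNetwork:
    """Build the layered network carrying exactly the non-zero weights.

    Weights must lie in [0, 1] and reference declared nodes; layered-mode
    validation (adjacent layers only, single HWBI node) applies.
    """
    w = pd.to_numeric(weights["weight"])
    if (w > 1).any() or (w < 0).any():
        raise NetworkValidationError("weight out of range: weights must lie in [0, 1]")
    links = [
        Link(str(r.source), str(r.target), float(r.weight))
        for r in weights.itertuples(index=False)
        if r.weight > 0
    ]
    net = build_network(list(nodes), links, layered=True)
    if net.is_degenerate:
        logger.warning("assembled community network is degenerate (no positive links)")
    return net  # type: ignore[return-value]


def _sample_link_set(
    nodes: Sequence[NodeSpec], n_links: int, rng: np.random.Generator
) -> list[tuple[str, str, str]]:
    """Sample (source, target, link_type) triples honoring the structure.

    Constructive guarantee: all D->HWBI links first, then one inbound
    AC->S and one outbound S->D per used service node, then a uniform
    fill from the remaining permissible links among used services.
    """
    ac = [n.id for n in nodes if n.layer == "AC"]
    s = [n.id for n in nodes if n.layer == "S"]
    d = [n.id for n in nodes if n.layer == "D"]
    hwbi = [n.id for n in nodes if n.layer == "HWBI"][0]

    links: list[tuple[str, str, str]] = [(di, hwbi, "D-HWBI") for di in d]
    budget = n_links - len(links)
    s_use_count = min(len(s), budget // 2)
    if s_use_count < 1:
        raise NetworkValidationError(
            "cannot satisfy structure: too few links for the D-HWBI backbone "
            "plus one in/out link per service node"
        )
    s_used = list(rng.choice(s, size=s_use_count, replace=False))
    chosen: set[tuple[str, str]] = set()
    for si in s_used:
        a = ac[int(rng.integers(len(ac)))]
        di = d[int(rng.integers(len(d)))]
        links.append((a, si, "AC-S"))
        links.append((si, di, "S-D"))
        chosen.update({(a, si), (si, di)})
    remaining = n_links - len(links)
    pool = [(a, si, "AC-S") for a in ac for si in s_used if (a, si) not in chosen]
    pool += [(si, di, "S-D") for si in s_used for di in d if (si, di) not in chosen]
    if remaining > len(pool):
        raise NetworkValidationError(
            "cannot satisfy structure: requested link count exceeds the "
            "permissible link space"
        )
    extra_idx = rng.choice(len(pool), size=remaining, replace=False)
    links.extend(pool[i] for i in sorted(extra_idx))
    return links


def generate_synthetic_community(
    seed: int = 0,
    n_links: int = 287,
    weight_mean: float = 0.70,
    weight_concentration: float = 10.0,
    nodes: Sequence[NodeSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, LayeredNetwork]:
    """Synthetic engagement tables and the network they assemble into.

    Emulates a community's consolidated scoring: ``n_links`` links over
    the default 60-node taxonomy (every domain linked to HWBI, every
    used service with at least one inbound and one outbound link) with
    target weights drawn from a Beta distribution of the requested mean
    (Beta(mean*k, (1-mean)*k) with concentration k).  Two raw source
    tables (workshop votes, keyword counts) are emitted whose
    normalize -> consolidate output reproduces the returned network's
    weights exactly.

    Returns
    -------
    (raw_table, network)
        The raw score table (both data sources stacked) and the layered
        network obtained by running the pipeline on it.
    """
    if nodes is None:
        nodes = default_node_registry()
    cap = max_permissible_links(
        LayeredNetwork(nodes, []).layer_spec
    )
    if n_links > cap:
        raise NetworkValidationError(
            f"cannot satisfy structure: n_links={n_links} exceeds the "
            f"{cap} permissible links"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 287]))
    triples = _sample_link_set(nodes, n_links, rng)
    alpha = weight_mean * weight_concentration
    beta = (1.0 - weight_mean) * weight_concentration
    target = rng.beta(alpha, beta, size=len(triples))

    rows = []
    for (src, tgt, ltype), w in zip(triples, target):
        for dsource, scales in _FIXTURE_SCALES.items():
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "link_type": ltype,
                    "data_source": dsource,
                    "raw_score": float(w) * scales[ltype],
                }
            )
    raw = pd.DataFrame(rows, columns=list(RAW_SCORE_COLUMNS))
    weights = consolidate_sources(normalize_scores(raw))
    net = assemble_community_network(nodes, weights)
    return raw, net
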