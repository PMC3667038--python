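"""Interaction-network connectivity: degrees, hub classes, and their
relation to disorder.

Connectivity k is the number of distinct interaction partners of a protein
after merging all edge sources (duplicates across sources count once).
Partners outside the analysed protein set still contribute to k. Proteins
are classified as hubs (k >= 25), intermediately connected proteins
(ICP, 4 <= k <= 24) or non-hubs (k <= 3); the three classes partition the
non-negative integers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import Edge
from .segmentation_metrics import SegmentSet
from .stats_tests import Tail, mann_whitney

__all__ = [
    "ConnectivityThresholds",
    "ConnectivityClass",
    "ConnectivityRecord",
    "build_degrees",
    "classify_connectivity",
    "connectivity_disorder_summary",
]


class ConnectivityClass(str, enum.Enum):
    HUB = "HUB"
    ICP = "ICP"
    NONHUB = "NONHUB"


@dataclass(frozen=True)
class ConnectivityThresholds:
    hub_min: int = 25
    icp_min: int = 4
    icp_max: int = 24
    nonhub_max: int = 3

    def __post_init__(self) -> None:
        if self.nonhub_max + 1 != self.icp_min or self.icp_max + 1 != self.hub_min:
            raise ValueError("connectivity classes must partition k = 0, 1, 2, ...")


@dataclass(frozen=True)
class ConnectivityRecord:
    protein_id: str
    k: int
    klass: ConnectivityClass


def build_degrees(
    edge_sources: Sequence[Iterable[Edge]] | Iterable[Edge],
    ids: Sequence[str],
) -> dict[str, int]:
    """Distinct-partner counts for ``ids`` from one or more edge sources.

    Multiple sources (e.g. a binary E2-E3 interaction table and a
    STRING-like edge list) are merged by the union of partner sets before
    counting, so an interaction reported by both counts once. Proteins
    absent from every source get k = 0; partners outside ``ids`` still
    count toward k.
    """
    edge_sources = list(edge_sources)
    if edge_sources and isinstance(edge_sources[0], Edge):
        edge_sources = [edge_sources]  # single flat edge list
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for source in edge_sources:
        for e in source:
            graph.add_edge(e.id_a, e.id_b)
    return {pid: graph.degree(pid) for pid in ids}


def classify_connectivity(
    k: int, thresholds: ConnectivityThresholds | None = None
) -> ConnectivityClass:
    th = thresholds or ConnectivityThresholds()
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= th.hub_min:
        return ConnectivityClass.HUB
    if k >= th.icp_min:
        return ConnectivityClass.ICP
    return ConnectivityClass.NONHUB


def connectivity_records(
    degrees: Mapping[str, int], thresholds: ConnectivityThresholds | None = None
) -> list[ConnectivityRecord]:
    th = thresholds or ConnectivityThresholds()
    return [
        ConnectivityRecord(pid, k, classify_connectivity(k, th))
        for pid, k in degrees.items()
    ]


def connectivity_disorder_summary(
    records: Sequence[ConnectivityRecord],
    metrics: Mapping[str, SegmentSet],
) -> tuple[pd.DataFrame, float]:
    """Per-class disorder summary plus the hub-vs-non-hub significance test.

    Rows (HUB, ICP, NONHUB, in that order): count, mean protein length,
    unweighted mean disorder content, mean k; empty classes get missing
    means. The returned p-value is a one-tailed Mann-Whitney U test of the
    alternative that hubs are more disordered than non-hubs (NaN when
    either class is empty).
    """
    by_class: dict[ConnectivityClass, list[ConnectivityRecord]] = {
        c: [] for c in (ConnectivityClass.HUB, ConnectivityClass.ICP, ConnectivityClass.NONHUB)
    }
    for rec in records:
        if rec.protein_id not in metrics:
            raise KeyError(f"no metrics for {rec.protein_id}")
        by_class[rec.klass].append(rec)

    rows = []
    for klass, recs in by_class.items():
        contents = [metrics[r.protein_id].disorder_content for r in recs]
        lengths = [metrics[r.protein_id].length for r in recs]
        ks = [r.k for r in recs]
        rows.append(
            {
                "class": klass.value,
                "n": len(recs),
                "mean_length": sum(lengths) / len(lengths) if recs else math.nan,
                "mean_disorder_content": sum(contents) / len(contents) if recs else math.nan,
                "mean_k": sum(ks) / len(ks) if recs else math.nan,
            }
        )
    hub_contents = [
        metrics[r.protein_id].disorder_content for r in by_class[ConnectivityClass.HUB]
    ]
    nonhub_contents = [
        metrics[r.protein_id].disorder_content for r in by_class[ConnectivityClass.NONHUB]
    ]
    if hub_contents and nonhub_contents:
        p = mann_whitney(hub_contents, nonhub_contents, tail=Tail.ONE_GREATER).p_value
    else:
        p = math.nan
    return pd.DataFrame(rows), p
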