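"""Degree/betweenness centralities and hub-bottleneck classification.

Central nodes are found with the mean + 1 SD rule: a node is a hub when its
degree exceeds mean(degree) + sd(degree), and a bottleneck when its normalized
betweenness exceeds the analogous threshold. Crossing both thresholds makes a
hub-bottleneck (HB); betweenness alone a nonhub-bottleneck (NH-B); degree alone
a hub-nonbottleneck (H-NB); neither, noncentral (NC). "Central" nodes — the
biomarker candidate pool — are the bottleneck classes {HB, NH-B}.

Betweenness follows the undirected convention with endpoints excluded, each
(s, t) pair counted once, normalized by (N-1)(N-2)/2 so values lie in [0, 1];
for disconnected graphs the sum runs over reachable pairs only.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

HUB_BOTTLENECK = "HB"
NONHUB_BOTTLENECK = "NH-B"
HUB_NONBOTTLENECK = "H-NB"
NONCENTRAL = "NC"
CENTRAL_CLASSES = frozenset({HUB_BOTTLENECK, NONHUB_BOTTLENECK})

__all__ = [
    "CentralityRecord",
    "CentralitySummary",
    "node_degrees",
    "betweenness_centrality",
    "centrality_summary",
    "classify_nodes",
    "centrality_table",
    "CENTRAL_CLASSES",
    "HUB_BOTTLENECK",
    "NONHUB_BOTTLENECK",
    "HUB_NONBOTTLENECK",
    "NONCENTRAL",
]


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    degree: int
    betweenness: float
    node_class: str = NONCENTRAL

    @property
    def is_central(self) -> bool:
        return self.node_class in CENTRAL_CLASSES


@dataclass(frozen=True)
class CentralitySummary:
    """Mean, sample SD, and the mean + 1 SD selection threshold for a metric."""

    metric: str
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean + self.sd


def node_degrees(graph: nx.Graph) -> dict[str, int]:
    """Neighbor count per node (simple undirected graph)."""
    return {node: int(deg) for node, deg in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Normalized betweenness, endpoints excluded, scale [0, 1].

    Graphs with fewer than 3 nodes have no interior shortest-path positions;
    all values are 0 by convention.
    """
    if graph.number_of_nodes() < 3:
        return {node: 0.0 for node in graph.nodes}
    # networkx normalizes undirected graphs by 2/((N-1)(N-2)) with each pair
    # counted once, matching the (N-1)(N-2)/2 convention used here.
    return dict(nx.betweenness_centrality(graph, normalized=True))


def centrality_summary(values: Iterable[float], metric: str) -> CentralitySummary:
    """Mean and sample (n-1) standard deviation of a centrality distribution."""
    values = list(values)
    if len(values) < 2:
        raise ValueError(f"need >= 2 values to summarize {metric!r}, got {len(values)}")
    return CentralitySummary(
        metric=metric,
        mean=statistics.fmean(values),
        sd=statistics.stdev(values),
    )


def classify_nodes(
    records: Iterable[CentralityRecord | tuple[str, int, float]],
    degree_threshold: float,
    betweenness_threshold: float,
) -> list[CentralityRecord]:
    """Assign HB/NH-B/H-NB/NC classes by strict threshold exceedance."""
    out = []
    for rec in records:
        if not isinstance(rec, CentralityRecord):
            rec = CentralityRecord(node=rec[0], degree=rec[1], betweenness=rec[2])
        hub = rec.degree > degree_threshold
        bottleneck = rec.betweenness > betweenness_threshold
        if hub and bottleneck:
            cls = HUB_BOTTLENECK
        elif bottleneck:
            cls = NONHUB_BOTTLENECK
        elif hub:
            cls = HUB_NONBOTTLENECK
        else:
            cls = NONCENTRAL
        out.append(
            CentralityRecord(
                node=rec.node,
                degree=rec.degree,
                betweenness=rec.betweenness,
                node_class=cls,
            )
        )
    return out


def centrality_table(graph: nx.Graph) -> tuple[list[CentralityRecord], dict[str, CentralitySummary]]:
    """Full centrality analysis of a graph.

    Computes degree and betweenness for every node, derives mean + 1 SD
    thresholds over ALL nodes (connectors included), and classifies. Returns
    the classified records (node order of the graph) and the per-metric
    summaries.
    """
    degrees = node_degrees(graph)
    betweenness = betweenness_centrality(graph)
    deg_summary = centrality_summary(degrees.values(), "degree")
    btw_summary = centrality_summary(betweenness.values(), "betweenness")
    records = classify_nodes(
        ((n, degrees[n], betweenness[n]) for n in graph.nodes),
        degree_threshold=deg_summary.threshold,
        betweenness_threshold=btw_summary.threshold,
    )
    return records, {"degree": deg_summary, "betweenness": btw_summary}


def records_to_frame(records: Sequence[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [r.node for r in records],
            "degree": [r.degree for r in records],
            "betweenness": [r.betweenness for r in records],
            "node_class": [r.node_class for r in records],
        }
    )


def write_centrality_tsv(records: Sequence[CentralityRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_summary_json(summaries: Mapping[str, CentralitySummary], path) -> None:
    payload = {
        name: {"mean": s.mean, "sd": s.sd, "threshold": s.threshold}
        for name, s in summaries.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
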