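"""Protein-interaction network construction from confidence-scored interaction tables.

This module ingests STRING-style tab-delimited interaction dumps, filters
interactions by evidence channel and confidence, builds the subnetwork induced
by one or more pathway seed-gene sets, and connects stranded seed genes to the
main component with a greedy connector-augmentation algorithm: at each step the
non-seed protein that joins the largest number of still-disconnected nodes to
the main component is added (ties broken by global degree, then
lexicographically), until the network is connected or no candidate remains.

Node origin labels record pathway membership: seed genes carry their seed-set
labels (e.g. ``ST``, ``Ca``, or the joined ``ST+Ca`` for shared members) and
added connectors are labelled ``CON``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

CONNECTOR_LABEL = "CON"

__all__ = [
    "Interaction",
    "SeedSet",
    "AugmentationResult",
    "parse_interaction_table",
    "combine_channel_scores",
    "filter_interactions",
    "induced_subgraph",
    "augment_with_connectors",
    "read_seed_list",
    "apply_id_mapping",
    "write_edge_list",
    "write_graphml",
    "write_connectors_json",
]


@dataclass(frozen=True)
class Interaction:
    """One unordered protein pair with per-channel confidence scores in [0, 1]."""

    protein_a: str
    protein_b: str
    channel_scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction not allowed: {self.protein_a!r}")
        a, b = sorted((self.protein_a, self.protein_b))
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        for channel, score in self.channel_scores.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"score for channel {channel!r} out of [0, 1]: {score}"
                )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class SeedSet:
    """A named pathway gene set used to seed network construction."""

    pathway_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"seed set {self.pathway_id!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class AugmentationResult:
    """Outcome of greedy connector augmentation.

    ``connectors`` lists added non-seed nodes in addition order; ``unresolved``
    holds seed nodes that no available connector could join to the main
    component (the graph is connected iff this set is empty).
    """

    graph: nx.Graph
    connectors: list[str] = field(default_factory=list)
    unresolved: set[str] = field(default_factory=set)

    @property
    def is_connected(self) -> bool:
        return len(self.unresolved) == 0


class InteractionFormatError(ValueError):
    """Raised when an interaction table cannot be parsed."""


def parse_interaction_table(stream: IO[str] | Iterable[str]) -> list[Interaction]:
    """Parse a tab- or whitespace-delimited interaction table.

    The header must name two protein columns (the first two columns) followed by
    one or more score columns; score column names become channel names. Scores
    may be given on the [0, 1] scale or on the STRING integer [0, 1000] scale
    (detected per column: any value > 1 switches the column to /1000).
    Duplicate unordered pairs are merged keeping the channel-wise maximum;
    self-pairs are dropped with a logged count.
    """
    lines = iter(stream)
    header: list[str] | None = None
    for raw in lines:
        if raw.strip() and not raw.startswith("#"):
            header = raw.split()
            break
    if header is None:
        return []
    if len(header) < 3:
        raise InteractionFormatError(
            "header must name two protein columns and at least one score column; "
            f"got {header!r}"
        )
    channels = header[2:]

    rows: list[tuple[str, str, list[float]]] = []
    integer_scale = [False] * len(channels)
    n_self = 0
    for lineno, raw in enumerate(lines, start=2):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split()
        if len(parts) != len(header):
            raise InteractionFormatError(
                f"line {lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        a, b = parts[0], parts[1]
        try:
            scores = [float(x) for x in parts[2:]]
        except ValueError as exc:
            raise InteractionFormatError(f"line {lineno}: non-numeric score: {exc}")
        if a == b:
            n_self += 1
            continue
        for i, s in enumerate(scores):
            if s > 1.0:
                integer_scale[i] = True
        rows.append((a, b, scores))
    if n_self:
        logger.info("dropped %d self-interaction rows", n_self)

    merged: dict[tuple[str, str], dict[str, float]] = {}
    order: list[tuple[str, str]] = []
    for a, b, scores in rows:
        pair = (a, b) if a <= b else (b, a)
        values = {
            ch: (s / 1000.0 if integer_scale[i] else s)
            for i, (ch, s) in enumerate(zip(channels, scores))
        }
        if pair not in merged:
            merged[pair] = values
            order.append(pair)
        else:
            prev = merged[pair]
            for ch, s in values.items():
                prev[ch] = max(prev[ch], s)
    return [
        Interaction(protein_a=a, protein_b=b, channel_scores=merged[(a, b)])
        for a, b in order
    ]


def combine_channel_scores(*scores: float) -> float:
    """Combine independent evidence-channel scores with the noisy-OR rule.

    Returns ``1 - prod(1 - s_i)``: symmetric, at least the maximum input, and
    the raw score when only one channel carries evidence.
    """
    product = 1.0
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score out of [0, 1]: {s}")
        product *= 1.0 - s
    return 1.0 - product


def filter_interactions(
    interactions: Sequence[Interaction],
    channels: Iterable[str],
    min_score: float,
) -> list[Interaction]:
    """Keep interactions whose combined score over *channels* is >= *min_score*.

    Channels outside the selection are ignored entirely. Output order is the
    input order. Unknown channel names raise with the available names listed.
    """
    channels = sorted(set(channels))
    if not channels:
        raise ValueError("at least one channel must be selected")
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score out of [0, 1]: {min_score}")
    available: set[str] = set()
    for it in interactions:
        available.update(it.channel_scores)
    unknown = [ch for ch in channels if available and ch not in available]
    if unknown:
        raise KeyError(
            f"unknown channel(s) {unknown}; available: {sorted(available)}"
        )
    kept = []
    for it in interactions:
        combined = combine_channel_scores(
            *(it.channel_scores.get(ch, 0.0) for ch in channels)
        )
        if combined >= min_score:
            kept.append(it)
    return kept


def _retained_score(it: Interaction, channels: Sequence[str] | None) -> float:
    if channels is None:
        return combine_channel_scores(*it.channel_scores.values())
    return combine_channel_scores(*(it.channel_scores.get(ch, 0.0) for ch in channels))


def induced_subgraph(
    interactions: Sequence[Interaction],
    seeds: Sequence[SeedSet],
    channels: Sequence[str] | None = None,
) -> nx.Graph:
    """Build the seed-induced network: nodes are the seed union (isolated seed
    genes retained), edges are the given (already filtered) interactions with
    both endpoints in the union.

    Node attribute ``origin`` records seed membership: the pathway id for
    single-set members and a ``+``-joined label for shared genes.
    """
    union: set[str] = set()
    for seed in seeds:
        union |= seed.genes
    if not union:
        raise ValueError("seed union is empty")
    graph = nx.Graph()
    for gene in sorted(union):  # deterministic node order regardless of hashing
        labels = [s.pathway_id for s in seeds if gene in s.genes]
        graph.add_node(gene, origin="+".join(labels))
    for it in interactions:
        if it.protein_a in union and it.protein_b in union:
            graph.add_edge(
                it.protein_a, it.protein_b, score=_retained_score(it, channels)
            )
    return graph


def _main_component(graph: nx.Graph) -> set[str]:
    """Largest connected component; ties go to the one holding the
    lexicographically smallest node."""
    components = list(nx.connected_components(graph))
    if not components:
        return set()
    max_size = max(len(c) for c in components)
    return min((c for c in components if len(c) == max_size), key=min)


def _better_candidate(
    cand: tuple[int, int, str], best: tuple[int, int, str]
) -> bool:
    """(nodes joined desc, global degree desc, name asc)."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] < best[2]


def augment_with_connectors(
    global_interactions: Sequence[Interaction],
    seed_graph: nx.Graph,
    channels: Sequence[str] | None = None,
) -> AugmentationResult:
    """Greedily add non-seed connector proteins until the network is connected.

    Loop: find the main (largest) component; candidate connectors are non-seed
    proteins of the filtered global interaction universe adjacent to at least
    one main-component node and at least one node outside it. The candidate
    joining the most disconnected nodes wins; ties break by degree in the
    global universe, then lexicographically. The winner is added with all its
    edges to current graph nodes and labelled ``CON``. Terminates when the
    graph is connected or no candidate exists; leftover disconnected seed
    nodes are reported in ``unresolved`` with a logged warning.
    """
    graph = seed_graph.copy()
    seed_nodes = set(seed_graph.nodes)

    adjacency: dict[str, set[str]] = {}
    scores: dict[tuple[str, str], float] = {}
    for it in global_interactions:
        adjacency.setdefault(it.protein_a, set()).add(it.protein_b)
        adjacency.setdefault(it.protein_b, set()).add(it.protein_a)
        scores[it.pair] = _retained_score(it, channels)
    global_degree = {node: len(neigh) for node, neigh in adjacency.items()}

    connectors: list[str] = []
    while True:
        main = _main_component(graph)
        disconnected = set(graph.nodes) - main
        if not disconnected:
            break
        current = set(graph.nodes)
        best: tuple[int, int, str] | None = None
        for candidate, neighbours in adjacency.items():
            if candidate in seed_nodes or candidate in current:
                continue
            if not (neighbours & main):
                continue
            joined = len(neighbours & disconnected)
            if joined == 0:
                continue
            key = (joined, global_degree[candidate], candidate)
            if best is None or _better_candidate(key, best):
                best = key
        if best is None:
            logger.warning(
                "no connector available for %d disconnected node(s): %s",
                len(disconnected),
                sorted(disconnected),
            )
            return AugmentationResult(
                graph=graph, connectors=connectors, unresolved=disconnected
            )
        winner = best[2]
        graph.add_node(winner, origin=CONNECTOR_LABEL)
        for neighbour in adjacency[winner] & current:
            pair = tuple(sorted((winner, neighbour)))
            graph.add_edge(winner, neighbour, score=scores[pair])
        connectors.append(winner)
    return AugmentationResult(graph=graph, connectors=connectors, unresolved=set())


def read_seed_list(stream: IO[str] | Iterable[str], pathway_id: str) -> SeedSet:
    """Read a one-identifier-per-line seed gene list."""
    genes = {line.strip() for line in stream if line.strip() and not line.startswith("#")}
    return SeedSet(pathway_id=pathway_id, genes=frozenset(genes))


def apply_id_mapping(
    interactions: Sequence[Interaction], mapping: Mapping[str, str]
) -> list[Interaction]:
    """Rename interaction endpoints through a two-column identifier mapping
    (e.g. protein id -> gene symbol); unmapped identifiers pass through.
    Self-pairs created by the mapping are dropped."""
    out = []
    for it in interactions:
        a = mapping.get(it.protein_a, it.protein_a)
        b = mapping.get(it.protein_b, it.protein_b)
        if a == b:
            continue
        out.append(Interaction(protein_a=a, protein_b=b, channel_scores=it.channel_scores))
    return out


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0):.6g}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_connectors_json(result: AugmentationResult, path) -> None:
    payload = {
        "connectors": result.connectors,
        "unresolved": sorted(result.unresolved),
        "connected": result.is_connected,
        "n_nodes": result.graph.number_of_nodes(),
        "n_edges": result.graph.number_of_edges(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
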