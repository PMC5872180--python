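"""Cross-dataset replication of differential-expression calls and biomarker
nomination among central network nodes.

A gene "replicates" at level k when it is significant (adjusted p < alpha) in
at least k independent datasets and — for k >= 2 — all of its significant
calls share one direction of change. Central nodes (HB or NH-B) that replicate
in at least ``min_datasets`` datasets are nominated as candidate biomarkers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .topology import CENTRAL_CLASSES, CentralityRecord

__all__ = [
    "ConcordanceRecord",
    "BiomarkerNomination",
    "aggregate_calls",
    "tabulate_replication",
    "nominate_biomarkers",
    "concordance_frame",
]


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-gene cross-dataset significance/direction profile.

    ``calls`` maps dataset id -> (direction, p_adj); genes absent from a
    dataset appear as ("NS", nan). ``n_significant`` counts datasets with
    adjusted p < alpha; ``direction_concordant`` is true when all significant
    calls share one sign (vacuously true with < 2 significant calls).
    """

    gene: str
    calls: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    n_significant: int = 0
    direction_concordant: bool = True

    def replication_at_least(self, k: int) -> bool:
        if k <= 1:
            return self.n_significant >= k
        return self.n_significant >= k and self.direction_concordant

    @property
    def n_replicated(self) -> int:
        """Largest k at which the gene replicates (0 if never significant)."""
        if self.n_significant >= 2 and not self.direction_concordant:
            return 1 if self.n_significant >= 1 else 0
        return self.n_significant


@dataclass(frozen=True)
class BiomarkerNomination:
    gene: str
    node_class: str
    n_replicated: int
    directions: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.node_class not in CENTRAL_CLASSES:
            raise ValueError(
                f"nominated gene {self.gene!r} must be central (HB/NH-B), "
                f"got {self.node_class!r}"
            )


def aggregate_calls(
    de_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> list[ConcordanceRecord]:
    """Aggregate per-dataset DE tables (gene-indexed, with ``direction`` and
    ``p_adj`` columns) into one ConcordanceRecord per gene of the union.

    Dataset gene universes may differ; missing genes count as NS. Duplicate
    genes within one dataset are an error.
    """
    universe: set[str] = set()
    for dataset_id, table in de_tables.items():
        if table.index.duplicated().any():
            dupes = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"{dataset_id}: duplicate gene(s) {dupes[:5]}")
        universe.update(table.index)
    records = []
    for gene in sorted(universe):
        calls: dict[str, tuple[str, float]] = {}
        significant_directions: list[str] = []
        n_significant = 0
        for dataset_id, table in de_tables.items():
            if gene in table.index:
                row = table.loc[gene]
                direction, p_adj = str(row["direction"]), float(row["p_adj"])
            else:
                direction, p_adj = "NS", float("nan")
            calls[dataset_id] = (direction, p_adj)
            if p_adj < alpha and direction != "NS":
                n_significant += 1
                significant_directions.append(direction)
        concordant = len(set(significant_directions)) <= 1
        records.append(
            ConcordanceRecord(
                gene=gene,
                calls=calls,
                n_significant=n_significant,
                direction_concordant=concordant,
            )
        )
    return records


def tabulate_replication(
    records: Sequence[ConcordanceRecord],
    node_classes: Mapping[str, str],
    ks: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Count genes per (node class, replication level).

    Returns a frame indexed by node class with columns ``at_least_k`` and
    ``exactly_k`` for each k (exactly-k derived as at_least(k) −
    at_least(k+1)); both tallies are always emitted. Genes missing from
    ``node_classes`` are grouped under class "?".
    """
    if ks is None:
        d = max((len(r.calls) for r in records), default=1)
        ks = range(1, d + 1)
    ks = sorted(ks)
    classes = sorted({node_classes.get(r.gene, "?") for r in records} | set(node_classes.values()))
    counts = pd.DataFrame(
        0,
        index=pd.Index(classes, name="node_class"),
        columns=[f"at_least_{k}" for k in ks],
    )
    for record in records:
        cls = node_classes.get(record.gene, "?")
        for k in ks:
            if record.replication_at_least(k):
                counts.loc[cls, f"at_least_{k}"] += 1
    for k in ks:
        upper = counts[f"at_least_{k + 1}"] if k + 1 in ks else 0
        counts[f"exactly_{k}"] = counts[f"at_least_{k}"] - upper
    return counts


def nominate_biomarkers(
    records: Sequence[ConcordanceRecord],
    centrality: Sequence[CentralityRecord],
    min_datasets: int = 2,
) -> list[BiomarkerNomination]:
    """Nominate central (HB / NH-B) genes replicating in >= min_datasets
    datasets with one direction of change; sorted by replication count
    descending, then gene name."""
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    class_by_gene = {c.node: c.node_class for c in centrality}
    nominations = []
    for record in records:
        cls = class_by_gene.get(record.gene)
        if cls not in CENTRAL_CLASSES:
            continue
        if not record.replication_at_least(min_datasets):
            continue
        nominations.append(
            BiomarkerNomination(
                gene=record.gene,
                node_class=cls,
                n_replicated=record.n_replicated,
                directions={d: call[0] for d, call in record.calls.items()},
            )
        )
    nominations.sort(key=lambda n: (-n.n_replicated, n.gene))
    return nominations


def concordance_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Tabular view: per-dataset direction/p_adj plus summary columns."""
    dataset_ids = sorted({d for r in records for d in r.calls})
    rows = []
    for r in records:
        row: dict[str, object] = {"gene": r.gene}
        for d in dataset_ids:
            direction, p_adj = r.calls.get(d, ("NS", float("nan")))
            row[f"{d}_direction"] = direction
            row[f"{d}_p_adj"] = p_adj
        row["n_significant"] = r.n_significant
        row["direction_concordant"] = r.direction_concordant
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def write_nominations_json(nominations: Sequence[BiomarkerNomination], path) -> None:
    payload = [
        {
            "gene": n.gene,
            "node_class": n.node_class,
            "n_replicated": n.n_replicated,
            "directions": dict(n.directions),
        }
        for n in nominations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
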