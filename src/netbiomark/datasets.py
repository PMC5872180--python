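"""Bundled reference data.

The melanoma central-node table is a published worked example: the 27 central
nodes (8 hub-bottlenecks, 19 nonhub-bottlenecks) of a 294-node / 2995-edge
interactome merging the stem-cell pluripotency and calcium-signaling pathways,
with each node's degree, normalized betweenness, pathway-origin label, and
per-dataset differential-expression call (direction + BH-corrected p-value at
alpha = 0.05) across three melanoma metastasis vs. primary-tumor microarray
series (GSE8401, GSE46517, GSE15605). It exercises the classification and
concordance stages end to end without any external download.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_melanoma_central_nodes",
    "load_melanoma_network_summary",
    "melanoma_de_tables",
]

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def load_melanoma_central_nodes() -> pd.DataFrame:
    """The 27-row central-node reference table, indexed by gene symbol."""
    with (_DATA / "melanoma_central_nodes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene")


def load_melanoma_network_summary() -> dict:
    """Whole-network statistics (node/edge counts, centrality mean/SD/threshold
    per metric, dataset ids, alpha) for the same study."""
    with (_DATA / "melanoma_network_summary.json").open() as fh:
        return json.load(fh)


def melanoma_de_tables() -> dict[str, pd.DataFrame]:
    """Reshape the reference table into per-dataset DE tables (gene-indexed,
    ``direction`` + ``p_adj`` columns) as consumed by the concordance stage."""
    table = load_melanoma_central_nodes()
    summary = load_melanoma_network_summary()
    out: dict[str, pd.DataFrame] = {}
    for dataset_id in summary["datasets"]:
        out[dataset_id] = pd.DataFrame(
            {
                "direction": table[f"{dataset_id}_direction"],
                "p_adj": table[f"{dataset_id}_p_adj"],
            }
        )
    return out
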