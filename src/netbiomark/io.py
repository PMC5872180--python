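"""Readers and writers for the pipeline's tabular interchange formats.

Everything is plain text: tab-delimited tables for matrices and results,
GraphML for graphs, JSON for nominations and manifests.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .diffexpr import ExpressionDataset
from .interactome import Interaction, SeedSet, parse_interaction_table, read_seed_list

__all__ = [
    "read_interactions",
    "read_seeds",
    "read_id_mapping",
    "read_expression_dataset",
    "write_expression_dataset",
    "write_de_table",
    "read_de_table",
]


def read_interactions(path) -> list[Interaction]:
    with open(path) as fh:
        return parse_interaction_table(fh)


def read_seeds(path, pathway_id: str | None = None) -> SeedSet:
    path = Path(path)
    with open(path) as fh:
        return read_seed_list(fh, pathway_id or path.stem)


def read_id_mapping(path) -> dict[str, str]:
    """Two-column TSV (source id, target id), no header required."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: identifier mapping needs two columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def read_expression_dataset(
    matrix_path, groups_path, dataset_id: str | None = None
) -> ExpressionDataset:
    """Expression TSV (first column gene id, remaining columns samples) plus a
    two-column sample annotation TSV (sample id, group)."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    annotation = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"], dtype=str,
        comment="#",
    )
    if annotation.iloc[0, 0] in ("sample", "sample_id"):  # tolerate a header row
        annotation = annotation.iloc[1:]
    groups = pd.Series(annotation["group"].values, index=annotation["sample"].values)
    return ExpressionDataset(
        dataset_id=dataset_id or Path(matrix_path).stem,
        matrix=matrix,
        groups=groups,
    )


def write_expression_dataset(dataset: ExpressionDataset, matrix_path, groups_path) -> None:
    dataset.matrix.to_csv(matrix_path, sep="\t", float_format="%.6g")
    with open(groups_path, "w") as fh:
        for sample, group in dataset.groups.items():
            fh.write(f"{sample}\t{group}\n")


_DE_COLUMNS = ["log_fc", "t_mod", "df_total", "p_raw", "p_adj", "direction"]


def write_de_table(table: pd.DataFrame, path) -> None:
    table[_DE_COLUMNS].to_csv(path, sep="\t", float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
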