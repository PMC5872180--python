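import numpy as np
import pandas as pd
import pytest

from netbiomark.datasets import (
    load_melanoma_central_nodes,
    load_melanoma_network_summary,
    melanoma_de_tables,
)
from netbiomark.diffexpr import ExpressionDataset


@pytest.fixture(scope="session")
def central_node_table() -> pd.DataFrame:
    return load_melanoma_central_nodes()


@pytest.fixture(scope="session")
def network_summary() -> dict:
    return load_melanoma_network_summary()


@pytest.fixture(scope="session")
def reference_de_tables() -> dict[str, pd.DataFrame]:
    return melanoma_de_tables()


def make_dataset(
    values: np.ndarray,
    n_control: int,
    n_case: int,
    dataset_id: str = "test",
    genes: list[str] | None = None,
) -> ExpressionDataset:
    """Wrap a (genes × samples) array as an ExpressionDataset; the first
    n_control columns are controls."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix, groups=groups)
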