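import numpy as np
import pandas as pd
import pytest

from stimflow.io_core import (
    CLUSTER_COL,
    REPLICATE_COL,
    TIME_COL,
    ExpressionDataset,
    TimepointDesign,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def four_tp_design():
    return TimepointDesign(("control", "3h", "24h", "72h"))


def make_dataset(matrix, time=None, replicate=None, cluster=None, gene_names=None,
                 state="raw"):
    """Build a small ExpressionDataset with optional metadata columns."""
    matrix = np.asarray(matrix, dtype=float)
    n, g = matrix.shape
    meta = pd.DataFrame(index=pd.Index([f"cell{i}" for i in range(n)], name="barcode"))
    if time is not None:
        meta[TIME_COL] = list(time)
    if replicate is not None:
        meta[REPLICATE_COL] = list(replicate)
    if cluster is not None:
        meta[CLUSTER_COL] = list(cluster)
    genes = gene_names if gene_names is not None else [f"g{j}" for j in range(g)]
    return ExpressionDataset(matrix=matrix, cell_meta=meta, gene_names=genes,
                             state=state)


@pytest.fixture
def toy_counts():
    """5 cells x 4 genes raw counts incl. one mitochondrial gene."""
    mat = np.array(
        [
            [5, 3, 2, 0],   # clean
            [1, 1, 0, 2],   # 50% mito
            [4, 0, 0, 0],   # only 1 unique gene
            [2, 2, 2, 0],   # clean
            [3, 1, 4, 1],   # ~11% mito
        ],
        dtype=float,
    )
    return make_dataset(mat, gene_names=["g0", "g1", "g2", "mt-Nd1"])
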