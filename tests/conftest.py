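import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scatlas import io_core, synthetic_data


def make_matrix(counts: np.ndarray, cell_ids=None, gene_ids=None) -> io_core.ExpressionMatrix:
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = cell_ids or [f"cell{i}" for i in range(n_cells)]
    gene_ids = gene_ids or [f"gene{j}" for j in range(n_genes)]
    return io_core.ExpressionMatrix(cell_ids, gene_ids, sp.csr_matrix(counts))


def normalized(counts, **kwargs) -> io_core.ExpressionMatrix:
    return io_core.normalize_log2_tpm(make_matrix(counts, **kwargs))


@pytest.fixture(scope="session")
def default_cohort():
    """The stock synthetic cohort, QC'd and normalized, with ground truth."""
    cfg = synthetic_data.default_config(seed=1)
    matrix, annotation, genes, truth = synthetic_data.simulate_counts(cfg)
    matrix = io_core.qc_filter_cells(matrix)
    matrix = io_core.filter_genes(matrix)
    matrix = io_core.normalize_log2_tpm(matrix)
    annotation = annotation.subset(matrix.cell_ids)
    return matrix, annotation, genes, truth, cfg


@pytest.fixture()
def tiny_annotation():
    rows = []
    for i, (subset, lineage, origin, sample) in enumerate(
        [
            ("Tcell", "T/NK", "tLung", "tLung_S1"),
            ("Tcell", "T/NK", "nLung", "nLung_S1"),
            ("Myeloid", "Myeloid", "tLung", "tLung_S1"),
            ("Myeloid", "Myeloid", "nLung", "nLung_S1"),
            ("AT2", "Epithelial", "nLung", "nLung_S1"),
            ("Malignant", "Epithelial", "tLung", "tLung_S1"),
        ]
    ):
        rows.append(
            {
                "cell_id": f"cell{i}",
                "sample_id": sample,
                "tissue_origin": origin,
                "lineage": lineage,
                "subset": subset,
            }
        )
    return io_core.CellAnnotation(pd.DataFrame(rows))
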