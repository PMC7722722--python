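import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import immscape as im


def make_matrix(counts, genes=None, barcodes=None, meta=None):
    """Build an ExpressionMatrix from a dense array of counts (genes x cells)."""
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"C{i}" for i in range(counts.shape[1])]
    if meta is not None and not isinstance(meta, pd.DataFrame):
        meta = pd.DataFrame(meta, index=barcodes)
    return im.ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=pd.Index(genes),
        cell_barcodes=pd.Index(barcodes),
        cell_meta=meta,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down default cohort shared by read-only tests."""
    return im.simulate_cohort(im.default_config(seed=11, cells_per_sample=250))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
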