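import numpy as np
import pandas as pd
import pytest

import emtdecouple as ed
import emtdecouple.sc as scm


@pytest.fixture(scope="session")
def default_config():
    return ed.SyntheticConfig(n_cells=800, seed=0)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One fully generated synthetic study: single cells, bulk, cell lines."""
    matrix, meta, positions, truth = ed.generate_sc_dataset(default_config)
    bulk = ed.generate_bulk_cohort(default_config, truth)
    celllines = ed.generate_cellline_profiles(default_config, truth)
    return {
        "config": default_config,
        "matrix": matrix,
        "sclog": scm.normalize_tpm(matrix),
        "meta": meta,
        "positions": positions,
        "truth": truth,
        "bulk": bulk,
        "celllines": celllines,
    }


@pytest.fixture(scope="session")
def deconv_result(dataset):
    truth = dataset["truth"]
    return ed.run_deconvolution(dataset["bulk"].expression, truth.esg_genes,
                                markers_per_type=truth.confounder_genes)


def two_block_correlation(n: int = 20, within: float = 0.9,
                          between: float = -0.6) -> pd.DataFrame:
    """Noiseless two-block correlation matrix (first half vs second half)."""
    half = n // 2
    corr = np.full((n, n), between)
    corr[:half, :half] = within
    corr[half:, half:] = within
    np.fill_diagonal(corr, 1.0)
    genes = [f"g{i:02d}" for i in range(n)]
    return pd.DataFrame(corr, index=genes, columns=genes)


def end_recovery(result, truth):
    """Fraction of the top-20 genes at each end matching its best planted
    program (returns min over the two ends)."""
    pemt, caf = set(truth.pemt_genes), set(truth.caf_genes)
    a = set(result.top_genes("endA", 20))
    b = set(result.top_genes("endB", 20))
    orientations = [(len(a & pemt) + len(b & caf)), (len(a & caf) + len(b & pemt))]
    if orientations[0] >= orientations[1]:
        return min(len(a & pemt) / 20, len(b & caf) / 20)
    return min(len(a & caf) / 20, len(b & pemt) / 20)
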