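"""EMT-signature-gene (ESG) list assembly and single-cell filtering.

A cancer type's ESG list is the union of three sources: a Hallmark-style EMT
set, a Tan-style tumour+cell-line EMT set, and genes in the top fraction of
average bulk correlation with the six classical EMT markers.  Single-cell
filters then remove genes whose expression peaks in a cell type other than
cancer cells or CAFs, and genes below a mean-TPM threshold.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import (CLASSICAL_EMT_MARKERS, EsgList, ExpressionMatrix,
                         SCALE_TPM)


def bulk_marker_correlated_genes(bulk: ExpressionMatrix,
                                 markers=CLASSICAL_EMT_MARKERS,
                                 top_frac: float = 0.01) -> list[str]:
    """Genes in the top ``top_frac`` of mean Pearson correlation with the
    classical EMT markers (markers themselves are eligible candidates).

    Constant genes have undefined correlations and are excluded.  The cutoff
    is ``ceil(top_frac * n_candidates)`` with ties broken by stable gene order.
    """
    present = [m for m in markers if m in bulk.data.index]
    if not present:
        raise ValueError("no EMT marker present in the bulk matrix")
    data = bulk.data
    sd = data.std(axis=1)
    candidates = data.loc[sd > 0]
    marker_block = data.loc[present]

    x = candidates.to_numpy()
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    m = marker_block.to_numpy()
    msd = m.std(axis=1, keepdims=True)
    m = np.where(msd > 0, (m - m.mean(axis=1, keepdims=True)) / msd, 0.0)
    corr = x @ m.T / x.shape[1]            # candidates x markers
    mean_corr = pd.Series(corr.mean(axis=1), index=candidates.index)

    k = math.ceil(top_frac * len(mean_corr))
    order = mean_corr.sort_values(ascending=False, kind="stable")
    return list(order.index[:k])


def assemble_esgs(hallmark, tan, bulk_correlated,
                  cancer_type: str = "synthetic") -> EsgList:
    """Union of the three source sets with per-gene source tags, sorted."""
    sources = {"hallmark": set(hallmark), "tan": set(tan),
               "bulk_correlated": set(bulk_correlated)}
    for name, genes in sources.items():
        if not genes:
            raise ValueError(f"empty source gene set: {name}")
    union = sorted(set().union(*sources.values()))
    tags = [tuple(tag for tag in ("hallmark", "tan", "bulk_correlated")
                  if g in sources[tag]) for g in union]
    table = pd.DataFrame({"sources": tags, "status": "kept"}, index=pd.Index(union, name="gene"))
    return EsgList(table, cancer_type=cancer_type)


def filter_esgs_by_celltype(esgs: EsgList, sc_matrix: ExpressionMatrix,
                            meta: pd.DataFrame) -> EsgList:
    """Flag genes whose mean expression peaks in a cell type other than cancer
    or CAF as ``removed_celltype``.  Ties involving cancer/CAF favour
    retention (the filter removes only strictly dominated genes).
    """
    counts = meta["cell_type"].value_counts()
    types = [t for t in counts.index if counts[t] > 0]
    if "cancer" not in types or "CAF" not in types:
        raise ValueError("need at least one cancer cell and one CAF")

    genes = [g for g in esgs.genes if g in sc_matrix.data.index]
    means = pd.DataFrame(index=genes, columns=types, dtype=float)
    cells_by_type = meta.groupby("cell_type")["cell_id"]
    for t in types:
        cells = [c for c in cells_by_type.get_group(t) if c in sc_matrix.data.columns]
        means[t] = sc_matrix.data.loc[genes, cells].mean(axis=1)

    out = esgs.copy()
    max_mean = means.max(axis=1)
    focal_max = means[["cancer", "CAF"]].max(axis=1)
    removed = means.index[focal_max < max_mean]
    mask = out.table.index.isin(removed) & (out.table["status"] == "kept")
    out.table.loc[mask, "status"] = "removed_celltype"
    return out


def filter_esgs_by_expression(esgs: EsgList, sc_matrix: ExpressionMatrix,
                              threshold: float, over=None) -> EsgList:
    """Flag genes whose mean TPM over the given cells is <= threshold (the
    rule keeps genes strictly above it) as ``removed_expression``."""
    if sc_matrix.scale != SCALE_TPM:
        raise ValueError("expression filter operates on the TPM scale")
    if over is not None:
        over = [c for c in over if c in sc_matrix.data.columns]
        if not over:
            raise ValueError("empty cell set for the expression filter")
        data = sc_matrix.data[over]
    else:
        data = sc_matrix.data
    genes = [g for g in esgs.genes if g in data.index]
    means = data.loc[genes].mean(axis=1)
    removed = means.index[means <= threshold]
    out = esgs.copy()
    mask = out.table.index.isin(removed) & (out.table["status"] == "kept")
    out.table.loc[mask, "status"] = "removed_expression"
    return out


def write_esg_tsv(esgs: EsgList, path) -> None:
    table = esgs.table.copy()
    table["sources"] = [",".join(t) for t in table["sources"]]
    table.to_csv(path, sep="\t", index_label="gene")


def read_esg_tsv(path, cancer_type: str = "synthetic") -> EsgList:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    table["sources"] = [tuple(s.split(",")) if isinstance(s, str) and s else ()
                        for s in table["sources"]]
    return EsgList(table, cancer_type=cancer_type)
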