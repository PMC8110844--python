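"""Core in-memory containers shared across the package.

Expression data is kept as a genes x samples :class:`pandas.DataFrame` wrapped
in :class:`ExpressionMatrix`, which carries the scale tag (``tpm`` for linear
transcripts-per-million, ``log2_tpm10`` for log2(TPM/10 + 1)).  Cell metadata
is a plain DataFrame with a required column contract, validated by
:func:`validate_cell_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALE_TPM = "tpm"
SCALE_LOG2_TPM10 = "log2_tpm10"

#: classical EMT markers: Vimentin plus the five core EMT transcription factors
CLASSICAL_EMT_MARKERS = ("SNAI1", "SNAI2", "TWIST1", "VIM", "ZEB1", "ZEB2")

MALIGNANT_FLAGS = ("malignant", "non_malignant", "excluded", "unassigned")

CELL_META_COLUMNS = ("cell_id", "patient_id", "cell_type", "malignant")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample/cell ids as columns.
    scale
        ``"tpm"`` or ``"log2_tpm10"``.
    """

    data: pd.DataFrame
    scale: str = SCALE_TPM

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_TPM, SCALE_LOG2_TPM10):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if values.size and values.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], scale=self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)], scale=self.scale)


def validate_cell_metadata(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check the cell metadata column contract; returns the frame unchanged."""
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns {missing}")
    if meta["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in metadata")
    bad = set(meta["malignant"]) - set(MALIGNANT_FLAGS)
    if bad:
        raise ValueError(f"unknown malignant flags {sorted(bad)}")
    if matrix is not None:
        absent = set(meta["cell_id"]) - set(matrix.sample_ids)
        if absent:
            raise ValueError(f"{len(absent)} metadata cells absent from matrix")
    return meta


@dataclass
class EsgList:
    """Ordered, source-tagged EMT signature genes for one cancer type.

    ``table`` is indexed by gene id with columns ``sources`` (tuple of tags
    from {hallmark, tan, bulk_correlated}) and ``status`` (one of ``kept``,
    ``removed_celltype``, ``removed_expression``).
    """

    table: pd.DataFrame
    cancer_type: str = "synthetic"

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate genes in ESG list")
        allowed = {"kept", "removed_celltype", "removed_expression"}
        bad = set(self.table["status"]) - allowed
        if bad:
            raise ValueError(f"unknown ESG status values {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def kept_genes(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "kept"])

    def copy(self) -> "EsgList":
        return EsgList(self.table.copy(), cancer_type=self.cancer_type)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    The generator guarantees that pemt/caf/shared gene sets are pairwise
    disjoint and that every planted gene exists in the generated matrices.
    """

    pemt_genes: list[str]
    caf_genes: list[str]
    shared_genes: list[str]
    confounder_genes: dict[str, list[str]] = field(default_factory=dict)
    cna_blocks: list[tuple[str, int, int, float]] = field(default_factory=list)
    caf_fraction: pd.Series | None = None
    pemt_fraction: pd.Series | None = None
    clinical_effect: tuple[str, str, float] | None = None

    def __post_init__(self) -> None:
        sets = [set(self.pemt_genes), set(self.caf_genes), set(self.shared_genes)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("planted gene programs must be pairwise disjoint")
        for frac in (self.caf_fraction, self.pemt_fraction):
            if frac is not None:
                arr = np.asarray(frac, dtype=float)
                if arr.size and (arr.min() < 0 or arr.max() > 1):
                    raise ValueError("fractions must lie in [0, 1]")

    @property
    def esg_genes(self) -> list[str]:
        return list(self.pemt_genes) + list(self.caf_genes) + list(self.shared_genes)
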