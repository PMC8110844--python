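"""Readers and writers for the plain-text formats used by the pipeline.

Expression travels as dense TSV or MatrixMarket + id sidecars, gene positions
as BED (0-based half-open), gene sets as GMT, tables as TSV and ground truth
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, GroundTruth


# ---------------------------------------------------------------- expression

def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path, scale: str) -> ExpressionMatrix:
    data = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(data, scale=scale)


def write_expression_mtx(matrix: ExpressionMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.tsv``/``.samples.tsv``."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(matrix.data.to_numpy()))
    pd.Series(matrix.gene_ids).to_csv(prefix.parent / (prefix.name + ".genes.tsv"),
                                      sep="\t", index=False, header=False)
    pd.Series(matrix.sample_ids).to_csv(prefix.parent / (prefix.name + ".samples.tsv"),
                                        sep="\t", index=False, header=False)


def read_expression_mtx(prefix, scale: str) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = pd.read_csv(prefix.parent / (prefix.name + ".genes.tsv"), sep="\t", header=None)[0]
    samples = pd.read_csv(prefix.parent / (prefix.name + ".samples.tsv"), sep="\t", header=None)[0]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


# ------------------------------------------------------------ gene positions

def write_bed(positions: pd.DataFrame, path) -> None:
    """Write gene positions (columns chrom/start/end/gene) as 4-column BED."""
    positions[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    pos = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene"])
    return pos


# ------------------------------------------------------------------ gene sets

def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# --------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "pemt_genes": list(truth.pemt_genes),
        "caf_genes": list(truth.caf_genes),
        "shared_genes": list(truth.shared_genes),
        "confounder_genes": {k: list(v) for k, v in truth.confounder_genes.items()},
        "cna_blocks": [list(b) for b in truth.cna_blocks],
        "caf_fraction": None if truth.caf_fraction is None else truth.caf_fraction.to_dict(),
        "pemt_fraction": None if truth.pemt_fraction is None else truth.pemt_fraction.to_dict(),
        "clinical_effect": list(truth.clinical_effect) if truth.clinical_effect else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        pemt_genes=payload["pemt_genes"],
        caf_genes=payload["caf_genes"],
        shared_genes=payload["shared_genes"],
        confounder_genes=payload.get("confounder_genes", {}),
        cna_blocks=[tuple(b) for b in payload.get("cna_blocks", [])],
        caf_fraction=None if payload.get("caf_fraction") is None else pd.Series(payload["caf_fraction"]),
        pemt_fraction=None if payload.get("pemt_fraction") is None else pd.Series(payload["pemt_fraction"]),
        clinical_effect=None if payload.get("clinical_effect") is None else tuple(payload["clinical_effect"]),
    )
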