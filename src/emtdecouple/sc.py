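"""Single-cell preprocessing, signature scoring and CNA-based malignant calls.

Scoring follows the control-gene-set scheme: genes are binned by average
expression, each signature gene is compared against ``n`` bin-matched control
genes, and the cell score is the mean relative expression over the signature.
This controls for per-cell complexity (genes detected), which would otherwise
inflate any naive mean-expression score.

CNA inference orders genes by chromosomal location, takes a per-chromosome
moving average of relative expression (window of 100 genes by default,
centred, truncated at chromosome ends) and recentres against the average
profile of a reference set of non-malignant cells.  CAFs must not be in the
reference, since downstream analysis distinguishes cancer cells from CAFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SCALE_LOG2_TPM10, SCALE_TPM


def normalize_tpm(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Convert TPM to log2(TPM/10 + 1).

    Dividing by 10 reflects an upper-bound estimate of ~100,000 transcripts in
    a single-cell library.
    """
    if raw.scale != SCALE_TPM:
        raise ValueError("normalize_tpm expects a TPM-scale matrix")
    return ExpressionMatrix(np.log2(raw.data / 10.0 + 1.0), scale=SCALE_LOG2_TPM10)


def genes_detected(matrix: ExpressionMatrix) -> pd.Series:
    """Number of genes with strictly positive expression per cell."""
    return (matrix.data > 0).sum(axis=0)


def filter_low_complexity_cells(matrix: ExpressionMatrix, min_genes: int = 1000,
                                meta: pd.DataFrame | None = None):
    """Drop cells with fewer than ``min_genes`` genes detected (strict <).

    Returns the filtered matrix, or ``(matrix, meta)`` when metadata is given.
    """
    keep = genes_detected(matrix) >= min_genes
    if not keep.any():
        raise ValueError("no cells left after complexity filtering")
    out = ExpressionMatrix(matrix.data.loc[:, keep[keep].index], scale=matrix.scale)
    if meta is None:
        return out
    kept_meta = meta[meta["cell_id"].isin(out.sample_ids)].reset_index(drop=True)
    return out, kept_meta


# ----------------------------------------------------------------- scoring

@dataclass
class ScoringConfig:
    """Control-binned scoring parameters.

    ``n_bins`` (m) expression bins; ``n_controls`` (n) control genes sampled
    (with replacement) per signature gene; ``min_expression`` drops genes whose
    average expression is at or below the threshold before binning;
    ``group_key`` makes binning/sampling/scoring run independently per group
    (e.g. per tumour).
    """

    n_bins: int = 25
    n_controls: int = 100
    min_expression: float | None = None
    group_key: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_controls < 1:
            raise ValueError("n_bins and n_controls must be >= 1")


def _score_one_group(data: pd.DataFrame, signature: list[str],
                     cfg: ScoringConfig, rng: np.random.Generator) -> pd.Series:
    mean_expr = data.mean(axis=1)
    if cfg.min_expression is not None:
        data = data.loc[mean_expr > cfg.min_expression]
        mean_expr = mean_expr.loc[data.index]
    sig = [g for g in signature if g in data.index]
    if not sig:
        raise ValueError("signature empty after the minimum-expression filter")
    if cfg.n_bins > data.shape[0]:
        raise ValueError("more bins than available genes")

    order = mean_expr.sort_values(kind="stable").index
    bins = np.array_split(np.arange(len(order)), cfg.n_bins)
    bin_of = pd.Series(
        np.concatenate([np.full(len(b), i) for i, b in enumerate(bins)]), index=order)
    bin_members = {i: order[b] for i, b in enumerate(bins)}

    values = data.to_numpy()
    row_of = {g: i for i, g in enumerate(data.index)}
    rel = np.zeros((len(sig), data.shape[1]))
    for k, g in enumerate(sig):
        pool = bin_members[bin_of[g]]
        controls = rng.choice(len(pool), size=cfg.n_controls, replace=True)
        control_rows = [row_of[pool[c]] for c in controls]
        rel[k] = values[row_of[g]] - values[control_rows].mean(axis=0)
    return pd.Series(rel.mean(axis=0), index=data.columns)


def score_signature(matrix: ExpressionMatrix, signature, cfg: ScoringConfig,
                    meta: pd.DataFrame | None = None) -> pd.Series:
    """Per-cell control-binned signature score.

    With ``cfg.group_key`` set, ``meta`` must map cells to groups and the whole
    procedure runs separately within each group.
    """
    signature = list(signature)
    if cfg.group_key is None:
        rng = np.random.default_rng(cfg.seed)
        return _score_one_group(matrix.data, signature, cfg, rng)
    if meta is None:
        raise ValueError("group scoring requires cell metadata")
    scores = []
    groups = meta.groupby(cfg.group_key, sort=True)["cell_id"]
    for gi, (_, cells) in enumerate(groups):
        rng = np.random.default_rng([cfg.seed, gi])
        cells = [c for c in cells if c in matrix.data.columns]
        scores.append(_score_one_group(matrix.data[cells], signature, cfg, rng))
    return pd.concat(scores).reindex(matrix.sample_ids)


def naive_mean_score(matrix: ExpressionMatrix, signature) -> pd.Series:
    """Plain mean expression over the signature (the complexity-biased baseline)."""
    sig = [g for g in signature if g in matrix.data.index]
    return matrix.data.loc[sig].mean(axis=0)


# ------------------------------------------------------------------- CNA

@dataclass
class CnaResult:
    """Windowed CNA values (chromosome-ordered genes x cells)."""

    values: pd.DataFrame
    window: int
    positions: pd.DataFrame


def infer_cna(matrix: ExpressionMatrix, positions: pd.DataFrame,
              reference: set[str] | list[str], window: int = 100) -> CnaResult:
    """Moving-average CNA estimate recentred on a reference-cell profile.

    Windows restart at chromosome boundaries and shrink near the ends
    (centred, truncated).  If a chromosome holds fewer genes than the window,
    the window shrinks to the chromosome length.
    """
    reference = [c for c in reference if c in matrix.data.columns]
    if not reference:
        raise ValueError("empty reference cell set")
    if matrix.scale != SCALE_LOG2_TPM10:
        raise ValueError("infer_cna expects log2(TPM/10+1) input")

    pos = positions[positions["gene"].isin(matrix.data.index)]
    pos = pos.sort_values(["chrom", "start"], kind="stable")
    data = matrix.data.loc[pos["gene"]]

    relative = data.sub(data.mean(axis=1), axis=0)
    # per-cell centring removes library-size / complexity offsets that would
    # otherwise masquerade as genome-wide copy-number shifts
    relative = relative.sub(relative.mean(axis=0), axis=1)
    smoothed = []
    for chrom, idx in pos.groupby("chrom", sort=False).groups.items():
        block = relative.loc[pos.loc[idx, "gene"]]
        win = min(window, block.shape[0])
        smoothed.append(block.rolling(win, center=True, min_periods=1).mean())
    values = pd.concat(smoothed)
    values = values.sub(values[reference].mean(axis=1), axis=0)
    return CnaResult(values=values, window=window, positions=pos.reset_index(drop=True))


def cna_summary(cna: CnaResult, malignant_seed: set[str] | list[str],
                subclones: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-cell CNA signal (mean of squared CNA values) and CNA correlation
    (Pearson with the mean profile of the malignant seed; with subclones, the
    best-matching subclone's value)."""
    seed_cells = [c for c in malignant_seed if c in cna.values.columns]
    if not seed_cells:
        raise ValueError("empty malignant seed")
    signal = (cna.values ** 2).mean(axis=0)

    def _corr_with(profile: np.ndarray) -> pd.Series:
        if np.std(profile) == 0:
            return pd.Series(np.nan, index=cna.values.columns)
        mat = cna.values.to_numpy()
        sd = mat.std(axis=0)
        centred = mat - mat.mean(axis=0)
        p = profile - profile.mean()
        num = centred.T @ p / len(p)
        denom = sd * p.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / denom, np.nan)
        return pd.Series(r, index=cna.values.columns)

    if subclones:
        corrs = pd.concat(
            [_corr_with(cna.values[[c for c in cells if c in cna.values.columns]]
                        .mean(axis=1).to_numpy())
             for cells in subclones.values()], axis=1)
        correlation = corrs.max(axis=1)
    else:
        correlation = _corr_with(cna.values[seed_cells].mean(axis=1).to_numpy())
    return pd.DataFrame({"cna_signal": signal, "cna_correlation": correlation})


#: default thresholds for the synthetic data only; on real data these are
#: chosen per tumour by inspecting the CNA signal/correlation distributions
DEFAULT_SYNTHETIC_CNA_THRESHOLDS = (0.10, 0.13, 0.5, 0.75)


def classify_malignant(summary: pd.DataFrame,
                       thresholds: tuple[float, float, float, float]) -> pd.Series:
    """Two-threshold malignant call: below both lows -> non-malignant, above
    both highs -> malignant, anything intermediate -> excluded."""
    signal_lo, signal_hi, corr_lo, corr_hi = thresholds
    if signal_lo > signal_hi or corr_lo > corr_hi:
        raise ValueError("low thresholds must not exceed high thresholds")
    sig = summary["cna_signal"]
    corr = summary["cna_correlation"].fillna(-np.inf)
    flags = pd.Series("excluded", index=summary.index)
    flags[(sig < signal_lo) & (corr < corr_lo)] = "non_malignant"
    flags[(sig > signal_hi) & (corr > corr_hi)] = "malignant"
    return flags


# -------------------------------------------- epithelial markers vs EMT score

def filter_epithelial_markers(matrix_tpm: ExpressionMatrix, universe,
                              mean_tpm_threshold: float = 10.0,
                              high_log2: float = 7.0,
                              high_frac: float = 0.01) -> list[str]:
    """Keep markers with mean TPM above threshold OR log2(TPM/10+1) >= 7 in at
    least 1% of cells."""
    markers = [g for g in universe if g in matrix_tpm.data.index]
    data = matrix_tpm.data.loc[markers]
    mean_ok = data.mean(axis=1) > mean_tpm_threshold
    high_ok = (np.log2(data / 10.0 + 1.0) >= high_log2).mean(axis=1) >= high_frac
    return list(data.index[mean_ok | high_ok])


def epithelial_emt_correlation(matrix: ExpressionMatrix, meta: pd.DataFrame,
                               markers, emt_scores: pd.Series,
                               tumour_key: str = "patient_id"):
    """Average within-tumour Pearson correlation of each epithelial marker with
    the EMT score, plus per-gene z-scored relative expression for display.

    Tumours where a marker is constant are omitted from that marker's average.
    """
    markers = [g for g in markers if g in matrix.data.index]
    per_tumour = []
    for _, cells in meta.groupby(tumour_key, sort=True)["cell_id"]:
        cells = [c for c in cells if c in matrix.data.columns]
        if len(cells) < 3:
            continue
        score = emt_scores.loc[cells]
        if score.std() == 0:
            continue
        block = matrix.data.loc[markers, cells]
        sd = block.std(axis=1)
        r = block.T.corrwith(score)
        r[sd == 0] = np.nan
        per_tumour.append(r)
    if not per_tumour:
        raise ValueError("no tumour with enough cells for correlation")
    avg = pd.concat(per_tumour, axis=1).mean(axis=1)

    block = matrix.data.loc[markers]
    sd = block.std(axis=1).replace(0, np.nan)
    zscores = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    return avg, zscores
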