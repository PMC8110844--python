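"""Validation tracks and pEMT/CAF annotation of the ordering ends.

Three independent measures are aligned to the refined gene order as running
averages (window 30, centred, truncated at the ends):

* purity track -- correlation of centred expression with tumour purity; the
  cancer (pEMT) end correlates positively with purity, the CAF end negatively;
* cell-line track -- observed tumour mean minus a robust local-regression
  prediction from cell-line means; positive = higher in tumours than in
  cancer-only cell lines, i.e. stroma-enriched (CAF side);
* single-cell track -- per-cell relative ESG expression of cancer cells and
  CAFs, centred on the cancer/CAF midpoint; cancer cells run high at the pEMT
  end, CAFs at the CAF end.

The end labels follow the majority of available measures with the single-cell
evidence (the most direct measure) breaking ties; a purity track that opposes
the other measures without single-cell backing marks the dataset for
exclusion.  Robustness QC regresses each cell type's marker correlations on
ordering position and excludes datasets where any slope <= -0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix
from .deconvolve import ConfounderModel, DeconvolutionResult


def running_average(values: pd.Series, window: int = 30) -> pd.Series:
    """Centred moving average truncated at the ends (window shrinks)."""
    return values.rolling(window, center=True, min_periods=1).mean()


# ------------------------------------------------------------------- tracks

def purity_track(bulk: ExpressionMatrix, order: list[str], purity: pd.Series,
                 window: int = 30) -> pd.DataFrame:
    """Running average of per-gene correlations of centred expression with
    purity, aligned to the gene order."""
    order = [g for g in order if g in bulk.data.index]
    purity = purity.reindex(bulk.sample_ids)
    if purity.isna().mean() > 0.5:
        raise ValueError("purity missing for more than half the samples")
    keep = purity.notna()
    purity = purity[keep]
    if purity.std() == 0:
        raise ValueError("purity is constant; correlations undefined")
    data = bulk.data.loc[order, keep[keep].index]
    centred = data.sub(data.mean(axis=0), axis=1)    # E' = E - per-sample ESG mean
    corr = centred.T.corrwith(purity)
    return pd.DataFrame({"correlation": corr,
                         "track": running_average(corr, window)})


def cellline_track(tumour_mean: pd.Series, cellline_mean: pd.Series,
                   order: list[str], window: int = 30, span: float = 0.25,
                   robust_iter: int = 4) -> pd.DataFrame:
    """Tumour-vs-cell-line comparison score along the gene order.

    A local linear regression (tricube-weighted, robust reweighting) of tumour
    means on cell-line means over all shared genes gives a per-gene prediction;
    the score is observed minus predicted (positive = tumour-enriched), centred
    over the ordered genes and max-normalized so the track lies in [-1, 1].
    """
    shared = tumour_mean.index.intersection(cellline_mean.index)
    if len(shared) < 50:
        raise ValueError("too few shared genes for a stable local regression")
    if len(shared) < 500:
        warnings.warn("fewer than 500 shared genes; local regression may be unstable")
    x = cellline_mean.loc[shared]
    y = tumour_mean.loc[shared]
    if x.std() == 0:
        raise ValueError("cell-line means are constant; fit degenerate")
    order = [g for g in order if g in shared]
    predicted = lowess(y.to_numpy(), x.to_numpy(), frac=span, it=robust_iter,
                       xvals=x.loc[order].to_numpy())
    score = pd.Series(y.loc[order].to_numpy() - predicted, index=order)
    score = score - score.mean()
    track = running_average(score, window)
    peak = track.abs().max()
    if peak > 0:
        track = track / peak
    return pd.DataFrame({"score": score, "track": track})


@dataclass
class ScTrack:
    """Per-cell running-average relative ESG expression along the order."""

    values: pd.DataFrame                 # ordered genes x (cancer + CAF) cells
    cancer_cells: list[str]
    caf_cells: list[str]
    mask: pd.Series                      # ordered ESGs present in the sc data


def sc_track(sc_matrix: ExpressionMatrix, meta: pd.DataFrame, order: list[str],
             window: int = 30) -> ScTrack:
    """Relative expression of cancer cells and CAFs along the gene order.

    Each gene is centred on the midpoint of its cancer-cell and CAF means;
    each cell's ESG vector is then centred on its own mean before smoothing.
    Genes absent from the single-cell data are masked out of the track.
    """
    present = [g for g in order if g in sc_matrix.data.index]
    mask = pd.Series([g in sc_matrix.data.index for g in order], index=order)
    cancer = [c for c in meta.loc[meta["cell_type"] == "cancer", "cell_id"]
              if c in sc_matrix.data.columns]
    caf = [c for c in meta.loc[meta["cell_type"] == "CAF", "cell_id"]
           if c in sc_matrix.data.columns]
    if not cancer or not caf:
        raise ValueError("need both cancer cells and CAFs for the sc track")
    data = sc_matrix.data.loc[present, cancer + caf]
    midpoint = (data[cancer].mean(axis=1) + data[caf].mean(axis=1)) / 2.0
    centred = data.sub(midpoint, axis=0)
    centred = centred.sub(centred.mean(axis=0), axis=1)   # per-cell centring
    smoothed = centred.rolling(window, center=True, min_periods=1).mean()
    return ScTrack(values=smoothed, cancer_cells=cancer, caf_cells=caf, mask=mask)


@dataclass
class ValidationTracks:
    purity: pd.DataFrame | None = None
    cellline: pd.DataFrame | None = None
    sc: ScTrack | None = None

    def available(self) -> list[str]:
        return [name for name in ("sc", "purity", "cellline")
                if getattr(self, name) is not None]


# ---------------------------------------------------------------- annotation

@dataclass
class ClusterAnnotation:
    """End labels with the per-measure votes behind them."""

    labels: dict[str, str]               # {"endA": "pEMT"|"CAF", "endB": ...}
    votes: dict[str, str]                # measure -> end voted pEMT
    confidence: str                      # "full" | "partial"
    flags: list[str] = field(default_factory=list)
    excluded: bool = False


def _vote_purity(result: DeconvolutionResult, track: pd.DataFrame, n_end: int) -> str:
    end_a = track.loc[[g for g in result.top_genes("endA", n_end)
                       if g in track.index], "track"].mean()
    end_b = track.loc[[g for g in result.top_genes("endB", n_end)
                       if g in track.index], "track"].mean()
    return "endA" if end_a > end_b else "endB"


def _vote_cellline(result: DeconvolutionResult, track: pd.DataFrame, n_end: int) -> str:
    end_a = track.loc[[g for g in result.top_genes("endA", n_end)
                       if g in track.index], "track"].mean()
    end_b = track.loc[[g for g in result.top_genes("endB", n_end)
                       if g in track.index], "track"].mean()
    # positive = tumour-enriched = stromal; the LOWER end is the cancer (pEMT) side
    return "endA" if end_a < end_b else "endB"


def _vote_sc(result: DeconvolutionResult, track: ScTrack, n_end: int) -> str:
    diffs = {}
    for end in ("endA", "endB"):
        genes = [g for g in result.top_genes(end, n_end) if g in track.values.index]
        block = track.values.loc[genes]
        diffs[end] = (block[track.cancer_cells].mean().mean()
                      - block[track.caf_cells].mean().mean())
    return "endA" if diffs["endA"] > diffs["endB"] else "endB"


def annotate_clusters(result: DeconvolutionResult, tracks: ValidationTracks,
                      n_end: int = 20) -> ClusterAnnotation:
    """Label the two ordering ends pEMT vs CAF from the available measures.

    Majority vote with single-cell evidence breaking ties and overriding an
    opposing purity pattern (flagged); a purity pattern opposing the cell-line
    measure with no single-cell data available marks the dataset excluded.
    """
    votes: dict[str, str] = {}
    if tracks.sc is not None:
        votes["sc"] = _vote_sc(result, tracks.sc, n_end)
    if tracks.purity is not None:
        votes["purity"] = _vote_purity(result, tracks.purity, n_end)
    if tracks.cellline is not None:
        votes["cellline"] = _vote_cellline(result, tracks.cellline, n_end)
    if not votes:
        raise ValueError("no validation track available")

    counts = pd.Series(votes).value_counts()
    if len(counts) == 1:
        pemt_end = counts.index[0]
        confidence = "full"
    else:
        # disagreement: priority sc > purity > cellline decides
        for measure in ("sc", "purity", "cellline"):
            if measure in votes:
                pemt_end = votes[measure]
                break
        confidence = "partial"

    flags: list[str] = []
    excluded = False
    if "purity" in votes and votes["purity"] != pemt_end:
        flags.append("purity_conflict")
    if ("sc" not in votes and "purity" in votes and "cellline" in votes
            and votes["purity"] != votes["cellline"]):
        flags.append("exclude_no_sc_backing")
        excluded = True

    other = "endB" if pemt_end == "endA" else "endA"
    return ClusterAnnotation(labels={pemt_end: "pEMT", other: "CAF"},
                             votes=votes, confidence=confidence,
                             flags=flags, excluded=excluded)


# ------------------------------------------------------------- robustness QC

@dataclass
class RobustnessResult:
    slopes: pd.Series                    # alpha_i per cell type
    intercepts: pd.Series
    exclude: bool
    within_cluster: dict[str, float]
    within_cluster_mean: float
    between_cluster: float
    measure_differences: dict[str, float]


def robustness_qc(model: ConfounderModel, result: DeconvolutionResult,
                  tracks: ValidationTracks | None = None,
                  slope_cut: float = -0.1, n_top: int = 30,
                  pemt_end: str = "endA") -> RobustnessResult:
    """Residual-confounding check plus separation-strength statistics.

    For each cell type, OLS of its marker correlations on the ordering
    position scaled to [0, 1] from the pEMT end; the dataset is excluded when
    any slope <= ``slope_cut`` (a drift of >= 0.1 in marker correlation from
    the CAF end towards the pEMT end).  Also reports mean within- and
    between-cluster correlations of the top genes per end and, for each
    available track, mean over the top third minus the bottom third of the
    ordered genes.
    """
    ordered = result.ordered_genes
    if pemt_end == "endB":
        ordered = ordered[::-1]
    genes = [g for g in ordered if g in model.rho.index]
    r = pd.Series(np.linspace(0.0, 1.0, len(genes)), index=genes)
    slopes, intercepts = {}, {}
    for ctype in model.rho.columns:
        y = model.rho.loc[genes, ctype]
        alpha = np.polyfit(r.to_numpy(), y.to_numpy(), 1)
        slopes[ctype], intercepts[ctype] = alpha[0], alpha[1]
    slopes = pd.Series(slopes)
    intercepts = pd.Series(intercepts)
    exclude = bool((slopes <= slope_cut).any())

    within = {}
    tops = {}
    for end in ("endA", "endB"):
        top = result.top_genes(end, n_top)
        if len(top) < n_top:
            warnings.warn(f"{end} has fewer than {n_top} genes; using all")
        tops[end] = top
        block = result.corr.loc[top, top].to_numpy()
        n = len(top)
        within[end] = float((block.sum() - n) / (n * (n - 1))) if n > 1 else np.nan
    between = float(result.corr.loc[tops["endA"], tops["endB"]].to_numpy().mean())

    diffs: dict[str, float] = {}
    if tracks is not None:
        ordered = result.ordered_genes
        third = len(ordered) // 3
        top_third, bottom_third = ordered[:third], ordered[-third:]
        for name in tracks.available():
            track = getattr(tracks, name)
            values = track.values.mean(axis=1) if isinstance(track, ScTrack) else track["track"]
            diffs[name] = float(values.reindex(top_third).mean()
                                - values.reindex(bottom_third).mean())
    return RobustnessResult(slopes=slopes, intercepts=intercepts, exclude=exclude,
                            within_cluster=within,
                            within_cluster_mean=float(np.mean(list(within.values()))),
                            between_cluster=between, measure_differences=diffs)
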