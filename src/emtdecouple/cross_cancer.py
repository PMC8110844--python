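"""Comparison of pEMT/CAF programs across cancer types.

Each gene gets a per-type pEMT-CAF score: its average residual-space
correlation with the type's top-20 pEMT genes minus that with the top-20 CAF
genes, scaled by 3 standard deviations across genes and clipped to [-1, 1].
Commonness ranks summarise how consistently a gene sits at the pEMT end of
the per-type orderings; cancer types are clustered (average linkage on
1 - correlation over the 100 most common pEMT genes) with silhouette <= 0.2
flagging intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .deconvolve import ResidualizedMatrix, _cross_corr


# ------------------------------------------------------------------- scores

def pemt_caf_scores_one_type(residualized: ResidualizedMatrix,
                             top_pemt: list[str], top_caf: list[str]) -> pd.Series:
    """Raw-then-scaled pEMT-CAF score per gene for one cancer type.

    score_g = mean corr(g, top-20 pEMT) - mean corr(g, top-20 CAF), computed on
    residualized expression, divided by 3 x SD across all scored genes and
    clipped to [-1, 1].
    """
    res = residualized.residuals
    top_pemt = [g for g in top_pemt if g in res.index]
    top_caf = [g for g in top_caf if g in res.index]
    if not top_pemt or not top_caf:
        raise ValueError("top gene lists absent from the residualized matrix")
    values = res.to_numpy()
    corr_p = _cross_corr(values, res.loc[top_pemt].to_numpy()).mean(axis=1)
    corr_c = _cross_corr(values, res.loc[top_caf].to_numpy()).mean(axis=1)
    raw = pd.Series(corr_p - corr_c, index=res.index)
    sd = raw.std()
    if sd == 0:
        return raw * 0.0
    return (raw / (3.0 * sd)).clip(-1.0, 1.0)


def pemt_caf_scores(per_type: dict[str, tuple[ResidualizedMatrix, list[str], list[str]]]
                    ) -> pd.DataFrame:
    """ScoreMatrix over the global ESG union: genes x cancer types, missing
    where a gene is absent from a type's data."""
    columns = {t: pemt_caf_scores_one_type(res, pemt, caf)
               for t, (res, pemt, caf) in per_type.items()}
    return pd.DataFrame(columns)


def gene_significance(scores: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-test of each gene's scores against zero.

    Degenerate cases: all-zero scores give p = 1 by convention; nonzero
    constant scores have zero variance and the p-value is reported missing.
    """
    means, pvals = [], []
    for _, row in scores.iterrows():
        vals = row.dropna().to_numpy()
        if len(vals) < 2:
            means.append(np.nan if len(vals) == 0 else vals.mean())
            pvals.append(np.nan)
            continue
        means.append(vals.mean())
        if np.std(vals) == 0:
            pvals.append(1.0 if vals[0] == 0 else np.nan)
        else:
            pvals.append(stats.ttest_1samp(vals, 0.0).pvalue)
    return pd.DataFrame({"mean_score": means, "p_value": pvals}, index=scores.index)


# ---------------------------------------------------------------- commonness

def common_gene_ranks(ordered_lists: dict[str, list[str]]) -> pd.DataFrame:
    """Commonness percentiles from per-type orderings (pEMT end first).

    A gene's rank in a type is position / list length when present, 0.5 when
    absent.  The pEMT commonness is the 25th percentile of its ranks (low =
    consistently near the pEMT end); the CAF commonness the 75th (high =
    consistently near the CAF end).  Linear-interpolation quantiles.
    """
    if not ordered_lists or any(len(v) == 0 for v in ordered_lists.values()):
        raise ValueError("ordered gene lists must be non-empty")
    genes = sorted(set().union(*ordered_lists.values()))
    ranks = pd.DataFrame(0.5, index=genes, columns=list(ordered_lists))
    for t, order in ordered_lists.items():
        n = len(order)
        for pos, g in enumerate(order, start=1):
            ranks.loc[g, t] = pos / n
    arr = ranks.to_numpy()
    return pd.DataFrame({
        "pemt_commonness": np.percentile(arr, 25, axis=1),
        "caf_commonness": np.percentile(arr, 75, axis=1),
    }, index=ranks.index)


def top_common_genes(ranks: pd.DataFrame, n: int, which: str = "pemt") -> list[str]:
    """The n most consistently pEMT-proximal (lowest 25th percentile) or
    CAF-proximal (highest 75th percentile) genes."""
    if which == "pemt":
        order = ranks["pemt_commonness"].sort_values(kind="stable")
    else:
        order = ranks["caf_commonness"].sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


# ----------------------------------------------------------------- clustering

@dataclass
class CancerClustering:
    correlation: pd.DataFrame
    linkage: np.ndarray
    assignments: pd.Series               # k-cut labels for all types
    silhouettes: pd.Series
    intermediates: list[str]
    final_clusters: dict[int, list[str]] # after removing intermediates


def cluster_cancer_types(scores: pd.DataFrame, common_pemt_genes: list[str],
                         k: int = 3, sil_cut: float = 0.2) -> CancerClustering:
    """Average-linkage clustering of cancer types on 1 - correlation over the
    common pEMT genes; silhouette <= ``sil_cut`` flags intermediates."""
    types = sorted(scores.columns)
    if len(types) < k + 1:
        raise ValueError("need more cancer types than clusters")
    genes = [g for g in common_pemt_genes if g in scores.index]
    block = scores.loc[genes, types]
    corr = block.corr(min_periods=2)     # pairwise-complete over missing scores
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.average(squareform(dist, checks=False))
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    sil = silhouette_samples(dist, labels, metric="precomputed")
    assignments = pd.Series(labels, index=types)
    silhouettes = pd.Series(sil, index=types)
    intermediates = list(silhouettes.index[silhouettes <= sil_cut])
    final = {int(c): [t for t in assignments.index[assignments == c]
                      if t not in intermediates]
             for c in sorted(set(labels))}
    return CancerClustering(correlation=corr, linkage=linkage,
                            assignments=assignments, silhouettes=silhouettes,
                            intermediates=intermediates, final_clusters=final)


def cluster_characteristic_genes(scores: pd.DataFrame,
                                 clustering: CancerClustering,
                                 n: int = 20) -> dict[int, pd.Series]:
    """Per final cluster, genes ranked by mean score inside minus outside."""
    out: dict[int, pd.Series] = {}
    for cid, members in clustering.final_clusters.items():
        if not members:
            continue
        others = [t for t in scores.columns if t not in members]
        diff = scores[members].mean(axis=1) - scores[others].mean(axis=1)
        diff = diff.sort_values(ascending=False, kind="stable")
        out[cid] = diff.head(n)
    return out


def global_similarity(bulk_by_type: dict[str, pd.DataFrame],
                      n_var: int = 5000) -> pd.DataFrame:
    """Pairwise correlation of mean expression over the intersection of each
    pair's most variable genes."""
    import warnings as _warnings

    if len(bulk_by_type) < 2:
        raise ValueError("need at least two cancer types")
    means, variable = {}, {}
    for t, data in bulk_by_type.items():
        means[t] = data.mean(axis=1)
        variances = data.var(axis=1)
        variable[t] = set(variances.sort_values(ascending=False, kind="stable")
                          .index[:n_var])
    types = sorted(bulk_by_type)
    sim = pd.DataFrame(np.eye(len(types)), index=types, columns=types)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            shared = sorted(variable[a] & variable[b])
            if len(shared) < 100:
                _warnings.warn(f"fewer than 100 shared variable genes for {a}/{b}")
            r = means[a].loc[shared].corr(means[b].loc[shared])
            sim.loc[a, b] = sim.loc[b, a] = r
    return sim
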