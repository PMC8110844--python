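"""Correlation-based deconvolution of ESG expression in bulk cohorts.

The method: (1) score each ESG by its average correlation with marker genes of
potentially confounding TME cell types and keep the least-confounded ``n``;
(2) replace each ESG's expression by the residuals of an OLS regression on the
per-sample ESG sum, removing the shared mesenchymal load; (3) build the
gene-gene Pearson correlation matrix and order it with the SPIN side-to-side
(STS) heuristic on distance 1 - r; (4) refine: compute each gene's average
correlation with the top and bottom 20 ordered genes, drop genes associating
with both ends the same way, and re-sort the survivors into the two end
clusters that downstream annotation labels pEMT and CAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASSICAL_EMT_MARKERS, ExpressionMatrix


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between two matrices sharing columns."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = az.std(axis=1, keepdims=True)
    bsd = bz.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.where(asd > 0, az / asd, 0.0)
        bz = np.where(bsd > 0, bz / bsd, 0.0)
    return az @ bz.T / a.shape[1]


# ----------------------------------------------------------- confounder model

@dataclass
class ConfounderModel:
    """Average marker correlations per ESG and the per-type weights W_i."""

    rho: pd.DataFrame                    # ESG x cell type
    weights: pd.Series                   # per cell type
    quantile_q: float
    overrides: dict[str, float] | None = None


def confounder_weights(bulk: ExpressionMatrix, esg_genes,
                       markers_per_type: dict[str, list[str]],
                       quantile_q: float = 0.75,
                       overrides: dict[str, float] | None = None) -> ConfounderModel:
    """Weight each TME cell type by its overall correlation with the ESGs.

    rho[g, i] is the mean Pearson correlation of ESG g with the markers of
    type i; W_i is the ``quantile_q`` quantile of that column.  An explicit
    override map replaces the weights entirely (suspected confounder 1, all
    others 0).
    """
    if not 0 <= quantile_q <= 1:
        raise ValueError("quantile_q must lie in [0, 1]")
    esg_genes = [g for g in esg_genes if g in bulk.data.index]
    rho = pd.DataFrame(index=pd.Index(esg_genes, name="gene"),
                       columns=list(markers_per_type), dtype=float)
    esg_block = bulk.data.loc[esg_genes]
    for ctype, markers in markers_per_type.items():
        present = [m for m in markers if m in bulk.data.index]
        dropped = set(markers) - set(present)
        if dropped:
            warnings.warn(f"{len(dropped)} marker(s) for {ctype!r} absent from bulk")
        if not present:
            raise ValueError(f"all markers for {ctype!r} absent from the bulk matrix")
        corr = _cross_corr(esg_block.to_numpy(), bulk.data.loc[present].to_numpy())
        rho[ctype] = corr.mean(axis=1)
    if overrides is not None:
        weights = pd.Series({t: float(overrides.get(t, 0.0)) for t in markers_per_type})
    else:
        weights = rho.quantile(quantile_q)
    return ConfounderModel(rho=rho, weights=weights, quantile_q=quantile_q,
                           overrides=overrides)


def score_and_select_esgs(model: ConfounderModel, n: int,
                          classical_markers=CLASSICAL_EMT_MARKERS) -> list[str]:
    """Retain the n ESGs least correlated with confounding cell types.

    SC_g = -sum_i rho[g,i] * W_i, sorted descending (stable, gene-id
    tie-break).  Classical EMT markers dropped by the cut are added back.
    """
    if n > len(model.rho):
        raise ValueError("n exceeds the number of ESGs")
    sc = -(model.rho @ model.weights)
    order = sc.iloc[np.lexsort((model.rho.index, -sc.to_numpy()))]
    kept = list(order.index[:n])
    for marker in classical_markers:
        if marker in model.rho.index and marker not in kept:
            kept.append(marker)
    return kept


# -------------------------------------------------------------- residualizing

@dataclass
class ResidualizedMatrix:
    """ESG expression replaced by residuals of OLS against the ESG sample sums."""

    residuals: pd.DataFrame              # ESG x sample
    sample_sums: pd.Series
    coefficients: pd.DataFrame           # per gene: alpha (slope), beta (intercept)


def residualize_esgs(bulk: ExpressionMatrix, esg_genes) -> ResidualizedMatrix:
    """Regress each ESG on the per-sample sum over the ESG list; keep residuals.

    This damps genes that track the overall mesenchymal load (and hence
    correlate with most other ESGs) rather than a specific compartment.  With
    a constant sum the regression is degenerate; mean-centred values are
    returned with a warning.
    """
    esg_genes = [g for g in esg_genes if g in bulk.data.index]
    data = bulk.data.loc[esg_genes]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to residualize")
    s = data.sum(axis=0)
    sc = s - s.mean()
    ss = (sc ** 2).sum()
    y = data.to_numpy()
    if ss == 0:
        warnings.warn("ESG sample sums are constant; returning centred values")
        alpha = np.zeros(len(esg_genes))
    else:
        alpha = (y - y.mean(axis=1, keepdims=True)) @ sc.to_numpy() / ss
    beta = y.mean(axis=1) - alpha * s.mean()
    fitted = np.outer(alpha, s.to_numpy()) + beta[:, None]
    residuals = pd.DataFrame(y - fitted, index=data.index, columns=data.columns)
    coef = pd.DataFrame({"alpha": alpha, "beta": beta}, index=data.index)
    return ResidualizedMatrix(residuals=residuals, sample_sums=s, coefficients=coef)


def correlation_matrix(residualized: ResidualizedMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix of the residualized expression."""
    r = np.corrcoef(residualized.residuals.to_numpy())
    genes = residualized.residuals.index
    return pd.DataFrame(r, index=genes, columns=genes)


# --------------------------------------------------------------- STS ordering

@dataclass
class StsResult:
    order: list[str]
    energies: list[float]
    n_iter: int
    converged: bool


def _sts_weights(n: int) -> np.ndarray:
    # centred linear ramp: +((n-1)/2) ... -((n-1)/2)
    return (n - 1) / 2.0 - np.arange(n)


def sts_energy(distance: np.ndarray, perm: np.ndarray, w: np.ndarray) -> float:
    d = distance[np.ix_(perm, perm)]
    return float(w @ d @ w)


def _best_swap(distance: np.ndarray, perm: np.ndarray, w: np.ndarray):
    """Energy change of every position swap, in closed form.

    For positions a, b with items u = perm[a], v = perm[b]:
    delta(a, b) = 2 (w_a - w_b) [(c_b - c_a) - (w_a - w_b) S_ab]
    with S the permuted distance matrix and c = S w.
    """
    s = distance[np.ix_(perm, perm)]
    c = s @ w
    dw = w[:, None] - w[None, :]
    delta = 2.0 * dw * ((c[None, :] - c[:, None]) - dw * s)
    a, b = np.unravel_index(np.argmin(delta), delta.shape)
    return delta[a, b], a, b


def spin_sts_order(corr: pd.DataFrame, seed: int | None = None,
                   max_iter: int = 100) -> StsResult:
    """Side-to-side seriation of a correlation matrix (distance 1 - r).

    Each iteration scores every item by the dot product of its distance row
    with the centred ramp weights under the current permutation and re-sorts
    by that score; items close to the high-weight (leading) side move forward.
    A sort step is accepted only when it strictly lowers the ramp energy;
    otherwise an energy-decreasing pair swap is applied (this breaks the
    degenerate alternating fixed points that perfectly symmetric matrices
    admit).  The iteration stops when neither move improves, so the energy is
    strictly decreasing across accepted steps.  ``seed=None`` starts from the
    given order; an integer seed starts from a random permutation.
    """
    values = corr.to_numpy()
    if np.isnan(values).any():
        raise ValueError("correlation matrix contains NaN")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    distance = 1.0 - values
    n = distance.shape[0]
    w = _sts_weights(n)
    if seed is None:
        perm = np.arange(n)
    else:
        perm = np.random.default_rng(seed).permutation(n)

    energies = [sts_energy(distance, perm, w)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        scores = np.empty(n)
        scores[perm] = distance[np.ix_(perm, perm)] @ w
        # minimise sum_pos w[pos] * score[item]: largest scores go to the tail
        candidate = np.argsort(scores, kind="stable")
        accepted = False
        if not np.array_equal(candidate, perm):
            e = sts_energy(distance, candidate, w)
            if e < energies[-1] - 1e-12:
                perm = candidate
                energies.append(e)
                accepted = True
        if not accepted:
            delta, a, b = _best_swap(distance, perm, w)
            if delta < -1e-9:
                perm = perm.copy()
                perm[a], perm[b] = perm[b], perm[a]
                energies.append(sts_energy(distance, perm, w))
            else:
                converged = True
                break
    return StsResult(order=[corr.index[i] for i in perm], energies=energies,
                     n_iter=it, converged=converged)


# ------------------------------------------------------------------ refinement

@dataclass
class DeconvolutionResult:
    """Refined ESG ordering with end-cluster membership.

    ``table`` is indexed by gene in the refined order (removed genes excluded)
    with columns sigma1/sigma2 (average correlation with the top/bottom 20 of
    the initial ordering), key, cluster (endA/endB) and a flag for classical
    markers retained despite failing the opposite-sign rule.
    """

    table: pd.DataFrame
    removed: list[str]
    corr: pd.DataFrame
    initial_order: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def ordered_genes(self) -> list[str]:
        return list(self.table.index)

    def top_genes(self, cluster: str, n: int = 20) -> list[str]:
        """The n strongest genes of one end (endA from the head of the order,
        endB from the tail)."""
        genes = self.table.index[self.table["cluster"] == cluster]
        if cluster == "endA":
            return list(genes[:n])
        return list(genes[::-1][:n])


def refine_ordering(corr: pd.DataFrame, order: list[str],
                    classical_markers=CLASSICAL_EMT_MARKERS,
                    n_end: int = 20) -> DeconvolutionResult:
    """Filter and re-sort an STS ordering into two end clusters.

    For each gene g: sigma1 = mean correlation with the top ``n_end`` ordered
    genes (excluding g itself when inside), sigma2 likewise for the bottom.
    Genes with sign(sigma1) == sign(sigma2) are removed -- they associate with
    both ends alike -- except classical EMT markers, which are retained and
    flagged.  Survivors are re-sorted descending by
    key = max(sigma1, sigma2) * (+1 if sigma1 is the larger else -1);
    positive keys form endA, negative endB.
    """
    if len(order) < 2 * n_end:
        raise ValueError(f"need at least {2 * n_end} genes in the ordering")
    corr = corr.loc[order, order]
    top, bottom = order[:n_end], order[-n_end:]

    def _avg_with(group: list[str]) -> pd.Series:
        block = corr[group].copy()
        sums = block.sum(axis=1)
        inside = block.index.isin(group)
        # a gene inside the group excludes its own (unit) self-correlation
        avg = np.where(inside, (sums - 1.0) / (len(group) - 1), sums / len(group))
        return pd.Series(avg, index=block.index)

    sigma1, sigma2 = _avg_with(top), _avg_with(bottom)
    same_sign = np.sign(sigma1) == np.sign(sigma2)
    classical = sigma1.index.isin(classical_markers)
    removed = list(sigma1.index[same_sign & ~classical])
    kept = sigma1.index[~same_sign | classical]

    key = pd.Series(np.where(sigma1 >= sigma2, sigma1, -sigma2), index=sigma1.index)
    table = pd.DataFrame({
        "sigma1": sigma1, "sigma2": sigma2, "key": key,
        "cluster": np.where(key > 0, "endA", "endB"),
        "retained_classical": same_sign & classical,
    }).loc[kept]
    table = table.iloc[np.lexsort((table.index, -table["key"].to_numpy()))]
    return DeconvolutionResult(table=table, removed=removed, corr=corr,
                               initial_order=list(order))


# -------------------------------------------------------------- whole method

def run_deconvolution(bulk: ExpressionMatrix, esg_genes,
                      markers_per_type: dict[str, list[str]] | None = None,
                      quantile_q: float = 0.75, n_select: int | None = None,
                      overrides: dict[str, float] | None = None,
                      seed: int | None = None,
                      max_iter: int = 100) -> DeconvolutionResult:
    """Confounder filter (optional) -> residualize -> correlate -> STS -> refine."""
    esg_genes = [g for g in esg_genes if g in bulk.data.index]
    model = None
    if markers_per_type is not None:
        model = confounder_weights(bulk, esg_genes, markers_per_type,
                                   quantile_q=quantile_q, overrides=overrides)
        esg_genes = score_and_select_esgs(model, n_select or len(esg_genes))
    residualized = residualize_esgs(bulk, esg_genes)
    corr = correlation_matrix(residualized)
    sts = spin_sts_order(corr, seed=seed, max_iter=max_iter)
    result = refine_ordering(corr, sts.order)
    result.metadata = {
        "quantile_q": quantile_q, "n_select": n_select, "overrides": overrides,
        "seed": seed, "sts_iterations": sts.n_iter, "sts_converged": sts.converged,
        "n_esgs_in": len(esg_genes), "n_removed": len(result.removed),
    }
    result.confounder_model = model
    result.residualized = residualized
    return result


# ---------------------------------------------------------- small-n oracle aid

def enumerate_sts_local_optima(corr: pd.DataFrame) -> set[float]:
    """Energies of all permutations from which one STS step cannot strictly
    decrease the ramp energy.  Exhaustive; use only for <= 8 items."""
    from itertools import permutations

    values = corr.to_numpy()
    distance = 1.0 - values
    n = distance.shape[0]
    w = _sts_weights(n)
    optima: set[float] = set()
    for perm in permutations(range(n)):
        perm = np.array(perm)
        e = sts_energy(distance, perm, w)
        scores = np.empty(n)
        scores[perm] = distance[np.ix_(perm, perm)] @ w
        candidate = np.argsort(scores, kind="stable")
        if sts_energy(distance, candidate, w) < e - 1e-12:
            continue
        delta, _, _ = _best_swap(distance, perm, w)
        if delta < -1e-9:
            continue
        optima.add(round(e, 9))
    return optima
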