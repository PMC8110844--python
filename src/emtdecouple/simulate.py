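"""Pseudobulk simulation by aggregating sampled single cells.

Two designs are provided.  The composition sweep fixes a focal cell type at a
requested proportion q (normal-distributed counts, uniform draws for the other
types scaled by a closed-form factor) and accounts for each cell type's share
of total ESG expression.  The deconvolution cohort makes cancer cells the
focal type over 40 proportions in [0.1, 0.9] and emits bulk profiles
log2(sum TPM / 10 + 1) with the realised cancer fraction as purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SCALE_LOG2_TPM10, SCALE_TPM

RARE_LABEL = "rare cell types"

DEFAULT_SWEEP_Q = tuple(np.round(np.arange(0.1, 0.81, 0.1), 10))


def merge_rare_cell_types(meta: pd.DataFrame, min_count: int) -> pd.DataFrame:
    """Relabel cell types with fewer than ``min_count`` cells as a combined
    rare category, so they are not overrepresented in simulated tumours."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = meta["cell_type"].value_counts()
    rare = counts.index[counts < min_count]
    out = meta.copy()
    out.loc[out["cell_type"].isin(rare), "cell_type"] = RARE_LABEL
    return out


@dataclass
class SimulatedCohort:
    """Simulated tumours with known composition.

    ``composition`` holds integer cell counts per tumour x cell type;
    ``requested`` the focal type and requested proportion per tumour;
    ``sampled_cells`` the multiset of sampled cell ids per tumour;
    ``contributions`` the per-type fractions of total ESG expression (when
    computed); ``bulk``/``purity`` are set by the deconvolution design.
    """

    composition: pd.DataFrame
    requested: pd.DataFrame
    sampled_cells: dict[str, list[str]] = field(default_factory=dict)
    contributions: pd.DataFrame | None = None
    bulk: ExpressionMatrix | None = None
    purity: pd.Series | None = None

    def realized_fraction(self) -> pd.Series:
        """Realised focal-type fraction per tumour."""
        totals = self.composition.sum(axis=1)
        focal = self.composition.to_numpy()[
            np.arange(len(self.composition)),
            self.composition.columns.get_indexer(self.requested["focal_type"])]
        return pd.Series(focal / totals.to_numpy(), index=self.composition.index)


def _draw_composition(rng: np.random.Generator, types: list[str], focal: str,
                      q: float, mu: float, q_max: float) -> pd.Series:
    if not 0 < q < 1:
        raise ValueError("requested proportion must lie in (0, 1)")
    mu_j = mu * q / q_max
    n_focal = max(1, round(rng.normal(mu_j, 0.2 * mu_j)))
    others = [t for t in types if t != focal]
    n_unif = rng.uniform(0.0, mu, size=len(others))
    lam = n_focal * (1.0 - q) / (q * n_unif.sum())
    counts = pd.Series(0, index=types, dtype=int)
    counts[focal] = n_focal
    counts[others] = np.round(lam * n_unif).astype(int)
    return counts


def _sample_cells(rng: np.random.Generator, cells_by_type: dict[str, np.ndarray],
                  counts: pd.Series) -> list[str]:
    sampled: list[str] = []
    for ctype, n in counts.items():
        if n == 0:
            continue
        pool = cells_by_type.get(ctype)
        if pool is None or len(pool) == 0:
            raise ValueError(f"no cells of required type {ctype!r}")
        sampled.extend(rng.choice(pool, size=int(n), replace=True))
    return sampled


def simulate_composition_sweep(meta: pd.DataFrame, focal_type: str,
                               q_values=DEFAULT_SWEEP_Q, reps: int = 100,
                               mu: float = 100.0, seed: int = 0) -> SimulatedCohort:
    """Simulate ``reps`` tumours at each requested focal proportion.

    Focal counts are Normal(mu*q/max(Q), 0.2*mu*q/max(Q)), truncated below at
    one cell and rounded; the other types (including the rare category) get
    Uniform(0, mu) draws scaled so the focal proportion is exactly q before
    rounding.  Cells are sampled with replacement.
    """
    if focal_type == RARE_LABEL:
        raise ValueError("the rare-cell-types category cannot be the focal type")
    types = sorted(meta["cell_type"].unique())
    if focal_type not in types:
        raise ValueError(f"focal type {focal_type!r} not present")
    if mu <= 0:
        raise ValueError("mu must be positive")
    rng = np.random.default_rng(seed)
    cells_by_type = {t: g.to_numpy() for t, g in meta.groupby("cell_type")["cell_id"]}
    q_max = max(q_values)

    rows, req, sampled = [], [], {}
    for q in q_values:
        for r in range(reps):
            counts = _draw_composition(rng, types, focal_type, q, mu, q_max)
            tid = f"sim_q{q:.3f}_r{r:03d}"
            rows.append(counts.rename(tid))
            req.append({"tumour": tid, "focal_type": focal_type, "q": q})
            sampled[tid] = _sample_cells(rng, cells_by_type, counts)
    return SimulatedCohort(composition=pd.DataFrame(rows),
                           requested=pd.DataFrame(req).set_index("tumour"),
                           sampled_cells=sampled)


def esg_contribution(cohort: SimulatedCohort, sc_tpm: ExpressionMatrix,
                     meta: pd.DataFrame, esg_genes) -> pd.DataFrame:
    """Fraction of total ESG expression (TPM scale) contributed by each cell
    type in each simulated tumour.  Undefined (all-NaN) when the tumour has no
    ESG expression at all."""
    if sc_tpm.scale != SCALE_TPM:
        raise ValueError("contributions are computed on the TPM scale")
    esg_genes = [g for g in esg_genes if g in sc_tpm.data.index]
    esg_sum = sc_tpm.data.loc[esg_genes].sum(axis=0)   # per cell
    type_of = meta.set_index("cell_id")["cell_type"]
    types = list(cohort.composition.columns)

    rows = {}
    for tid, cells in cohort.sampled_cells.items():
        per_cell = esg_sum.loc[cells]
        total = per_cell.sum()
        if total == 0:
            rows[tid] = pd.Series(np.nan, index=types)
            continue
        by_type = per_cell.groupby(type_of.loc[cells].to_numpy()).sum()
        rows[tid] = by_type.reindex(types).fillna(0.0) / total
    contributions = pd.DataFrame(rows).T.reindex(cohort.composition.index)
    cohort.contributions = contributions
    return contributions


def simulate_deconv_cohort(sc_tpm: ExpressionMatrix, meta: pd.DataFrame,
                           n_q: int = 40, q_range: tuple[float, float] = (0.1, 0.9),
                           reps: int = 25, mu: float = 100.0,
                           seed: int = 0) -> SimulatedCohort:
    """Simulate the cancer-fraction cohort used for deconvolution.

    Cancer cells are the focal type over ``n_q`` equally spaced proportions;
    each tumour's bulk value for gene l is log2(sum_m TPM_{l,m} / 10 + 1) over
    its sampled cells m, and purity is the realised cancer-cell fraction.
    """
    if sc_tpm.scale != SCALE_TPM:
        raise ValueError("deconvolution cohort aggregates TPM values")
    if "cancer" not in set(meta["cell_type"]):
        raise ValueError("no cancer cells present")
    q_values = np.linspace(q_range[0], q_range[1], n_q)
    cohort = simulate_composition_sweep(meta, "cancer", q_values=q_values,
                                        reps=reps, mu=mu, seed=seed)
    profiles = {
        tid: np.log2(sc_tpm.data[cells].sum(axis=1) / 10.0 + 1.0)
        for tid, cells in cohort.sampled_cells.items()
    }
    bulk = pd.DataFrame(profiles).reindex(columns=cohort.composition.index)
    cohort.bulk = ExpressionMatrix(bulk, scale=SCALE_LOG2_TPM10)
    cohort.purity = cohort.realized_fraction()
    return cohort
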