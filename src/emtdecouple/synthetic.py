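"""Synthetic single-cell / bulk data with planted pEMT and CAF programs.

The generator emulates the structural assumptions behind co-expression-based
decoupling of cancer-cell partial-EMT (pEMT) expression from
cancer-associated-fibroblast (CAF) expression:

* CAFs express a mesenchymal program (the planted ``caf_genes``) broadly and
  strongly; a subset of cancer cells expresses a weaker partial program
  (``pemt_genes``, default mean shift half the CAF shift).
* A third block of ``shared_genes`` is expressed by both populations, so the
  two programs genuinely overlap.
* Cancer cells carry contiguous copy-number blocks (multiplicative shifts on
  chromosome-ordered genes); per-cell capture efficiency varies so the number
  of genes detected spans at least two-fold.
* Bulk cohorts are noisy convex mixtures of cell-type archetype profiles in
  which the CAF fraction and the pEMT fraction vary between tumours with
  limited mutual correlation (Gaussian-copula control), purity equals the
  cancer fraction, and the clinical table carries one planted association.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GroundTruth, SCALE_LOG2_TPM10, SCALE_TPM

CELL_TYPES = ("cancer", "CAF", "endothelial", "macrophage", "T cell", "rare")

#: archetype columns used for bulk mixing (cancer split by pEMT state)
ARCHETYPES = ("cancer_pemt", "cancer_nonpemt", "CAF",
              "endothelial", "macrophage", "T cell", "rare")

CLINICAL_FEATURE_COLUMNS = (
    "lymph_node_count", "n_stage", "lymphovascular_invasion", "grade",
    "t_stage", "days_to_death", "followup_outcome", "m_stage",
)


def _default_proportions() -> dict[str, float]:
    return {"cancer": 0.40, "CAF": 0.20, "endothelial": 0.12,
            "macrophage": 0.12, "T cell": 0.12, "rare": 0.04}


def _default_cna_blocks() -> list[tuple[str, int, int, float]]:
    # (chromosome, first gene index on that chromosome, one-past-last, log2 shift)
    return [("chr2", 20, 170, 1.0), ("chr5", 40, 120, -0.7)]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic model. The seed fully determines output."""

    n_genes: int = 1200
    n_cells: int = 1500
    n_samples: int = 300
    n_patients: int = 5
    cell_type_proportions: dict[str, float] = field(default_factory=_default_proportions)

    # planted program sizes
    n_pemt_genes: int = 70
    n_caf_genes: int = 100
    n_shared_genes: int = 80
    n_epithelial_genes: int = 20
    n_marker_genes_per_type: int = 25

    # log2 mean shifts of the programs; the pEMT shift defaults to half the
    # CAF shift so cancer-cell expression of the partial program stays weak
    caf_shift: float = 3.0
    pemt_shift: float = 1.5
    shared_caf_shift: float = 2.5
    shared_pemt_shift: float = 1.25
    caf_on_pemt_shift: float = 0.5
    marker_shift: float = 3.0
    epithelial_shift: float = 2.0

    # single-cell noise model: lognormal dispersion plus expression-dependent
    # dropout -- gene g in cell c is detected with probability
    # 1 - exp(-TPM * capture_c / dropout_tpm_scale), so low-TPM genes drop out
    # while per-cell capture efficiency drives >= 2-fold variation in the
    # number of genes detected
    dispersion: float = 0.4          # lognormal sigma (natural log)
    capture_range: tuple[float, float] = (0.08, 1.0)
    dropout_tpm_scale: float = 100.0  # 0 disables dropout entirely
    pemt_cell_fraction: float = 0.4  # mean fraction of cancer cells in pEMT state

    # genome layout / CNAs
    n_chromosomes: int = 6
    cna_blocks: list[tuple[str, int, int, float]] = field(default_factory=_default_cna_blocks)

    # bulk cohort
    bulk_noise_sd: float = 0.1       # lognormal sigma on the mixed TPM values
    fraction_correlation: float = 0.1
    correlation_cap: float = 0.2
    # rank-correlates the macrophage fraction with the pEMT fraction, planting
    # a stromal confounder that robustness QC should catch (0 disables)
    stroma_pemt_confound: float = 0.0
    clinical_effect: tuple[str, str, float] = ("grade", "worse", 0.5)

    # cell lines
    n_cell_lines: int = 8
    cellline_noise_sd: float = 0.1
    cellline_pemt_mix: tuple[float, float] = (0.0, 0.3)

    seed: int = 0

    def validate(self) -> None:
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"cell type proportions sum to {total}, expected 1")
        n_special = (self.n_pemt_genes + self.n_caf_genes + self.n_shared_genes
                     + self.n_epithelial_genes + 3 * self.n_marker_genes_per_type)
        if n_special > self.n_genes:
            raise ValueError("planted programs larger than the gene universe")
        lo, hi = self.capture_range
        if not (0 < lo <= hi):
            raise ValueError("capture_range must satisfy 0 < lo <= hi")
        if self.dropout_tpm_scale < 0:
            raise ValueError("dropout_tpm_scale must be >= 0")
        if abs(self.fraction_correlation) > self.correlation_cap:
            raise ValueError("fraction_correlation exceeds the configured cap")


# --------------------------------------------------------------------- model

def _gene_names(config: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic gene naming; classical EMT markers sit inside the planted
    programs (Vimentin and four EMT TFs in the CAF program, SNAI2 in pEMT)."""
    pemt = ["SNAI2"] + [f"PEMT{i:03d}" for i in range(1, config.n_pemt_genes)]
    caf = ["VIM", "SNAI1", "TWIST1", "ZEB1", "ZEB2"] + [
        f"CAF{i:03d}" for i in range(1, config.n_caf_genes - 4)]
    shared = [f"SHARED{i:03d}" for i in range(1, config.n_shared_genes + 1)]
    epith = ["CDH1", "EPCAM", "SFN"] + [
        f"KRT{i:02d}" for i in range(1, config.n_epithelial_genes - 2)]
    markers = {
        "endothelial": [f"ENDOM{i:02d}" for i in range(1, config.n_marker_genes_per_type + 1)],
        "macrophage": [f"MACM{i:02d}" for i in range(1, config.n_marker_genes_per_type + 1)],
        "T cell": [f"TCELLM{i:02d}" for i in range(1, config.n_marker_genes_per_type + 1)],
    }
    n_special = (len(pemt) + len(caf) + len(shared) + len(epith)
                 + sum(len(v) for v in markers.values()))
    background = [f"G{i:04d}" for i in range(1, config.n_genes - n_special + 1)]
    return {"pemt": pemt, "caf": caf, "shared": shared, "epithelial": epith,
            "markers": markers, "background": background}


@dataclass
class _Model:
    """Internal deterministic model shared by the sc / bulk / cell-line ops."""

    genes: list[str]                 # genome order (chromosome-ordered)
    positions: pd.DataFrame          # chrom/start/end/gene, genome order
    base_tpm: pd.Series              # baseline TPM per gene
    shifts: pd.DataFrame             # genes x ARCHETYPES log2 shifts
    truth: GroundTruth

    def archetypes(self) -> pd.DataFrame:
        """Noise-free linear-TPM archetype profile per cell population."""
        return (2.0 ** self.shifts).mul(self.base_tpm, axis=0)


def build_model(config: SyntheticConfig) -> _Model:
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    names = _gene_names(config)

    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    chrom_of_block = {b[0] for b in config.cna_blocks}

    # lay the genome out so the CNA block intervals hold only background genes
    # (keeps copy-number structure orthogonal to the planted programs)
    block_slots: dict[str, set[int]] = {}
    for chrom, lo, hi, _ in config.cna_blocks:
        idx = int(chrom.removeprefix("chr")) - 1
        if hi > per_chrom:
            raise ValueError(f"CNA block on {chrom} exceeds chromosome length {per_chrom}")
        block_slots.setdefault(chrom, set()).update(range(lo, hi))
    n_block = sum(len(v) for v in block_slots.values())
    background = list(names["background"])
    if n_block > len(background):
        raise ValueError("CNA blocks require more background genes than available")
    rng.shuffle(background)
    block_pool = background[:n_block]
    special = (names["pemt"] + names["caf"] + names["shared"] + names["epithelial"]
               + [g for v in names["markers"].values() for g in v])
    free_pool = special + background[n_block:]
    rng.shuffle(free_pool)

    genome: list[str] = []
    bi = fi = 0
    for gi in range(config.n_genes):
        chrom = f"chr{gi // per_chrom + 1}"
        slot = gi % per_chrom
        if chrom in block_slots and slot in block_slots[chrom]:
            genome.append(block_pool[bi]); bi += 1
        else:
            genome.append(free_pool[fi]); fi += 1

    positions = pd.DataFrame({
        "chrom": [f"chr{gi // per_chrom + 1}" for gi in range(config.n_genes)],
        "start": [1000 * (gi % per_chrom) for gi in range(config.n_genes)],
        "end": [1000 * (gi % per_chrom) + 500 for gi in range(config.n_genes)],
        "gene": genome,
    })

    # baseline expression: log-normal TPM scaled to ~1e6 total per cell
    log2_base = rng.normal(3.5, 1.5, size=config.n_genes)
    base = pd.Series(2.0 ** log2_base, index=genome)
    base *= 1e6 / base.sum()

    shifts = pd.DataFrame(0.0, index=genome, columns=list(ARCHETYPES))
    shifts.loc[names["caf"], "CAF"] += config.caf_shift
    shifts.loc[names["pemt"], "cancer_pemt"] += config.pemt_shift
    shifts.loc[names["pemt"], "CAF"] += config.caf_on_pemt_shift
    shifts.loc[names["shared"], "CAF"] += config.shared_caf_shift
    shifts.loc[names["shared"], "cancer_pemt"] += config.shared_pemt_shift
    for ctype, markers in names["markers"].items():
        shifts.loc[markers, ctype] += config.marker_shift
    shifts.loc[names["epithelial"], ["cancer_pemt", "cancer_nonpemt"]] += config.epithelial_shift
    for chrom, lo, hi, log2fc in config.cna_blocks:
        block_genes = positions.loc[(positions["chrom"] == chrom)
                                    & (positions["start"] // 1000 >= lo)
                                    & (positions["start"] // 1000 < hi), "gene"]
        shifts.loc[block_genes, ["cancer_pemt", "cancer_nonpemt"]] += log2fc

    truth = GroundTruth(
        pemt_genes=names["pemt"],
        caf_genes=names["caf"],
        shared_genes=names["shared"],
        confounder_genes={k: list(v) for k, v in names["markers"].items()},
        cna_blocks=list(config.cna_blocks),
    )
    return _Model(genes=genome, positions=positions, base_tpm=base,
                  shifts=shifts, truth=truth)


# --------------------------------------------------------------- single cells

def generate_sc_dataset(config: SyntheticConfig):
    """Generate a single-cell TPM matrix with annotated cell types.

    Returns ``(matrix, cell_meta, gene_positions, ground_truth)``.  Cancer
    cells carry the planted CNA blocks; a per-patient-varying subset of them
    is in the pEMT state (``is_pemt`` column).
    """
    model = build_model(config)
    rng = np.random.default_rng([config.seed, 202])

    types = [t for t, p in config.cell_type_proportions.items() if p > 0]
    probs = np.array([config.cell_type_proportions[t] for t in types])
    if config.n_cells < len(types):
        raise ValueError("n_cells too small to realise every cell type")
    cell_types = rng.choice(types, size=config.n_cells, p=probs)
    patients = rng.integers(0, config.n_patients, size=config.n_cells)

    mean_p = np.clip(config.pemt_cell_fraction, 1e-6, 1 - 1e-6)
    patient_pemt = rng.beta(8 * mean_p, 8 * (1 - mean_p), size=config.n_patients)
    is_pemt = np.zeros(config.n_cells, dtype=bool)
    cancer_mask = cell_types == "cancer"
    is_pemt[cancer_mask] = rng.random(cancer_mask.sum()) < patient_pemt[patients[cancer_mask]]

    arche = np.where(cancer_mask, np.where(is_pemt, "cancer_pemt", "cancer_nonpemt"),
                     cell_types)
    log2_mean = (np.log2(model.base_tpm.to_numpy())[:, None]
                 + model.shifts.loc[:, arche].to_numpy())
    tpm = 2.0 ** log2_mean
    if config.dispersion > 0:
        tpm = tpm * np.exp(rng.normal(0.0, config.dispersion, size=tpm.shape))
    if config.dropout_tpm_scale > 0:
        lo, hi = config.capture_range
        capture = rng.uniform(lo, hi, size=config.n_cells)
        keep_prob = 1.0 - np.exp(-tpm * capture[None, :] / config.dropout_tpm_scale)
        tpm = tpm * (rng.random(tpm.shape) < keep_prob)

    cell_ids = [f"cell{i:05d}" for i in range(config.n_cells)]
    matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=model.genes, columns=cell_ids), scale=SCALE_TPM)
    meta = pd.DataFrame({
        "cell_id": cell_ids,
        "patient_id": [f"patient{p}" for p in patients],
        "cell_type": cell_types,
        "malignant": np.where(cancer_mask, "malignant", "non_malignant"),
        "is_pemt": is_pemt,
    })
    return matrix, meta, model.positions, model.truth


# ---------------------------------------------------------------- bulk cohort

@dataclass
class BulkCohort:
    """A simulated bulk cohort with known composition.

    ``expression`` is on the log2(TPM/10 + 1) scale; ``expression_tpm`` keeps
    the pre-log mixture so conservation against the archetypes can be checked
    exactly; ``weights`` holds the per-sample archetype mixing fractions.
    """

    expression: ExpressionMatrix
    expression_tpm: ExpressionMatrix
    purity: pd.Series
    clinical: pd.DataFrame
    weights: pd.DataFrame


def _sample_fractions(config: SyntheticConfig, rng: np.random.Generator):
    """Beta-distributed CAF / pEMT fractions tied by a Gaussian copula."""
    n = config.n_samples
    rho = config.fraction_correlation
    if n < 10 and rho != 0:
        raise ValueError("correlation control infeasible for fewer than 10 samples")
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    caf = 0.05 + 0.5 * stats.beta.ppf(u[:, 0], 2.0, 5.0)
    pemt = stats.beta.ppf(u[:, 1], 2.0, 4.0)

    stroma = rng.uniform(0.02, 0.10, size=(n, 3))     # endothelial/macrophage/T
    if config.stroma_pemt_confound > 0:
        c = config.stroma_pemt_confound
        ranks = stats.rankdata(pemt) / n
        stroma[:, 1] = 0.02 + 0.08 * (c * ranks + (1 - c) * rng.random(n))
    rare = rng.uniform(0.01, 0.03, size=n)
    other = stroma.sum(axis=1) + rare
    # keep the cancer compartment at >= 10%
    scale = np.minimum(1.0, (1.0 - 0.1 - caf) / np.maximum(other, 1e-12))
    stroma *= scale[:, None]
    rare *= scale
    cancer = 1.0 - caf - stroma.sum(axis=1) - rare
    return caf, pemt, stroma, rare, cancer


def _sample_clinical(config: SyntheticConfig, rng: np.random.Generator,
                     sample_ids: list[str]) -> pd.DataFrame:
    n = config.n_samples
    days = np.round(rng.lognormal(6.0, 0.8, size=n), 0)
    days[rng.random(n) < 0.3] = np.nan
    table = pd.DataFrame({
        "sample_id": sample_ids,
        "subtype": "synthetic",
        "lymph_node_count": rng.choice([0, 0, 0, 1, 2, 3, 5, 8], size=n),
        "n_stage": rng.choice(["n0", "n1", "n2", "n3"], size=n, p=[0.4, 0.2, 0.25, 0.15]),
        "lymphovascular_invasion": rng.choice(["yes", "no"], size=n),
        "grade": rng.choice(["g1", "g2", "g3", "g4", "high grade", "low grade"],
                            size=n, p=[0.15, 0.3, 0.3, 0.1, 0.05, 0.1]),
        "t_stage": rng.choice(["t1", "t2", "t3", "t4"], size=n, p=[0.2, 0.3, 0.35, 0.15]),
        "days_to_death": days,
        "followup_outcome": rng.choice(
            ["complete remission/response", "recurred/progressed",
             "stable disease", "partial remission/response"],
            size=n, p=[0.45, 0.3, 0.15, 0.1]),
        "m_stage": rng.choice(["m0", "m1", "mx"], size=n, p=[0.7, 0.1, 0.2]),
    })
    return table


def generate_bulk_cohort(config: SyntheticConfig, truth: GroundTruth | None = None) -> BulkCohort:
    """Simulate a bulk cohort of noisy convex archetype mixtures.

    The planted clinical effect shifts the pEMT exposure (cancer fraction x
    pEMT fraction) of the worse-prognosis group of the configured feature by
    ``shift`` standard deviations of that exposure.  Purity is the cancer
    fraction.  Ground-truth fractions are recorded on ``truth`` when given.
    """
    from .clinical import binarize_feature  # local import to avoid a cycle

    model = build_model(config)
    rng = np.random.default_rng([config.seed, 303])
    n = config.n_samples
    sample_ids = [f"tumour{i:04d}" for i in range(n)]

    caf, pemt, stroma, rare, cancer = _sample_fractions(config, rng)
    clinical = _sample_clinical(config, rng, sample_ids)

    feature, _, shift = config.clinical_effect
    if shift != 0:
        groups = binarize_feature(clinical, feature)
        worse = (groups == "worse").to_numpy()
        exposure_sd = np.std(cancer * pemt)
        pemt = np.clip(pemt + worse * shift * exposure_sd / np.maximum(cancer, 1e-9), 0.0, 1.0)

    weights = pd.DataFrame({
        "cancer_pemt": cancer * pemt,
        "cancer_nonpemt": cancer * (1.0 - pemt),
        "CAF": caf,
        "endothelial": stroma[:, 0],
        "macrophage": stroma[:, 1],
        "T cell": stroma[:, 2],
        "rare": rare,
    }, index=sample_ids)

    arche = model.archetypes()                      # genes x ARCHETYPES
    mix = arche.to_numpy() @ weights.to_numpy().T   # genes x samples, linear TPM
    if config.bulk_noise_sd > 0:
        mix = mix * np.exp(rng.normal(0.0, config.bulk_noise_sd, size=mix.shape))
    linear = pd.DataFrame(mix, index=model.genes, columns=sample_ids)

    purity = pd.Series(cancer, index=sample_ids, name="purity")
    if truth is not None:
        truth.caf_fraction = pd.Series(caf, index=sample_ids)
        truth.pemt_fraction = pd.Series(pemt, index=sample_ids)
        truth.clinical_effect = config.clinical_effect

    return BulkCohort(
        expression=ExpressionMatrix(np.log2(linear / 10.0 + 1.0), scale=SCALE_LOG2_TPM10),
        expression_tpm=ExpressionMatrix(linear, scale=SCALE_TPM),
        purity=purity,
        clinical=clinical,
        weights=weights,
    )


# ----------------------------------------------------------------- cell lines

def generate_cellline_profiles(config: SyntheticConfig,
                               truth: GroundTruth | None = None) -> ExpressionMatrix:
    """Average cancer-only profiles (log2(TPM/10 + 1)).

    Each line is a mixture of the two cancer archetypes with an independent
    pEMT admixture and multiplicative noise; CAF genes are therefore depleted
    relative to any matched bulk cohort.
    """
    model = build_model(config)
    rng = np.random.default_rng([config.seed, 404])
    lo, hi = config.cellline_pemt_mix
    u = rng.uniform(lo, hi, size=config.n_cell_lines)
    arche = model.archetypes()
    profiles = (np.outer(arche["cancer_nonpemt"], 1.0 - u)
                + np.outer(arche["cancer_pemt"], u))
    if config.cellline_noise_sd > 0:
        profiles = profiles * np.exp(
            rng.normal(0.0, config.cellline_noise_sd, size=profiles.shape))
    cols = [f"line{i:02d}" for i in range(config.n_cell_lines)]
    data = pd.DataFrame(np.log2(profiles / 10.0 + 1.0), index=model.genes, columns=cols)
    return ExpressionMatrix(data, scale=SCALE_LOG2_TPM10)


# ------------------------------------------------- ESG source lists (GMT-like)

def planted_gene_sets(truth: GroundTruth, seed: int = 0) -> dict[str, list[str]]:
    """Hallmark/Tan-style source lists covering the planted programs.

    The two lists overlap (as the real curated sets do) and together cover all
    planted pEMT + CAF + shared genes, plus a few decoys that the cell-type
    filter downstream should remove.
    """
    rng = np.random.default_rng([seed, 505])
    pemt, caf, shared = list(truth.pemt_genes), list(truth.caf_genes), list(truth.shared_genes)
    decoys = [g for gs in truth.confounder_genes.values() for g in gs[:5]]
    hallmark = sorted(set(caf) | set(pemt[: len(pemt) // 2]) | set(shared) | set(decoys[:8]))
    tan = sorted(set(pemt) | set(caf[: len(caf) // 2]) | set(shared[: len(shared) // 2])
                 | set(decoys[8:]))
    rng.shuffle(hallmark)
    rng.shuffle(tan)
    return {"HALLMARK_EMT_SYNTHETIC": hallmark, "TAN_EMT_SYNTHETIC": tan}


# ----------------------------------------------- cross-cancer score archetypes

def generate_score_archetypes(n_types: int = 12, n_archetypes: int = 3,
                              n_genes: int = 100, noise_sd: float = 0.15,
                              seed: int = 0):
    """Per-gene pEMT-CAF score profiles for synthetic cancer types drawn from a
    few archetypes, for exercising cross-cancer clustering.

    Returns ``(scores, labels)``: a genes x types DataFrame in [-1, 1] and the
    planted archetype label per type.
    """
    rng = np.random.default_rng([seed, 606])
    arche = rng.uniform(-0.8, 0.8, size=(n_genes, n_archetypes))
    labels = np.arange(n_types) % n_archetypes
    rng.shuffle(labels)
    scores = arche[:, labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_types))
    scores = np.clip(scores, -1.0, 1.0)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    types = [f"type{i:02d}" for i in range(n_types)]
    return pd.DataFrame(scores, index=genes, columns=types), pd.Series(labels, index=types)


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with every program shift and CNA removed (pure noise)."""
    cfg = SyntheticConfig(caf_shift=0.0, pemt_shift=0.0, shared_caf_shift=0.0,
                          shared_pemt_shift=0.0, caf_on_pemt_shift=0.0,
                          marker_shift=0.0, epithelial_shift=0.0, cna_blocks=[])
    return replace(cfg, **overrides)
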