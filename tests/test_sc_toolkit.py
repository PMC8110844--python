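"""Preprocessing, control-binned scoring, CNA inference and malignant calls."""

import numpy as np
import pandas as pd
import pytest

import emtdecouple as ed
import emtdecouple.sc as scm
from emtdecouple.containers import ExpressionMatrix, SCALE_LOG2_TPM10, SCALE_TPM


def _matrix(values, scale=SCALE_LOG2_TPM10, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells),
                            scale=scale)


# ------------------------------------------------------------- normalization

@pytest.mark.parametrize("tpm,expected", [
    (0.0, 0.0),
    (10.0, 1.0),               # log2(2) = 1
    (990.0, np.log2(100.0)),   # ~6.6439
])
def test_normalize_tpm_closed_form(tpm, expected):
    m = _matrix([[tpm]], scale=SCALE_TPM)
    assert scm.normalize_tpm(m).data.iloc[0, 0] == pytest.approx(expected)


def test_normalize_rejects_log_input():
    with pytest.raises(ValueError):
        scm.normalize_tpm(_matrix([[1.0]], scale=SCALE_LOG2_TPM10))


# ---------------------------------------------------------- complexity filter

def test_complexity_filter_strict_threshold():
    """A cell with 999 detected genes is removed, one with exactly 1000 kept."""
    n = 1200
    values = np.zeros((n, 3))
    values[:999, 0] = 1.0
    values[:1000, 1] = 1.0
    values[:, 2] = 1.0
    m = _matrix(values)
    out = scm.filter_low_complexity_cells(m, min_genes=1000)
    assert list(out.sample_ids) == ["c1", "c2"]
    # all cells above threshold: identity
    full = scm.filter_low_complexity_cells(m, min_genes=10)
    assert list(full.sample_ids) == ["c0", "c1", "c2"]


def test_complexity_filter_empty_result_errors():
    with pytest.raises(ValueError):
        scm.filter_low_complexity_cells(_matrix([[1.0]]), min_genes=5)


# -------------------------------------------------------------------- scoring

def test_score_constant_genes_is_zero():
    """With every gene at one shared constant, controls equal signature genes
    and the score vanishes for every cell."""
    m = _matrix(np.full((10, 5), 2.0))
    cfg = scm.ScoringConfig(n_bins=2, n_controls=3, seed=0)
    scores = scm.score_signature(m, ["g0", "g5"], cfg)
    np.testing.assert_allclose(scores, 0.0, atol=1e-12)


def test_score_linearity_in_signature_shift():
    """Adding c to all signature genes in one cell, with controls unchanged,
    raises exactly that cell's score by exactly c."""
    # constant genes with well-separated means keep binning and control draws
    # identical before and after the shift; the seed is one whose control
    # sample does not happen to include the signature gene itself
    values = np.tile(np.arange(30, dtype=float)[:, None], (1, 30))
    sig = ["g0"]
    cfg = scm.ScoringConfig(n_bins=3, n_controls=5, seed=0)
    base = scm.score_signature(_matrix(values), sig, cfg)
    shifted = values.copy()
    shifted[0, 4] += 0.25
    new = scm.score_signature(_matrix(shifted), sig, cfg)
    delta = new - base
    assert delta["c4"] == pytest.approx(0.25, abs=1e-12)
    np.testing.assert_allclose(delta.drop("c4"), 0.0, atol=1e-12)


def test_score_matches_closed_form_with_degenerate_bins():
    """When all genes within a bin share one expression vector, any control
    draw is equivalent and the score has a closed form."""
    low = np.tile([[1.0, 2.0, 3.0, 4.0]], (10, 1))
    high = np.tile([[5.0, 6.0, 7.0, 9.0]], (10, 1))
    values = np.vstack([low, high])
    values[3] = [1.0, 2.0, 3.0, 4.0]       # signature gene in the low bin
    values[15] = [5.0, 6.0, 7.0, 9.0]      # signature gene in the high bin
    m = _matrix(values)
    cfg = scm.ScoringConfig(n_bins=2, n_controls=3, seed=42)
    scores = scm.score_signature(m, ["g3", "g15"], cfg)
    # each signature gene equals its bin's control mean -> relative expr 0
    np.testing.assert_allclose(scores, 0.0, atol=1e-12)
    # lifting one signature gene above its (unchanged) bin gives exactly the lift
    lifted = values.copy()
    lifted[3] = lifted[3] + 0.4
    got = scm.score_signature(_matrix(lifted), ["g3", "g15"],
                              scm.ScoringConfig(n_bins=2, n_controls=3, seed=42))
    np.testing.assert_allclose(got, 0.2, atol=1e-12)   # mean over 2 sig genes


def test_score_errors():
    m = _matrix(np.ones((5, 3)))
    with pytest.raises(ValueError, match="signature"):
        scm.score_signature(m, ["absent"], scm.ScoringConfig(n_bins=2, n_controls=2))
    with pytest.raises(ValueError, match="bins"):
        scm.score_signature(m, ["g0"], scm.ScoringConfig(n_bins=10, n_controls=2))


def test_score_grouped_runs_per_tumour(dataset):
    meta = dataset["meta"]
    cfg = scm.ScoringConfig(n_bins=10, n_controls=20, seed=0,
                            group_key="patient_id")
    scores = scm.score_signature(dataset["sclog"], dataset["truth"].caf_genes,
                                 cfg, meta=meta)
    assert scores.notna().all()
    caf_cells = meta.loc[meta["cell_type"] == "CAF", "cell_id"]
    other = meta.loc[meta["cell_type"] != "CAF", "cell_id"]
    assert scores[caf_cells].mean() > scores[other].mean()


def test_scoring_more_complexity_robust_than_naive_mean():
    """On null data with varying library size, the control-binned score
    correlates less with genes detected than the naive mean (paired seeds)."""
    gaps = []
    for seed in range(8):
        cfg = ed.null_config(n_cells=200, seed=seed, capture_range=(0.04, 1.0))
        matrix, _, _, _ = ed.generate_sc_dataset(cfg)
        mlog = scm.normalize_tpm(matrix)
        gd = scm.genes_detected(mlog)
        sig = list(np.random.default_rng(seed).choice(mlog.data.index, 40,
                                                      replace=False))
        binned = scm.score_signature(mlog, sig,
                                     scm.ScoringConfig(seed=seed))
        naive = scm.naive_mean_score(mlog, sig)
        gaps.append(abs(np.corrcoef(naive, gd)[0, 1])
                    - abs(np.corrcoef(binned, gd)[0, 1]))
    assert all(g > 0 for g in gaps)


# ------------------------------------------------------------------------ CNA

def test_cna_reference_cells_average_to_zero(dataset):
    meta = dataset["meta"]
    ref = list(meta.loc[meta["cell_type"].isin(["endothelial", "macrophage",
                                                "T cell"]), "cell_id"])
    cna = scm.infer_cna(dataset["sclog"], dataset["positions"], ref)
    np.testing.assert_allclose(cna.values[ref].mean(axis=1), 0.0, atol=1e-9)


def test_cna_window_one_is_adjusted_relative_expression():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 5, size=(12, 6))
    m = _matrix(values)
    pos = pd.DataFrame({"chrom": ["chr1"] * 12, "start": range(12),
                        "end": range(1, 13), "gene": [f"g{i}" for i in range(12)]})
    ref = ["c0", "c1"]
    cna = scm.infer_cna(m, pos, ref, window=1)
    rel = m.data.sub(m.data.mean(axis=1), axis=0)
    rel = rel.sub(rel.mean(axis=0), axis=1)
    expected = rel.sub(rel[ref].mean(axis=1), axis=0)
    np.testing.assert_allclose(cna.values.to_numpy(),
                               expected.loc[cna.values.index].to_numpy(),
                               atol=1e-12)


def test_cna_planted_block_detected(dataset):
    meta, truth = dataset["meta"], dataset["truth"]
    ref = list(meta.loc[meta["cell_type"].isin(["endothelial", "macrophage",
                                                "T cell"]), "cell_id"])
    cna = scm.infer_cna(dataset["sclog"], dataset["positions"], ref)
    chrom, lo, hi, _ = truth.cna_blocks[0]
    pos = cna.positions
    block = pos.loc[(pos["chrom"] == chrom) & (pos["start"] // 1000 >= lo)
                    & (pos["start"] // 1000 < hi), "gene"]
    cancer = list(meta.loc[meta["cell_type"] == "cancer", "cell_id"])
    inside = cna.values.loc[cna.values.index.isin(block), cancer].mean().mean()
    outside = cna.values.loc[~cna.values.index.isin(block), cancer].mean().mean()
    assert inside > outside + 0.1


def test_cna_errors():
    m = _matrix(np.ones((4, 3)))
    pos = pd.DataFrame({"chrom": ["chr1"] * 4, "start": range(4),
                        "end": range(1, 5), "gene": [f"g{i}" for i in range(4)]})
    with pytest.raises(ValueError, match="reference"):
        scm.infer_cna(m, pos, [])


# ------------------------------------------------------------------ summaries

def test_cna_summary_closed_forms():
    genes = ["g0", "g1", "g2"]
    values = pd.DataFrame({"a": [0.1, -0.2, 0.3], "b": [0.0, 0.0, 0.0],
                           "c": [0.1, -0.2, 0.3]}, index=genes)
    cna = scm.CnaResult(values=values, window=1, positions=pd.DataFrame())
    summary = scm.cna_summary(cna, ["a"])
    assert summary.loc["a", "cna_signal"] == pytest.approx((0.01 + 0.04 + 0.09) / 3)
    assert summary.loc["b", "cna_signal"] == 0.0
    assert np.isnan(summary.loc["b", "cna_correlation"])   # zero variance
    assert summary.loc["c", "cna_correlation"] == pytest.approx(1.0)


def test_cna_summary_subclones_take_best_match():
    genes = [f"g{i}" for i in range(4)]
    values = pd.DataFrame({
        "s1": [1.0, 1.0, 0.0, 0.0], "s2": [0.0, 0.0, 1.0, 1.0],
        "x": [1.0, 0.9, 0.1, 0.0]}, index=genes)
    cna = scm.CnaResult(values=values, window=1, positions=pd.DataFrame())
    summary = scm.cna_summary(cna, ["s1", "s2"],
                              subclones={"A": ["s1"], "B": ["s2"]})
    assert summary.loc["x", "cna_correlation"] == pytest.approx(
        np.corrcoef(values["x"], values["s1"])[0, 1])


def test_classify_malignant_partitions_and_thresholds():
    summary = pd.DataFrame({
        "cna_signal": [0.01, 0.30, 0.30, 0.01],
        "cna_correlation": [0.0, 0.9, 0.1, 0.9],
    }, index=["low_low", "high_high", "high_low", "low_high"])
    flags = scm.classify_malignant(summary, (0.05, 0.1, 0.3, 0.5))
    assert flags["low_low"] == "non_malignant"
    assert flags["high_high"] == "malignant"
    assert flags["high_low"] == "excluded"
    assert flags["low_high"] == "excluded"
    assert set(flags) <= {"malignant", "non_malignant", "excluded"}
    with pytest.raises(ValueError):
        scm.classify_malignant(summary, (0.2, 0.1, 0.3, 0.5))


# ----------------------------------------------- epithelial marker comparison

def test_epithelial_marker_filter_rules():
    values = np.zeros((3, 100))
    values[0] = 50.0                       # passes mean-TPM rule
    values[1, :2] = 2000.0                 # log2(201) > 7 in 2% of cells
    values[2] = 1.0                        # fails both
    m = _matrix(values, scale=SCALE_TPM, genes=["CDH1", "KRT5", "SFN"])
    kept = scm.filter_epithelial_markers(m, ["CDH1", "KRT5", "SFN"],
                                         mean_tpm_threshold=10.0)
    assert kept == ["CDH1", "KRT5"]


def test_epithelial_correlation_identity_and_null():
    rng = np.random.default_rng(1)
    cells = [f"c{i}" for i in range(40)]
    score = pd.Series(rng.uniform(1.0, 5.0, size=40), index=cells)
    values = np.vstack([score.to_numpy(), rng.uniform(1.0, 5.0, size=40)])
    m = _matrix(values, genes=["mirror", "noise"], cells=cells)
    meta = pd.DataFrame({"cell_id": cells, "patient_id": ["t1"] * 20 + ["t2"] * 20,
                         "cell_type": "cancer", "malignant": "malignant"})
    avg, z = scm.epithelial_emt_correlation(m, meta, ["mirror", "noise"], score)
    assert avg["mirror"] == pytest.approx(1.0)
    assert abs(avg["noise"]) < 0.5
    assert z.shape == (2, 40)
    # single tumour: the average equals that tumour's correlation
    meta1 = meta.assign(patient_id="t1")
    avg1, _ = scm.epithelial_emt_correlation(m, meta1, ["mirror"], score)
    assert avg1["mirror"] == pytest.approx(1.0)
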