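"""Confounder weighting, residualization, STS seriation and refinement."""

import itertools

import numpy as np
import pandas as pd
import pytest

import emtdecouple.deconvolve as dc
from emtdecouple.containers import ExpressionMatrix, SCALE_LOG2_TPM10
from conftest import two_block_correlation, end_recovery


def _bulk(values, genes):
    cols = [f"s{i}" for i in range(np.asarray(values).shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols),
                            scale=SCALE_LOG2_TPM10)


# --------------------------------------------------------- confounder weights

def test_confounder_weights_null_and_override():
    rng = np.random.default_rng(0)
    genes = [f"e{i}" for i in range(20)] + ["m0", "m1", "m2", "m3"]
    bulk = _bulk(rng.uniform(0, 5, size=(24, 100)), genes)
    markers = {"macrophage": ["m0", "m1"], "T cell": ["m2", "m3"]}
    model = dc.confounder_weights(bulk, genes[:20], markers, quantile_q=0.75)
    assert model.weights.abs().max() < 0.25          # null cohort: W ~ 0
    forced = dc.confounder_weights(bulk, genes[:20], markers,
                                   overrides={"macrophage": 1.0})
    assert forced.weights.to_dict() == {"macrophage": 1.0, "T cell": 0.0}


def test_confounder_weights_median_hand_computed():
    """q=0.5 weight equals the median of the per-ESG average correlations."""
    rng = np.random.default_rng(1)
    n_s = 50
    driver = rng.uniform(0, 3, size=n_s)
    rows = {f"e{i}": np.clip(w * driver + rng.uniform(0, 1, n_s), 0, None)
            for i, w in enumerate([0.0, 0.3, 0.6, 1.0, 2.0])}
    rows["mk"] = driver
    bulk = _bulk(np.array(list(rows.values())), list(rows))
    model = dc.confounder_weights(bulk, list(rows)[:5], {"mac": ["mk"]},
                                  quantile_q=0.5)
    expected = np.median([np.corrcoef(rows[f"e{i}"], driver)[0, 1]
                          for i in range(5)])
    assert model.weights["mac"] == pytest.approx(expected)


def test_confounder_weights_missing_markers():
    bulk = _bulk(np.random.default_rng(2).uniform(0, 5, (4, 20)),
                 ["a", "b", "c", "m0"])
    with pytest.warns(UserWarning):
        model = dc.confounder_weights(bulk, ["a", "b"],
                                      {"mac": ["m0", "absent"]})
    assert list(model.rho.columns) == ["mac"]
    with pytest.raises(ValueError):
        dc.confounder_weights(bulk, ["a"], {"mac": ["absent"]})


def test_score_and_select_brute_force():
    rho = pd.DataFrame({"mac": [0.9, 0.0, 0.5, -0.2, 0.3, 0.1]},
                       index=["VIM", "a", "b", "c", "d", "e"])
    model = dc.ConfounderModel(rho=rho, weights=pd.Series({"mac": 1.0}),
                               quantile_q=0.75)
    # SC = -rho: order c(0.2) > a(0.0) > e(-0.1) > d(-0.3) > b(-0.5) > VIM(-0.9)
    assert dc.score_and_select_esgs(model, 3) == ["c", "a", "e", "VIM"]
    # W all zero: stable gene order, top n
    null = dc.ConfounderModel(rho=rho, weights=pd.Series({"mac": 0.0}),
                              quantile_q=0.75)
    assert dc.score_and_select_esgs(null, 2)[:2] == ["VIM", "a"]


# -------------------------------------------------------------- residualizing

def test_residualize_proportional_gene_vanishes():
    """Every gene an affine function of one driver: each is proportional to
    the centred sum S, so all residuals vanish."""
    driver = np.array([1.0, 2.0, 3.0, 4.0])
    bulk = _bulk(np.array([driver, 3.0 * driver, 2.0 * driver + 1.0]),
                 ["a", "b", "c"])
    res = dc.residualize_esgs(bulk, ["a", "b", "c"])
    np.testing.assert_allclose(res.residuals.to_numpy(), 0.0, atol=1e-10)


def test_residualize_matches_normal_equations():
    """4-sample worked case: residuals equal closed-form OLS residuals and are
    exactly uncorrelated with the sample sums."""
    rng = np.random.default_rng(4)
    values = rng.uniform(0, 5, size=(5, 4))
    bulk = _bulk(values, list("abcde"))
    res = dc.residualize_esgs(bulk, list("abcde"))
    sv = bulk.data.sum(axis=0).to_numpy()
    for i, g in enumerate("abcde"):
        y = values[i]
        alpha = np.cov(y, sv, bias=True)[0, 1] / np.var(sv)
        beta = y.mean() - alpha * sv.mean()
        np.testing.assert_allclose(res.residuals.loc[g], y - (alpha * sv + beta),
                                   atol=1e-10)
        assert abs(np.corrcoef(res.residuals.loc[g], sv)[0, 1]) < 1e-8


def test_residualize_degenerate_sum_warns():
    values = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])  # constant sums
    bulk = _bulk(values, ["a", "b"])
    with pytest.warns(UserWarning, match="constant"):
        res = dc.residualize_esgs(bulk, ["a", "b"])
    np.testing.assert_allclose(res.residuals.loc["a"], [-1.0, 0.0, 1.0])


def test_residual_decorrelation_on_synthetic(deconv_result):
    res = deconv_result.residualized
    s = res.sample_sums
    for g in res.residuals.index[:50]:
        r = res.residuals.loc[g]
        assert abs(np.corrcoef(r, s)[0, 1]) < 1e-8


# ------------------------------------------------------------------------ STS

def test_sts_two_block_matrix_stays_contiguous():
    corr = two_block_correlation(20)
    result = dc.spin_sts_order(corr, seed=None)
    labels = [g < "g10" for g in result.order]
    assert labels == sorted(labels) or labels == sorted(labels, reverse=True)
    # energy trace is non-increasing
    assert all(b <= a + 1e-9 for a, b in zip(result.energies,
                                             result.energies[1:]))


def test_sts_reversal_has_equal_energy():
    corr = two_block_correlation(12, within=0.7, between=-0.3)
    dist = 1.0 - corr.to_numpy()
    w = dc._sts_weights(12)
    rng = np.random.default_rng(0)
    perm = rng.permutation(12)
    assert dc.sts_energy(dist, perm, w) == pytest.approx(
        dc.sts_energy(dist, perm[::-1], w))


def test_sts_random_starts_recover_blocks():
    corr = two_block_correlation(20)
    for seed in range(20):
        result = dc.spin_sts_order(corr, seed=seed)
        labels = [g < "g10" for g in result.order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)


def test_sts_result_is_local_optimum_small_n():
    """On tiny matrices the returned energy lies in the exhaustively
    enumerated set of STS local optima."""
    rng = np.random.default_rng(3)
    for n in (5, 6, 7):
        values = rng.uniform(-0.5, 0.9, size=(n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        corr = pd.DataFrame(values, index=[f"g{i}" for i in range(n)],
                            columns=[f"g{i}" for i in range(n)])
        optima = dc.enumerate_sts_local_optima(corr)
        result = dc.spin_sts_order(corr, seed=0)
        energy = round(result.energies[-1], 9)
        assert any(abs(energy - e) < 1e-6 for e in optima)


def test_sts_rejects_bad_input():
    bad = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], index=["a", "b"],
                       columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        dc.spin_sts_order(bad)
    nan = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"],
                       columns=["a", "b"])
    with pytest.raises(ValueError, match="NaN"):
        dc.spin_sts_order(nan)


# ----------------------------------------------------------------- refinement

def _controlled_sigma_corr():
    """6-gene correlation matrix with hand-controllable end averages
    (n_end=2: top = first two of the order, bottom = last two)."""
    genes = ["t1", "t2", "k1", "VIM", "b1", "b2"]
    corr = pd.DataFrame(np.eye(6), index=genes, columns=genes)

    def set_pair(a, b, v):
        corr.loc[a, b] = corr.loc[b, a] = v

    # t1/t2 and b1/b2 are the ends; k1 has sigma1=0.5, sigma2=-0.5;
    # VIM has sigma1=0.3, sigma2=0.2 (same sign -> classical retention)
    set_pair("t1", "t2", 0.9)
    set_pair("b1", "b2", 0.9)
    set_pair("t1", "b1", -0.8); set_pair("t1", "b2", -0.8)
    set_pair("t2", "b1", -0.8); set_pair("t2", "b2", -0.8)
    set_pair("k1", "t1", 0.5); set_pair("k1", "t2", 0.5)
    set_pair("k1", "b1", -0.5); set_pair("k1", "b2", -0.5)
    set_pair("VIM", "t1", 0.3); set_pair("VIM", "t2", 0.3)
    set_pair("VIM", "b1", 0.2); set_pair("VIM", "b2", 0.2)
    return corr


def test_refine_rule_application():
    corr = _controlled_sigma_corr()
    order = ["t1", "t2", "k1", "VIM", "b1", "b2"]
    result = dc.refine_ordering(corr, order, n_end=2)
    table = result.table
    assert table.loc["k1", "sigma1"] == pytest.approx(0.5)
    assert table.loc["k1", "sigma2"] == pytest.approx(-0.5)
    assert table.loc["k1", "key"] == pytest.approx(0.5)
    assert table.loc["k1", "cluster"] == "endA"
    # same-sign gene is removed unless classical
    assert "VIM" in table.index and table.loc["VIM", "retained_classical"]
    mutated = corr.rename(index={"VIM": "x1"}, columns={"VIM": "x1"})
    removed = dc.refine_ordering(mutated, ["t1", "t2", "k1", "x1", "b1", "b2"],
                                 n_end=2)
    assert "x1" in removed.removed


def test_refine_requires_enough_genes():
    corr = two_block_correlation(20)
    with pytest.raises(ValueError):
        dc.refine_ordering(corr, list(corr.index), n_end=20)


def test_end_to_end_recovery_and_order_invariance(dataset, deconv_result):
    truth = dataset["truth"]
    assert end_recovery(deconv_result, truth) >= 0.9
    # permuting the input gene order leaves cluster memberships intact
    rng = np.random.default_rng(0)
    shuffled = list(rng.permutation(truth.esg_genes))
    other = dc.run_deconvolution(dataset["bulk"].expression, shuffled,
                                 markers_per_type=truth.confounder_genes)
    def membership(result):
        a = frozenset(result.table.index[result.table["cluster"] == "endA"])
        b = frozenset(result.table.index[result.table["cluster"] == "endB"])
        return {a, b}
    assert membership(deconv_result) == membership(other)
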