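"""NB GLM engine, normalization, dispersion and regulatory classes.

The GLM is checked against two independent oracles: a brute-force
likelihood grid search on small designs and statsmodels' NB GLM.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from translatome import dte
from translatome.dte import CountMatrix


def _two_group_cm(counts, conditions, assay="rna"):
    counts = pd.DataFrame(
        np.atleast_2d(counts),
        index=[f"g{i}" for i in range(np.atleast_2d(counts).shape[0])],
        columns=[f"s{i}" for i in range(len(conditions))],
    )
    design = pd.DataFrame(
        {"sample_id": counts.columns, "condition": conditions}
    )
    return CountMatrix(counts, design, assay)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_hand_computed():
    counts = np.array([[2, 8], [50, 200]])
    np.testing.assert_allclose(dte.size_factors(counts), [0.5, 2.0])


def test_size_factors_identical_columns_are_unit():
    counts = np.tile([[5], [10], [20]], (1, 4))
    np.testing.assert_allclose(dte.size_factors(counts), np.ones(4))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(0.25, 4.0), col=st.integers(0, 3))
def test_size_factor_scale_equivariance(scale, col):
    """Scaling one column by c multiplies its factor by c, relative to the
    others (the geometric-mean reference renormalizes by c**(1/m))."""
    rng = np.random.default_rng(1)
    counts = rng.poisson(50, size=(30, 4)) + 1.0
    base = dte.size_factors(counts)
    scaled = counts.copy()
    scaled[:, col] *= scale
    new = dte.size_factors(scaled)
    rel_new = new / np.exp(np.log(new).mean())
    rel_base = base / np.exp(np.log(base).mean())
    expected = rel_base[col] * scale / scale ** (1 / 4)
    assert rel_new[col] == pytest.approx(expected, rel=1e-9)
    # factor ratios against an unscaled column change by exactly c
    other = (col + 1) % 4
    assert new[col] / new[other] == pytest.approx(
        scale * base[col] / base[other], rel=1e-9
    )


def test_size_factors_error_without_positive_reference():
    counts = np.array([[0, 5], [5, 0]])
    with pytest.raises(ValueError, match="median-of-ratios"):
        dte.size_factors(counts)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_dispersion_poisson_limit_and_recovery():
    rng = np.random.default_rng(0)
    cond = np.array(["a"] * 10 + ["b"] * 10)
    pois = rng.poisson(100, size=(2000, 20))
    alpha_hat = dte.estimate_dispersion(pois, cond, np.ones(20))
    assert np.median(alpha_hat) <= 0.01
    r, mu = 1 / 0.2, 100
    nb = rng.negative_binomial(r, r / (r + mu), size=(2000, 20))
    alpha_hat = dte.estimate_dispersion(nb, cond, np.ones(20))
    assert 0.1 <= np.median(alpha_hat) <= 0.3


def test_dispersion_constant_gene_truncates_to_zero():
    counts = np.full((1, 6), 7.0)
    alpha = dte.estimate_dispersion(
        counts, np.array(["a"] * 3 + ["b"] * 3), np.ones(6), prior_df=0.0
    )
    assert alpha[0] == 0.0


# ---------------------------------------------------------------------------
# GLM engine vs oracles
# ---------------------------------------------------------------------------

def test_poisson_two_group_mle_is_log_mean_ratio():
    y = np.array([10, 10, 10, 20, 20, 20], dtype=float)
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    fit = dte.fit_nb_glm(y, X, alpha=0.0)
    assert fit.converged
    assert fit.beta[0] == pytest.approx(np.log(10), abs=1e-8)
    assert fit.beta[1] == pytest.approx(np.log(2), abs=1e-8)


def test_glm_deviance_matches_grid_search_oracle():
    """Brute-force likelihood maximization over a fine coefficient grid."""
    y = np.array([3, 8, 5, 14, 19, 11], dtype=float)
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    offset = np.log(np.array([0.8, 1.0, 1.2, 0.9, 1.0, 1.1]))
    alpha = 0.15
    fit = dte.fit_nb_glm(y, X, offset, alpha)
    assert fit.converged

    def grid_max(b0_range, b1_range, n):
        best, arg = -np.inf, None
        for beta0, beta1 in itertools.product(
            np.linspace(*b0_range, n), np.linspace(*b1_range, n)
        ):
            ll = dte.nb_loglik(y, np.exp(X @ [beta0, beta1] + offset), alpha)
            if ll > best:
                best, arg = ll, (beta0, beta1)
        return best, arg

    _, coarse = grid_max((0.0, 5.0), (-2.0, 2.0), 101)
    best, _ = grid_max(
        (coarse[0] - 0.1, coarse[0] + 0.1), (coarse[1] - 0.1, coarse[1] + 0.1), 401
    )
    ll_hat = dte.nb_loglik(y, np.exp(X @ fit.beta + offset), alpha)
    # the fitted likelihood dominates the grid, and the deviance gap
    # (2 x log-likelihood gap; the saturated term is shared) is < 1e-4
    assert ll_hat >= best - 1e-9
    assert 2.0 * (ll_hat - best) < 1e-4


def test_glm_matches_statsmodels_negative_binomial():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(12), rng.integers(0, 2, 12), rng.normal(0, 1, 12)])
    mu = np.exp(X @ [3.0, 0.7, 0.2])
    alpha = 0.1
    r = 1 / alpha
    y = rng.negative_binomial(r, r / (r + mu)).astype(float)
    fit = dte.fit_nb_glm(y, X, alpha=alpha)
    ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    np.testing.assert_allclose(fit.beta, ref.params, atol=1e-5)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-3)


def test_all_zero_response_flags_non_convergence():
    y = np.zeros(6)
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    fit = dte.fit_nb_glm(y, X, alpha=0.1)
    assert not fit.converged
    assert np.all(np.isfinite(fit.beta))


def test_rank_deficient_design_rejected():
    X = np.column_stack([np.ones(6), np.ones(6)])
    with pytest.raises(ValueError, match="rank"):
        dte.fit_nb_glm(np.arange(6.0) + 1, X, alpha=0.0)


# ---------------------------------------------------------------------------
# DEG / DTEG behaviour
# ---------------------------------------------------------------------------

def test_deg_all_zero_gene_convention():
    counts = np.array([[0, 0, 0, 0], [10, 12, 30, 28]])
    cm = _two_group_cm(counts, ["normal", "normal", "tumour", "tumour"])
    res = dte.test_deg(cm)
    assert res.loc["g0", "pvalue"] == 1.0
    assert res.loc["g0", "log2FC"] == 0.0


def test_dteg_interaction_cancels_shared_fold_change():
    """Noise-free means with a null-gene-dominated background (so the
    median-of-ratios factors are exactly 1): an equal fold change at both
    assay levels gives a zero interaction; a Ribo-only 4-fold change
    gives log2FC_te = 2."""
    n = 4
    conditions = ["normal"] * n + ["tumour"] * n
    null_means = np.array([20, 50, 80, 120, 200, 400, 35, 65], dtype=float)
    null_block = np.repeat(null_means[:, None], 2 * n, axis=1)
    rna = np.vstack(
        [null_block, [[100] * n + [200] * n], [[100] * n + [100] * n]]
    ).astype(float)
    ribo = np.vstack(
        [null_block, [[100] * n + [200] * n], [[100] * n + [400] * n]]
    ).astype(float)
    rna_cm = _two_group_cm(rna, conditions, "rna")
    ribo_cm = _two_group_cm(ribo, conditions, "ribo")
    res = dte.test_dteg(rna_cm, ribo_cm, dispersions=np.zeros(10))
    shared, te_only = res.index[8], res.index[9]
    assert res.loc[shared, "log2FC"] == pytest.approx(0.0, abs=1e-6)
    assert res.loc[shared, "pvalue"] > 0.9
    assert res.loc[te_only, "log2FC"] == pytest.approx(2.0, abs=1e-6)
    assert res.loc[te_only, "pvalue"] < 0.05


def test_compute_te_ratio_and_epsilon_guard():
    conditions = ["normal", "normal", "tumour", "tumour"]
    ones = np.ones(4)
    rna = _two_group_cm(np.array([[4, 4, 4, 4], [0, 0, 0, 0], [5, 5, 5, 5]]), conditions, "rna")
    ribo = _two_group_cm(np.array([[10, 10, 10, 10], [5, 5, 5, 5], [5, 5, 5, 5]]), conditions, "ribo")
    te = dte.compute_te(rna, ribo, ones, ones)
    assert te.loc["g0", "te_tumour"] == pytest.approx(2.5)
    assert te.loc["g1", "te_normal"] == pytest.approx(5.0)  # eps guard
    # at fixed size factors, doubling the ribo counts doubles TE
    ribo2 = _two_group_cm(2 * ribo.counts.to_numpy(), conditions, "ribo")
    te2 = dte.compute_te(rna, ribo2, ones, ones)
    np.testing.assert_allclose(te2.to_numpy(), 2 * te.to_numpy(), rtol=1e-9)
    # recomputed median-of-ratios factors are scale-invariant, so the
    # doubling propagates there too
    te3 = dte.compute_te(rna, ribo2)
    np.testing.assert_allclose(
        te3.to_numpy(), 2 * dte.compute_te(rna, ribo).to_numpy(), rtol=1e-9
    )


# ---------------------------------------------------------------------------
# regulatory classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p_rna,lfc_rna,p_te,lfc_te,expected",
    [
        (0.01, 1.0, 0.5, 0.3, "forwarded"),
        (0.5, 0.2, 0.01, 1.0, "exclusive"),
        (0.01, 1.0, 0.01, 0.8, "intensified"),
        (0.01, 1.0, 0.01, -1.0, "buffered"),
        (0.5, 0.1, 0.5, 0.1, "not_significant"),
    ],
)
def test_regulatory_class_definitions(p_rna, lfc_rna, p_te, lfc_te, expected):
    df = pd.DataFrame(
        {
            "p_rna": [p_rna],
            "log2FC_rna": [lfc_rna],
            "p_te": [p_te],
            "log2FC_te": [lfc_te],
        },
        index=["g"],
    )
    assert dte.classify_regulatory(df).iloc[0] == expected


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    p_rna=st.floats(1e-6, 1.0),
    p_te=st.floats(1e-6, 1.0),
    lfc_rna=st.floats(-5, 5),
    lfc_te=st.floats(-5, 5),
)
def test_classification_is_total_and_consistent(p_rna, p_te, lfc_rna, lfc_te):
    df = pd.DataFrame(
        {
            "p_rna": [p_rna],
            "log2FC_rna": [lfc_rna],
            "p_te": [p_te],
            "log2FC_te": [lfc_te],
        }
    )
    label = dte.classify_regulatory(df).iloc[0]
    assert label in dte.REGULATORY_CLASSES
    if label != "not_significant":
        assert p_rna < 0.05 or p_te < 0.05


def test_classification_permutes_with_gene_order(planted_sim):
    rna, ribo, truth = planted_sim
    res = dte.run_dte(rna, ribo)
    perm = np.random.default_rng(0).permutation(len(res))
    assert (
        res["regulatory_class"].iloc[perm].to_numpy()
        == res.iloc[perm]["regulatory_class"].to_numpy()
    ).all()


def test_bh_adjustment_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8, 1.0])
    adj = dte.bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
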