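"""Differential expression and differential translation efficiency.

Count model
-----------
Counts are modelled as negative binomial with mean ``mu`` and dispersion
``alpha`` (variance ``mu + alpha * mu**2``).  Per-sample sequencing depth
enters as a log size-factor offset (median-of-ratios factors).  Gene-wise
dispersions are method-of-moments estimates shrunk toward a fitted
mean-dispersion trend.

Differential expression at either assay level is a Wald test on the
condition coefficient of a log-link NB GLM.  Differential translation
efficiency is the Wald test on the ``condition:assay`` interaction of a
single NB GLM fit to the stacked RNA + Ribo counts of each gene, so a
fold-change shared by both assays cancels and only a change in the
Ribo/RNA ratio (i.e. in TE) loads on the interaction.

Genes significant at the RNA level, the TE level, or both are assigned to
four regulatory classes: *forwarded* (RNA only), *exclusive* (TE only),
*intensified* (both, same direction) and *buffered* (both, opposing
directions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

LN2 = np.log(2.0)

REGULATORY_CLASSES = (
    "forwarded",
    "exclusive",
    "intensified",
    "buffered",
    "not_significant",
)


@dataclass
class CountMatrix:
    """A feature x sample count matrix for one assay plus its design.

    ``design`` has one row per sample with at least columns ``sample_id``
    and ``condition``; ``assay`` labels the whole matrix (``rna`` or
    ``ribo``).
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    assay: str = "rna"

    def __post_init__(self):
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise ValueError("count columns and design sample_id differ")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def conditions(self) -> np.ndarray:
        return self.design["condition"].to_numpy()


@dataclass
class NbFit:
    """Result of one NB GLM fit."""

    beta: np.ndarray
    se: np.ndarray
    alpha: float
    deviance: float
    converged: bool
    iterations: int


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample the factor is the median over genes of
    ``count / geometric_mean(count across samples)``, restricted to genes
    whose geometric mean is positive (i.e. genes with no zero count).
    """
    x = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_x = np.log(x)
    positive = np.all(x > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "cannot form the median-of-ratios reference"
        )
    log_gm = log_x[positive].mean(axis=1)
    ratios = log_x[positive] - log_gm[:, None]
    return np.exp(np.median(ratios, axis=0))


def estimate_dispersion(
    counts: pd.DataFrame | np.ndarray,
    conditions: np.ndarray,
    factors: np.ndarray | None = None,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Per-gene NB dispersion, trend-shrunk method of moments.

    Raw gene-wise estimates ``max(0, (s2 - m) / m**2)`` are pooled across
    condition groups (weights = within-group degrees of freedom) on
    size-factor-normalized counts, then shrunk toward a mean-dispersion
    trend ``a0 + a1 / mu`` with weight proportional to the pooled degrees
    of freedom relative to ``prior_df``.
    """
    x = np.asarray(counts, dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    if factors is None:
        factors = size_factors(x)
    norm = x / factors[None, :]

    conditions = np.asarray(conditions)
    num = np.zeros(n_genes)
    total_df = 0.0
    mu_bar = np.zeros(n_genes)
    weight_mu = 0.0
    for level in np.unique(conditions):
        cols = conditions == level
        n_c = int(cols.sum())
        if n_c < 2:
            continue
        m = norm[:, cols].mean(axis=1)
        s2 = norm[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        raw = np.clip(raw, 0.0, None)
        num += (n_c - 1) * raw
        mu_bar += n_c * m
        total_df += n_c - 1
        weight_mu += n_c
    if total_df == 0:
        raise ValueError("at least one condition needs >= 2 samples")
    raw_alpha = num / total_df
    mu_bar = mu_bar / weight_mu

    trend = _dispersion_trend(mu_bar, raw_alpha)
    w = total_df / (total_df + prior_df)
    return np.clip(w * raw_alpha + (1.0 - w) * trend, 0.0, None)


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu over informative genes."""
    ok = (mu > 0) & np.isfinite(alpha)
    if ok.sum() < 10:
        med = float(np.median(alpha[ok])) if ok.any() else 0.0
        return np.full_like(alpha, max(med, 0.0))
    a = alpha[ok]
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    # one trimming pass to blunt the influence of outlying raw estimates
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    resid = a - design @ coef
    keep = np.abs(resid) <= 3.0 * max(np.std(resid), 1e-12)
    if keep.sum() >= 10:
        coef, *_ = np.linalg.lstsq(design[keep], a[keep], rcond=None)
    a0 = max(coef[0], 0.0)
    a1 = max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-12)
    return np.where(mu > 0, trend, a0)


# ---------------------------------------------------------------------------
# NB GLM engine
# ---------------------------------------------------------------------------

_ETA_MAX = 30.0


def nb_loglik(y, mu, alpha):
    """NB2 log-likelihood (Poisson limit at alpha == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def nb_deviance(y, mu, alpha):
    """Twice the log-likelihood gap to the saturated model."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    ypos = np.maximum(y, 1e-12)
    if alpha <= 0:
        dev = y * np.log(ypos / mu) - (y - mu)
    else:
        r = 1.0 / alpha
        dev = y * np.log(ypos / mu) - (y + r) * np.log((y + r) / (mu + r))
    return float(2.0 * np.sum(dev))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NbFit:
    """Fit a log-link NB GLM with fixed dispersion by Fisher scoring (IRLS).

    Wald standard errors come from the expected information
    ``X' W X`` with ``w = mu / (1 + alpha * mu)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    mu = np.maximum(y, 0.0) + 0.5
    eta = np.log(mu) - offset
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta + offset, -_ETA_MAX, _ETA_MAX))
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(xw.T @ X, xw.T @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        beta = beta_new
        eta = X @ beta
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    mu = np.exp(np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX))
    w = mu / (1.0 + alpha * mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    if y.sum() == 0:
        converged = False
    return NbFit(
        beta=beta,
        se=se,
        alpha=alpha,
        deviance=nb_deviance(y, mu, alpha),
        converged=converged,
        iterations=it,
    )


def _wald(fit: NbFit, index: int) -> tuple[float, float]:
    """(log2FC, two-sided p) for one coefficient."""
    se = fit.se[index]
    if not np.isfinite(se) or se <= 0:
        return 0.0, 1.0
    z = fit.beta[index] / se
    p = 2.0 * stats.norm.sf(abs(z))
    return fit.beta[index] / LN2, float(min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# gene-level testing
# ---------------------------------------------------------------------------

def _condition_indicator(conditions: np.ndarray) -> np.ndarray:
    """0/1 coding with 'normal' (or the first sorted level) as reference."""
    levels = sorted(set(conditions))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    if "normal" in levels:
        ref = "normal"
    else:
        ref = levels[0]
    return np.asarray([0.0 if c == ref else 1.0 for c in conditions])


def test_deg(
    cm: CountMatrix,
    factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene Wald test of the condition effect at one assay level.

    All-zero genes get ``log2FC = 0, p = 1`` by convention.
    """
    counts = cm.counts.to_numpy(dtype=float)
    cond = _condition_indicator(cm.conditions)
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, cm.conditions, factors)
    X = np.column_stack([np.ones(counts.shape[1]), cond])
    offset = np.log(factors)

    lfc = np.zeros(counts.shape[0])
    pval = np.ones(counts.shape[0])
    for g in range(counts.shape[0]):
        y = counts[g]
        if y.sum() == 0:
            continue
        fit = fit_nb_glm(y, X, offset, float(dispersions[g]))
        lfc[g], pval[g] = _wald(fit, 1)
    return pd.DataFrame(
        {"log2FC": lfc, "pvalue": pval}, index=cm.counts.index
    )


def test_dteg(
    rna: CountMatrix,
    ribo: CountMatrix,
    dispersions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Interaction Wald test for differential translation efficiency.

    One NB GLM per gene on the stacked RNA+Ribo counts with design
    ``~ condition + assay + condition:assay``; size factors are computed
    per assay and enter as offsets; the dispersion is shared between the
    two assays of a gene.
    """
    if not rna.counts.index.equals(ribo.counts.index):
        raise ValueError("RNA and Ribo matrices must share the gene index")
    for cm, name in ((rna, "rna"), (ribo, "ribo")):
        if "condition" not in cm.design.columns:
            raise ValueError(f"{name} design lacks a condition column")

    rna_x = rna.counts.to_numpy(dtype=float)
    ribo_x = ribo.counts.to_numpy(dtype=float)
    f_rna = size_factors(rna_x)
    f_ribo = size_factors(ribo_x)
    cond = np.concatenate(
        [_condition_indicator(rna.conditions), _condition_indicator(ribo.conditions)]
    )
    assay = np.concatenate(
        [np.zeros(rna_x.shape[1]), np.ones(ribo_x.shape[1])]
    )
    X = np.column_stack([np.ones(cond.size), cond, assay, cond * assay])
    offset = np.log(np.concatenate([f_rna, f_ribo]))

    if dispersions is None:
        d_rna = estimate_dispersion(rna_x, rna.conditions, f_rna)
        d_ribo = estimate_dispersion(ribo_x, ribo.conditions, f_ribo)
        dispersions = 0.5 * (d_rna + d_ribo)

    n_genes = rna_x.shape[0]
    lfc = np.zeros(n_genes)
    pval = np.ones(n_genes)
    for g in range(n_genes):
        y = np.concatenate([rna_x[g], ribo_x[g]])
        if y.sum() == 0:
            continue
        fit = fit_nb_glm(y, X, offset, float(dispersions[g]))
        lfc[g], pval[g] = _wald(fit, 3)
    return pd.DataFrame(
        {"log2FC": lfc, "pvalue": pval}, index=rna.counts.index
    )


def compute_te(
    rna: CountMatrix,
    ribo: CountMatrix,
    factors_rna: np.ndarray | None = None,
    factors_ribo: np.ndarray | None = None,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-condition translation efficiency.

    TE is the ratio of the mean normalized Ribo count to the mean
    normalized RNA count; ``eps`` replaces the denominator only when the
    RNA mean is exactly zero.  Size factors are median-of-ratios per
    assay unless supplied explicitly.
    """
    if not rna.counts.index.equals(ribo.counts.index):
        raise ValueError("RNA and Ribo matrices must share the gene index")
    f_rna = size_factors(rna.counts) if factors_rna is None else np.asarray(factors_rna)
    f_ribo = size_factors(ribo.counts) if factors_ribo is None else np.asarray(factors_ribo)
    norm_rna = rna.counts.to_numpy(dtype=float) / f_rna[None, :]
    norm_ribo = ribo.counts.to_numpy(dtype=float) / f_ribo[None, :]
    out = {}
    for level in sorted(set(rna.conditions)):
        rcols = rna.conditions == level
        bcols = ribo.conditions == level
        m_rna = norm_rna[:, rcols].mean(axis=1)
        m_ribo = norm_ribo[:, bcols].mean(axis=1)
        denom = np.where(m_rna == 0, eps, m_rna)
        out[f"te_{level}"] = m_ribo / denom
    return pd.DataFrame(out, index=rna.counts.index)


def classify_regulatory(
    results: pd.DataFrame,
    alpha_sig: float = 0.05,
) -> pd.Series:
    """Four-class regulatory categorization of DEG/DTEG calls.

    Input needs columns ``p_rna``, ``log2FC_rna``, ``p_te``, ``log2FC_te``.
    """
    for col in ("p_rna", "log2FC_rna", "p_te", "log2FC_te"):
        if col not in results.columns:
            raise ValueError(f"missing column {col}")
        if results[col].isna().any():
            raise ValueError(f"NaN in column {col}")
    rna_sig = results["p_rna"] < alpha_sig
    te_sig = results["p_te"] < alpha_sig
    same_sign = np.sign(results["log2FC_rna"]) == np.sign(results["log2FC_te"])
    labels = np.where(
        rna_sig & ~te_sig,
        "forwarded",
        np.where(
            te_sig & ~rna_sig,
            "exclusive",
            np.where(
                rna_sig & te_sig & same_sign,
                "intensified",
                np.where(rna_sig & te_sig, "buffered", "not_significant"),
            ),
        ),
    )
    return pd.Series(labels, index=results.index, name="regulatory_class")


def run_dte(
    rna: CountMatrix,
    ribo: CountMatrix,
    alpha_sig: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full per-gene analysis: DEG at both assay levels, DTEG, TE, class.

    With ``fdr=True`` the class assignment uses Benjamini-Hochberg
    adjusted p-values instead of raw ones.
    """
    deg_rna = test_deg(rna)
    deg_ribo = test_deg(ribo)
    dteg = test_dteg(rna, ribo)
    te = compute_te(rna, ribo)
    res = pd.DataFrame(
        {
            "log2FC_rna": deg_rna["log2FC"],
            "p_rna": deg_rna["pvalue"],
            "log2FC_ribo": deg_ribo["log2FC"],
            "p_ribo": deg_ribo["pvalue"],
            "log2FC_te": dteg["log2FC"],
            "p_te": dteg["pvalue"],
        },
        index=rna.counts.index,
    )
    res = res.join(te)
    if fdr:
        res["p_rna_adj"] = bh_adjust(res["p_rna"].to_numpy())
        res["p_te_adj"] = bh_adjust(res["p_te"].to_numpy())
        cls_input = res.rename(
            columns={"p_rna_adj": "p_rna", "p_te_adj": "p_te"}
        )[["p_rna", "log2FC_rna", "p_te", "log2FC_te"]]
    else:
        cls_input = res
    res["regulatory_class"] = classify_regulatory(cls_input, alpha_sig)
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)
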