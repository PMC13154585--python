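"""Comparison of 5'UTR regulatory features between gene sets.

Binary features (uORF presence, TOP element, predicted IRES, m6A site
presence) are compared as gene ratios with a two-sided Fisher exact test
(minimum-likelihood rule).  Continuous features (AU content, IRES
probability, cumulative m6A motif score) are compared with the two-sided
Wilcoxon rank-sum test: exact null for combined n <= 25, normal
approximation with tie and continuity corrections above.

The feature table is an input: uORF and TOP flags, IRES probabilities
and m6A site scores come from upstream resources; the cumulative m6A
score of a gene is the plain sum of its site scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BINARY_FEATURES = {
    "uORF": "has_uorf",
    "TOP": "has_top",
    "IRES_predicted": None,  # derived from ires_prob >= threshold
    "m6A_site": None,  # derived from cumulative m6a / site list
}
CONTINUOUS_FEATURES = {
    "AU_content": "au_content",
    "prob_IRES": "ires_prob",
    "cumulative_m6A": "cumulative_m6a",
}

EXACT_WILCOXON_MAX_N = 25


class FeatureCoverageError(ValueError):
    """A gene set lacks feature annotation for too many genes."""


@dataclass
class FeatureComparison:
    """One feature's target-vs-control comparison."""

    feature: str
    target: float
    control: float
    test: str
    pvalue: float


def cumulative_m6a_score(sites) -> float:
    """Sum of m6A site scores; 0 for no sites.

    ``sites`` is an iterable of (position, score) pairs or bare scores.
    """
    total = 0.0
    for site in sites:
        score = site[1] if isinstance(site, (tuple, list)) else site
        if score < 0:
            raise ValueError(f"negative m6A site score: {score}")
        total += float(score)
    return total


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p: exact when small and tie-free, else normal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size + y.size
    ties = np.unique(np.concatenate([x, y])).size < n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p (scipy's minimum-likelihood convention)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _subset(features: pd.DataFrame, genes, label: str) -> pd.DataFrame:
    present = features.index.intersection(genes)
    if len(present) < 0.5 * len(genes):
        raise FeatureCoverageError(
            f"features missing for more than half of the {label} set "
            f"({len(present)}/{len(genes)} covered)"
        )
    return features.loc[present]


def compare_sets(
    target_genes,
    control_genes,
    features: pd.DataFrame,
    ires_threshold: float = 0.5,
) -> pd.DataFrame:
    """Feature-wise comparison of a target gene set against controls.

    Returns one row per feature with the target and control gene ratio
    (binary features) or mean (continuous features), the test used, and
    the two-sided p-value.
    """
    target_genes = list(dict.fromkeys(target_genes))
    control_genes = list(dict.fromkeys(control_genes))
    if not target_genes or not control_genes:
        raise ValueError("gene sets must be non-empty")
    if set(target_genes) & set(control_genes):
        raise ValueError("target and control gene sets must be disjoint")
    tgt = _subset(features, target_genes, "target")
    ctl = _subset(features, control_genes, "control")

    tgt = tgt.assign(
        _ires_bin=tgt["ires_prob"] >= ires_threshold,
        _m6a_bin=tgt["cumulative_m6a"] > 0,
    )
    ctl = ctl.assign(
        _ires_bin=ctl["ires_prob"] >= ires_threshold,
        _m6a_bin=ctl["cumulative_m6a"] > 0,
    )
    binary_cols = {
        "uORF": "has_uorf",
        "TOP": "has_top",
        "IRES_predicted": "_ires_bin",
        "m6A_site": "_m6a_bin",
    }

    rows = []
    for name, col in binary_cols.items():
        a, b = int(tgt[col].sum()), int((~tgt[col].astype(bool)).sum())
        c, d = int(ctl[col].sum()), int((~ctl[col].astype(bool)).sum())
        rows.append(
            FeatureComparison(
                feature=name,
                target=a / (a + b),
                control=c / (c + d),
                test="fisher_exact",
                pvalue=fisher_two_sided([[a, b], [c, d]]),
            )
        )
    for name, col in CONTINUOUS_FEATURES.items():
        x, y = tgt[col].to_numpy(float), ctl[col].to_numpy(float)
        if np.array_equal(np.sort(x), np.sort(y)):
            p = 1.0  # identical samples carry no evidence either way
        else:
            p = wilcoxon_rank_sum(x, y)
        rows.append(
            FeatureComparison(
                feature=name,
                target=float(x.mean()),
                control=float(y.mean()),
                test="wilcoxon_rank_sum",
                pvalue=p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")


def au_fraction(sequence: str) -> float:
    """A+U (A+T) fraction of a nucleotide sequence; convenience helper."""
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    return sum(1 for b in seq if b in "AU") / len(seq)
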