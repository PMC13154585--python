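"""Consolidation and classification of de novo ORF call sets.

Per-sample ORF calls (any caller) are consolidated into a catalog by the
reproducibility rule *detected in >= min_samples tumour samples OR
>= min_samples normal samples*, followed by longest-ORF deduplication
among ORFs sharing a start or an end coordinate on the same transcript
and strand.  Retained ORFs are categorized by their relation to the host
gene's annotated CDS, classified for group specificity from Ribo-seq TPM
percentile ranks, and assigned to the four expression clusters C1-C4
from RNA- and Ribo-level differential calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import Annotation

ORF_CATEGORIES = ("annotated", "in_frame", "out_of_frame", "lncORF")
SPECIFICITY_CLASSES = ("tumour_specific", "normal_specific", "both", "neither")
EXPRESSION_CLUSTERS = ("C1", "C2", "C3", "C4", "none")


class DesignError(ValueError):
    """Sample labelling problem."""


class CoverageError(ValueError):
    """Required per-ORF results are missing."""


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def consolidate(
    callsets: dict,
    groups: dict,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Consolidate per-sample call sets into the retained ORF catalog.

    ``callsets`` maps sample id to a call table with columns ``orf_id``,
    ``transcript_id``, ``start``, ``end``, ``strand`` (``caller``
    optional: an ORF counts as detected in a sample if any caller reports
    it).  ``groups`` maps sample id to 'tumour' or 'normal'.

    Returns one row per retained ORF with detection counts, group
    retention flags and the union of reporting callers.
    """
    unlabelled = sorted(set(callsets) - set(groups))
    if unlabelled:
        raise DesignError(f"samples without group label: {unlabelled}")
    bad = {s: g for s, g in groups.items() if g not in ("tumour", "normal")}
    if bad:
        raise DesignError(f"group labels must be tumour/normal: {bad}")

    frames = []
    for sample, calls in callsets.items():
        if calls.empty:
            continue
        df = calls.copy()
        df["sample_id"] = sample
        df["group"] = groups[sample]
        frames.append(df)
    if not frames:
        raise DesignError("all call sets are empty")
    calls = pd.concat(frames, ignore_index=True)
    if "caller" not in calls.columns:
        calls["caller"] = "unknown"

    per_orf = (
        calls.groupby("orf_id")
        .agg(
            transcript_id=("transcript_id", "first"),
            start=("start", "first"),
            end=("end", "first"),
            strand=("strand", "first"),
            callers=("caller", lambda c: ",".join(sorted(set(c)))),
        )
    )
    detected = calls.drop_duplicates(["orf_id", "sample_id"])
    n_by_group = (
        detected.groupby(["orf_id", "group"])["sample_id"].nunique().unstack(fill_value=0)
    )
    per_orf["n_tumour"] = n_by_group.get("tumour", 0)
    per_orf["n_normal"] = n_by_group.get("normal", 0)
    per_orf[["n_tumour", "n_normal"]] = per_orf[["n_tumour", "n_normal"]].fillna(0).astype(int)
    per_orf["tumour_retained"] = per_orf["n_tumour"] >= min_samples
    per_orf["normal_retained"] = per_orf["n_normal"] >= min_samples
    retained = per_orf[per_orf["tumour_retained"] | per_orf["normal_retained"]]
    retained = retained.assign(length=retained["end"] - retained["start"])
    return _dedup(retained)


def _dedup(catalog: pd.DataFrame) -> pd.DataFrame:
    """Keep only the longest ORF among shared-start, then shared-end groups.

    Grouping is per transcript and strand; ties by length are broken by
    smallest start, then lexicographically smallest ORF id, so the result
    does not depend on input order.
    """
    df = catalog.copy()
    for coord in ("start", "end"):
        order = df.assign(_id=df.index).sort_values(
            by=["length", "start", "_id"], ascending=[False, True, True]
        )
        keep_ids = order.drop_duplicates(subset=["transcript_id", "strand", coord])["_id"]
        df = df.loc[df.index.isin(keep_ids)]
    return df.sort_index()


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def categorize(
    orf: pd.Series,
    annotation: Annotation,
) -> str:
    """Category of one ORF relative to its host transcript's CDS.

    lncORF if the host biotype is lncRNA; annotated if the coordinates
    match the annotated CDS exactly; otherwise in_frame or out_of_frame
    by ``(orf start - CDS start) mod 3``.
    """
    tid = orf["transcript_id"]
    if tid not in annotation:
        raise KeyError(f"transcript {tid} absent from annotation")
    t = annotation[tid]
    if t.biotype == "lncRNA" or not t.coding:
        return "lncORF"
    if orf["start"] == t.cds_start and orf["end"] == t.cds_end:
        return "annotated"
    return "in_frame" if (orf["start"] - t.cds_start) % 3 == 0 else "out_of_frame"


def categorize_catalog(catalog: pd.DataFrame, annotation: Annotation) -> pd.Series:
    return pd.Series(
        [categorize(row, annotation) for _, row in catalog.iterrows()],
        index=catalog.index,
        name="category",
    )


# ---------------------------------------------------------------------------
# TPM and specificity
# ---------------------------------------------------------------------------

def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalization.

    ``TPM_i = (count_i / length_i) / sum_j(count_j / length_j) * 1e6``
    per sample; columns sum to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"zero total rate in samples {zero}")
    return rate.div(totals, axis=1) * 1e6


def specificity_classify(
    tpm_matrix: pd.DataFrame,
    groups: dict,
    q_low: float = 0.10,
) -> pd.DataFrame:
    """Tumour/normal specificity from group-mean TPM percentile ranks.

    Within each group, every ORF's mean TPM is converted to a percentile
    rank among all catalog ORFs (ties take the maximum rank, so the
    smallest attainable rank is 1/n).  'Expressed' in a group means the
    rank is above the bottom-``q_low`` cut (rank > q_low, i.e. in the top
    90% for the default); the bottom decile is rank <= q_low.  An ORF is
    tumour-specific when expressed in tumours but not in normals;
    normal-specific is symmetric; 'both' requires expression in both
    groups, 'neither' in neither.
    """
    if tpm_matrix.empty:
        raise ValueError("empty catalog")
    samples = list(tpm_matrix.columns)
    tum = [s for s in samples if groups.get(s) == "tumour"]
    nor = [s for s in samples if groups.get(s) == "normal"]
    if not tum or not nor:
        raise DesignError("need samples in both groups")
    mean_t = tpm_matrix[tum].mean(axis=1)
    mean_n = tpm_matrix[nor].mean(axis=1)
    n = len(tpm_matrix)
    rank_t = rankdata(mean_t, method="max") / n
    rank_n = rankdata(mean_n, method="max") / n
    expressed_t = rank_t > q_low
    expressed_n = rank_n > q_low
    cls = np.where(
        expressed_t & ~expressed_n,
        "tumour_specific",
        np.where(
            expressed_n & ~expressed_t,
            "normal_specific",
            np.where(expressed_t & expressed_n, "both", "neither"),
        ),
    )
    return pd.DataFrame(
        {
            "mean_tpm_tumour": mean_t,
            "mean_tpm_normal": mean_n,
            "rank_tumour": rank_t,
            "rank_normal": rank_n,
            "specificity": cls,
        },
        index=tpm_matrix.index,
    )


# ---------------------------------------------------------------------------
# upregulated set and expression clusters
# ---------------------------------------------------------------------------

def upregulated_set(
    specificity: pd.Series,
    ribo_de: pd.DataFrame,
    alpha: float = 0.05,
) -> set:
    """Tumour-specific ORFs plus significantly tumour-upregulated 'both' ORFs.

    ``ribo_de`` needs columns ``log2FC`` and ``pvalue`` covering every
    'both' ORF; a missing record raises a coverage error.
    """
    tumour_specific = set(specificity.index[specificity == "tumour_specific"])
    both = specificity.index[specificity == "both"]
    missing = sorted(set(both) - set(ribo_de.index))
    if missing:
        raise CoverageError(f"no Ribo-level DE record for 'both' ORFs: {missing[:5]}")
    sub = ribo_de.loc[both]
    up = set(sub.index[(sub["pvalue"] < alpha) & (sub["log2FC"] > 0)])
    return tumour_specific | up


def expression_cluster(
    rna_de: pd.DataFrame,
    ribo_de: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """C1-C4 cluster from RNA- and Ribo-level differential calls.

    C1: RNA up only; C2: Ribo up only; C3: RNA down only; C4: Ribo down
    only; 'none' otherwise (including ORFs significant at both levels).
    """
    idx = rna_de.index
    if not idx.equals(ribo_de.index):
        raise CoverageError("RNA and Ribo DE tables must share the index")
    rna_sig = rna_de["pvalue"] < alpha
    ribo_sig = ribo_de["pvalue"] < alpha
    rna_up = rna_sig & (rna_de["log2FC"] > 0)
    rna_dn = rna_sig & (rna_de["log2FC"] < 0)
    ribo_up = ribo_sig & (ribo_de["log2FC"] > 0)
    ribo_dn = ribo_sig & (ribo_de["log2FC"] < 0)
    labels = np.select(
        [
            rna_up & ~ribo_sig,
            ribo_up & ~rna_sig,
            rna_dn & ~ribo_sig,
            ribo_dn & ~rna_sig,
        ],
        ["C1", "C2", "C3", "C4"],
        default="none",
    )
    return pd.Series(labels, index=idx, name="expression_cluster")


def build_catalog(
    callsets: dict,
    groups: dict,
    annotation: Annotation,
    ribo_counts: pd.DataFrame,
    lengths: pd.Series,
    rna_de: pd.DataFrame | None = None,
    ribo_de: pd.DataFrame | None = None,
    min_samples: int = 2,
    q_low: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """End-to-end catalog: consolidate, categorize, classify, cluster."""
    catalog = consolidate(callsets, groups, min_samples)
    catalog["category"] = categorize_catalog(catalog, annotation)
    tpm_matrix = tpm(
        ribo_counts.loc[ribo_counts.index.isin(catalog.index)],
        lengths,
    )
    spec = specificity_classify(tpm_matrix, groups, q_low)
    catalog = catalog.join(spec)
    if rna_de is not None and ribo_de is not None:
        shared = catalog.index.intersection(rna_de.index).intersection(ribo_de.index)
        clusters = expression_cluster(
            rna_de.loc[shared], ribo_de.loc[shared], alpha
        )
        catalog["expression_cluster"] = clusters.reindex(catalog.index).fillna("none")
    return catalog
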