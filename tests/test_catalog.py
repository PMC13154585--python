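"""ORF catalog rules: consolidation, dedup, categories, specificity."""

import numpy as np
import pandas as pd
import pytest

from translatome import catalog as cat
from translatome.annotation import Annotation, Transcript


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["orf_id", "transcript_id", "start", "end", "strand", "caller"]
    )


def _callsets(detections):
    """detections: dict sample -> list of (orf_id, start, end)."""
    out = {}
    for sample, orfs in detections.items():
        out[sample] = _calls(
            [(o, "tx", s, e, "+", "callerA") for o, s, e in orfs]
        )
    return out


GROUPS = {"T1": "tumour", "T2": "tumour", "T3": "tumour", "N1": "normal", "N2": "normal"}


def test_two_sample_rule_is_per_group():
    orf = ("orfA", 0, 300)
    # 2 tumour, 0 normal -> retained
    callsets = _callsets({"T1": [orf], "T2": [orf], "T3": [], "N1": [], "N2": []})
    result = cat.consolidate(callsets, GROUPS)
    assert "orfA" in result.index
    assert result.loc["orfA", "tumour_retained"]
    assert not result.loc["orfA", "normal_retained"]
    # 1 tumour + 1 normal -> discarded: neither group reaches 2
    callsets = _callsets({"T1": [orf], "T2": [], "T3": [], "N1": [orf], "N2": []})
    assert cat.consolidate(callsets, GROUPS).empty


def test_single_tumour_sample_orf_discarded():
    callsets = _callsets({"T1": [("orfR", 0, 90)], "T2": [], "T3": [], "N1": [], "N2": []})
    assert "orfR" not in cat.consolidate(callsets, GROUPS).index


def test_longest_orf_wins_shared_start_and_end():
    a, b = ("orfA", 100, 400), ("orfB", 100, 250)  # shared start
    c, d = ("orfC", 500, 900), ("orfD", 700, 900)  # shared end
    detections = {s: [a, b, c, d] for s in GROUPS}
    result = cat.consolidate(_callsets(detections), GROUPS)
    assert set(result.index) == {"orfA", "orfC"}


def test_dedup_tie_breaks_by_start_then_id():
    # same length and same end: smaller start wins; identical coords: lexicographic id
    a, b = ("orfB", 100, 400), ("orfA", 100, 400)
    detections = {s: [a, b] for s in GROUPS}
    result = cat.consolidate(_callsets(detections), GROUPS)
    assert set(result.index) == {"orfA"}


def test_consolidation_idempotent_and_order_independent():
    rng = np.random.default_rng(0)
    orfs = [(f"orf{i}", 10 * i, 10 * i + 30 * (1 + i % 3)) for i in range(12)]
    detections = {
        s: [o for o in orfs if rng.random() > 0.3] for s in GROUPS
    }
    callsets = _callsets(detections)
    first = cat.consolidate(callsets, GROUPS)
    # re-consolidating the retained calls changes nothing
    second_sets = {
        s: df[df["orf_id"].isin(first.index)] for s, df in callsets.items()
    }
    second = cat.consolidate(second_sets, GROUPS)
    pd.testing.assert_frame_equal(first, second)
    # input order does not matter
    shuffled = {s: df.sample(frac=1.0, random_state=1) for s, df in callsets.items()}
    third = cat.consolidate(shuffled, GROUPS)
    assert list(third.index) == list(first.index)


def test_unlabelled_sample_raises():
    callsets = _callsets({"T1": [("orfA", 0, 90)], "X9": [("orfA", 0, 90)]})
    with pytest.raises(cat.DesignError, match="X9"):
        cat.consolidate(callsets, GROUPS)


def test_multi_caller_counts_once_per_sample():
    calls = pd.concat(
        [
            _calls([("orfA", "tx", 0, 90, "+", "orfquant")]),
            _calls([("orfA", "tx", 0, 90, "+", "ribotricer")]),
        ]
    )
    callsets = {"T1": calls, "T2": calls.iloc[:1], "T3": _calls([]), "N1": _calls([]), "N2": _calls([])}
    result = cat.consolidate(callsets, GROUPS)
    assert result.loc["orfA", "n_tumour"] == 2
    assert result.loc["orfA", "callers"] == "orfquant,ribotricer"


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cat_annotation():
    return Annotation(
        [
            Transcript("txc", "geneC", 700, 100, 400, "protein_coding"),
            Transcript("txl", "geneL", 500, None, None, "lncRNA"),
        ]
    )


@pytest.mark.parametrize(
    "tid,start,end,expected",
    [
        ("txc", 100, 400, "annotated"),
        ("txc", 109, 400, "in_frame"),  # 9 into the CDS, mod 3 == 0
        ("txc", 104, 250, "out_of_frame"),  # 4 mod 3 == 1
        ("txl", 10, 100, "lncORF"),
    ],
)
def test_orf_categories(cat_annotation, tid, start, end, expected):
    orf = pd.Series({"transcript_id": tid, "start": start, "end": end})
    assert cat.categorize(orf, cat_annotation) == expected


def test_category_lookup_error(cat_annotation):
    orf = pd.Series({"transcript_id": "missing", "start": 0, "end": 9})
    with pytest.raises(KeyError):
        cat.categorize(orf, cat_annotation)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_single_feature_and_rate_ratio():
    counts = pd.DataFrame({"s1": [7]}, index=["a"])
    out = cat.tpm(counts, pd.Series({"a": 500}))
    assert out.loc["a", "s1"] == pytest.approx(1e6)

    counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
    out = cat.tpm(counts, pd.Series({"a": 1000, "b": 2000}))
    assert out.loc["a", "s1"] == pytest.approx(2e6 / 3)
    assert out.loc["b", "s1"] == pytest.approx(1e6 / 3)
    assert out["s1"].sum() == pytest.approx(1e6, abs=1e-3)


def test_tpm_zero_feature_and_zero_sample():
    counts = pd.DataFrame({"s1": [10, 0], "s2": [5, 0]}, index=["a", "b"])
    out = cat.tpm(counts, pd.Series({"a": 100, "b": 100}))
    assert (out.loc["b"] == 0).all()
    zero = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="zero total rate"):
        cat.tpm(zero, pd.Series({"a": 100, "b": 100}))


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def _tpm_toy():
    """10 ORFs; orf0 lowest in normal, mid-rank in tumour."""
    tum = np.arange(10, dtype=float) * 10 + 100
    tum[0] = 145  # 5th from the top in the tumour ranking
    nor = np.arange(10, dtype=float) * 10 + 100
    nor[0] = 1.0  # strictly lowest in normal
    idx = [f"orf{i}" for i in range(10)]
    return pd.DataFrame(
        {"T1": tum, "T2": tum, "N1": nor, "N2": nor}, index=idx
    )


def test_specificity_rank_arithmetic():
    groups = {"T1": "tumour", "T2": "tumour", "N1": "normal", "N2": "normal"}
    spec = cat.specificity_classify(_tpm_toy(), groups, q_low=0.10)
    assert spec.loc["orf0", "specificity"] == "tumour_specific"
    # orf1 holds the lowest tumour rank (orf0 overtook it), so it lands in
    # the tumour bottom decile while staying expressed in normals
    assert spec.loc["orf1", "specificity"] == "normal_specific"
    assert (spec.drop(["orf0", "orf1"])["specificity"] == "both").all()


def test_specificity_all_ties_classified_both():
    idx = [f"orf{i}" for i in range(10)]
    tied = pd.DataFrame(
        {"T1": 5.0, "T2": 5.0, "N1": 5.0, "N2": 5.0}, index=idx
    )
    groups = {"T1": "tumour", "T2": "tumour", "N1": "normal", "N2": "normal"}
    spec = cat.specificity_classify(tied, groups, q_low=0.10)
    assert (spec["specificity"] == "both").all()  # ties take the maximum rank


def test_specificity_empty_catalog_raises():
    with pytest.raises(ValueError):
        cat.specificity_classify(pd.DataFrame(), {"T1": "tumour"}, 0.1)


# ---------------------------------------------------------------------------
# upregulated set and expression clusters
# ---------------------------------------------------------------------------

def test_upregulated_union_clauses():
    spec = pd.Series(
        {"o1": "tumour_specific", "o2": "both", "o3": "both", "o4": "normal_specific"}
    )
    de = pd.DataFrame(
        {"log2FC": [0.5, -1.0], "pvalue": [0.04, 0.01]}, index=["o2", "o3"]
    )
    # o1 by clause (a) even without a DE record; o2 by clause (b); o3 wrong sign
    assert cat.upregulated_set(spec, de) == {"o1", "o2"}


def test_upregulated_missing_both_record_raises():
    spec = pd.Series({"o1": "both"})
    with pytest.raises(cat.CoverageError, match="o1"):
        cat.upregulated_set(spec, pd.DataFrame(columns=["log2FC", "pvalue"]))


@pytest.mark.parametrize(
    "rna,ribo,expected",
    [
        ((0.01, 1.0), (0.6, 0.2), "C1"),
        ((0.6, 0.1), (0.01, 1.0), "C2"),
        ((0.01, -1.0), (0.6, 0.2), "C3"),
        ((0.6, 0.1), (0.01, -1.0), "C4"),
        ((0.01, 1.0), (0.01, 1.0), "none"),  # significant at both levels
        ((0.6, 0.1), (0.6, 0.1), "none"),
    ],
)
def test_expression_clusters(rna, ribo, expected):
    rna_de = pd.DataFrame({"pvalue": [rna[0]], "log2FC": [rna[1]]}, index=["o"])
    ribo_de = pd.DataFrame({"pvalue": [ribo[0]], "log2FC": [ribo[1]]}, index=["o"])
    assert cat.expression_cluster(rna_de, ribo_de).loc["o"] == expected


# ---------------------------------------------------------------------------
# recovery on the synthetic bundle
# ---------------------------------------------------------------------------

def test_planted_specificity_recovery(orf_bundle):
    """>= 95% of planted tumour-specific ORFs recover their class."""
    result = cat.consolidate(orf_bundle.callsets, orf_bundle.groups)
    tpm_matrix = cat.tpm(
        orf_bundle.ribo_counts.counts.loc[result.index], orf_bundle.lengths
    )
    spec = cat.specificity_classify(tpm_matrix, orf_bundle.groups)
    truth = orf_bundle.truth.loc[result.index, "specificity"]
    planted_ts = truth.index[truth == "tumour_specific"]
    recovered = (spec.loc[planted_ts, "specificity"] == "tumour_specific").mean()
    assert recovered >= 0.95
    # partition: exactly one specificity class per retained ORF
    assert spec["specificity"].isin(cat.SPECIFICITY_CLASSES).all()
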