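"""Cross-referencing of immunopeptides against ORF translations.

MS-identified peptides are matched to the catalog's ORF protein
sequences by exact contiguous substring search (optionally with I/L
collapsed, since mass spectrometry cannot distinguish leucine from
isoleucine).  Peptides outside the retained 7-16 aa length window are
excluded before matching.  A peptide matching ORFs of several categories
is labelled by the precedence canonical > in_frame > out_of_frame >
lncORF; tumour-specific peptides are those present in at least one
tumour sample and absent from every normal sample.
"""

from __future__ import annotations

import pandas as pd

MIN_PEPTIDE_LEN = 7
MAX_PEPTIDE_LEN = 16

CATEGORY_PRECEDENCE = ("canonical", "in_frame", "out_of_frame", "lncORF")
_CANONICAL_ALIASES = {"annotated": "canonical", "canonical": "canonical"}

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class PeptideValidationError(ValueError):
    """A peptide contains non-amino-acid characters."""


def _normalize_category(category: str) -> str:
    return _CANONICAL_ALIASES.get(category, category)


def _il_collapse(seq: str) -> str:
    return seq.replace("I", "L")


def match_peptides(
    peptides: pd.DataFrame,
    proteins: dict,
    categories: dict | None = None,
    il_equivalent: bool = False,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> pd.DataFrame:
    """Match peptides to ORF translations by exact substring search.

    ``peptides`` has columns ``sample_id``, ``group``, ``peptide`` (an
    optional ``immunogenic`` column is passed through).  ``proteins``
    maps ORF id to its amino-acid sequence; ``categories`` maps ORF id to
    its catalog category (defaults to 'canonical' when absent).

    Returns one row per input record within the length window, annotated
    with matched ORF ids, the precedence-resolved source category, and a
    tumour-specific flag computed across samples.
    """
    for col in ("sample_id", "group", "peptide"):
        if col not in peptides.columns:
            raise ValueError(f"peptide table needs column {col}")
    categories = categories or {}

    bad = [
        p
        for p in peptides["peptide"].unique()
        if not set(p) <= VALID_AA
    ]
    if bad:
        raise PeptideValidationError(
            f"non-amino-acid characters in peptides: {bad[:5]}"
        )

    records = peptides.copy()
    lengths = records["peptide"].str.len()
    records = records[(lengths >= min_len) & (lengths <= max_len)].copy()

    search_proteins = {
        orf: (_il_collapse(seq.upper()) if il_equivalent else seq.upper())
        for orf, seq in proteins.items()
    }

    match_cache: dict[str, list] = {}

    def matches(peptide: str) -> list:
        if peptide not in match_cache:
            needle = _il_collapse(peptide) if il_equivalent else peptide
            match_cache[peptide] = sorted(
                orf for orf, seq in search_proteins.items() if needle in seq
            )
        return match_cache[peptide]

    records["matched_orfs"] = records["peptide"].map(
        lambda p: ",".join(matches(p))
    )

    def category_of(peptide: str) -> str:
        cats = {
            _normalize_category(categories.get(orf, "canonical"))
            for orf in matches(peptide)
        }
        for cat in CATEGORY_PRECEDENCE:
            if cat in cats:
                return cat
        return "unmatched"

    records["source_category"] = records["peptide"].map(category_of)

    specific = tumour_specific_peptides(records)
    records["tumour_specific"] = records["peptide"].isin(specific)
    return records.reset_index(drop=True)


def tumour_specific_peptides(records: pd.DataFrame) -> set:
    """Peptides seen in >= 1 tumour sample and in no normal sample."""
    if records["group"].isna().any():
        raise ValueError("every peptide record needs a group label")
    by_group = records.groupby("peptide")["group"].agg(set)
    return {
        pep
        for pep, groups in by_group.items()
        if "tumour" in groups and "normal" not in groups
    }


def summary_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Peptide counts by source category, total and tumour-specific."""
    unique = records.drop_duplicates("peptide")
    total = unique.groupby("source_category")["peptide"].nunique()
    specific = (
        unique[unique["tumour_specific"]]
        .groupby("source_category")["peptide"]
        .nunique()
    )
    out = pd.DataFrame(
        {"n_peptides": total, "n_tumour_specific": specific}
    ).fillna(0).astype(int)
    return out.sort_index()
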