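"""Readers and writers for the pipeline's tabular formats.

All tables are TSV with header rows.  Count matrices have features in
rows and a header of sample ids; m6A site lists are serialized as
``pos:score`` pairs joined by ``;``.  Protein sequences go through
Biopython FASTA.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dte import CountMatrix


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition"}
    if not required.issubset(design.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    return design


def read_count_matrix(counts_path, design_path, assay: str) -> CountMatrix:
    counts = read_counts(counts_path)
    design = read_design(design_path)
    if "assay" in design.columns:
        design = design[design["assay"] == assay].reset_index(drop=True)
    design = design.set_index("sample_id").loc[list(counts.columns)].reset_index()
    return CountMatrix(counts, design, assay)


def read_callsets(directory) -> dict:
    """One call-set TSV per sample: ``<sample_id>.tsv``."""
    callsets = {}
    for path in sorted(Path(directory).glob("*.tsv")):
        callsets[path.stem] = pd.read_csv(path, sep="\t")
    if not callsets:
        raise FileNotFoundError(f"no call-set TSV in {directory}")
    return callsets


def read_groups(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["group"]))


def _encode_sites(sites) -> str:
    return ";".join(f"{int(p)}:{s:g}" for p, s in sites)


def _decode_sites(text) -> list:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for item in text.split(";"):
        pos, score = item.split(":")
        out.append((int(pos), float(score)))
    return out


def write_features(features: pd.DataFrame, path) -> None:
    df = features.copy()
    if "m6a_sites" in df.columns:
        df["m6a_sites"] = df["m6a_sites"].map(_encode_sites)
    df.to_csv(path, sep="\t")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "m6a_sites" in df.columns:
        df["m6a_sites"] = df["m6a_sites"].map(_decode_sites)
    for col in ("has_uorf", "has_top"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_fasta(proteins: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=orf_id, description="")
        for orf_id, seq in sorted(proteins.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_peptides(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "peptide"}
    if not required.issubset(df.columns):
        raise ValueError(f"peptide table needs columns {sorted(required)}")
    return df


def write_bed12(catalog: pd.DataFrame, path, chrom_col: str = "transcript_id") -> None:
    """BED12 export of the catalog (transcript-space single-block records)."""
    rows = []
    for orf_id, row in catalog.iterrows():
        start, end = int(row["start"]), int(row["end"])
        rows.append(
            "\t".join(
                str(v)
                for v in (
                    row[chrom_col],
                    start,
                    end,
                    orf_id,
                    0,
                    row.get("strand", "+"),
                    start,
                    end,
                    "0,0,0",
                    1,
                    end - start,
                    0,
                )
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")
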