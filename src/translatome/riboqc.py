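"""Ribo-seq quality metrics.

Computes the standard footprint diagnostics: read-length distribution,
P-site offset calibration from a start-codon metagene, 3-nt periodicity
(fraction of P-sites in each reading frame), and partitioning of P-sites
over 5'UTR / CDS / 3'UTR.

Coordinates are 0-based, half-open transcript coordinates throughout.
The P-site of a read is its 5' end plus a length-specific offset; the
canonical default offset is 12 nt for ~30 nt footprints.  Reads are
counted only on each gene's canonical transcript (longest CDS, ties by
lexicographic id), and a read spanning a region boundary is assigned by
its P-site position alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation

DEFAULT_OFFSET = 12
MIN_READ_LENGTH = 25
MAX_READ_LENGTH = 50


class CalibrationError(RuntimeError):
    """No usable start-codon signal for a read length."""


class QcError(ValueError):
    """Invalid or empty QC input."""


@dataclass
class QcReport:
    """Summary of Ribo-seq quality metrics."""

    length_hist: dict = field(default_factory=dict)
    offsets: dict = field(default_factory=dict)
    frame_fractions: tuple = (np.nan, np.nan, np.nan)
    region_fractions: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "length_hist": {int(k): int(v) for k, v in self.length_hist.items()},
            "offsets": {int(k): int(v) for k, v in self.offsets.items()},
            "frame_fractions": [float(f) for f in self.frame_fractions],
            "region_fractions": {
                k: float(v) for k, v in self.region_fractions.items()
            },
        }


def _canonical_coding(annotation: Annotation) -> dict:
    """transcript_id -> Transcript for canonical coding transcripts."""
    out = {}
    for gene in annotation.genes:
        t = annotation.canonical(gene)
        if t.coding:
            out[t.transcript_id] = t
    return out


def calibrate_psite_offsets(
    reads: pd.DataFrame,
    annotation: Annotation,
    max_offset: int = 18,
) -> tuple[dict, pd.DataFrame]:
    """Per-read-length P-site offset from the start-codon metagene.

    For each read length the offset is the distance ``d`` (1..max_offset)
    maximizing the number of read 5' ends at ``start_codon - d`` across
    canonical coding transcripts; ties go to the smaller offset.  Returns
    the offset map and the supporting metagene profile (one row per
    length and candidate distance).
    """
    required = {"transcript_id", "five_prime", "length"}
    if not required.issubset(reads.columns):
        raise QcError(f"read table needs columns {sorted(required)}")
    coding = _canonical_coding(annotation)
    if not coding:
        raise QcError("annotation has no canonical coding transcript")

    sub = reads[reads["transcript_id"].isin(coding)].copy()
    cds_start = sub["transcript_id"].map({k: t.cds_start for k, t in coding.items()})
    sub["distance"] = cds_start - sub["five_prime"]

    offsets = {}
    profile_rows = []
    for length, grp in sub.groupby("length", sort=True):
        upstream = grp[(grp["distance"] >= 1) & (grp["distance"] <= max_offset)]
        counts = (
            upstream["distance"].value_counts().reindex(
                range(1, max_offset + 1), fill_value=0
            )
        )
        for d, c in counts.items():
            profile_rows.append(
                {"length": int(length), "distance": int(d), "count": int(c)}
            )
        if counts.sum() == 0:
            raise CalibrationError(
                f"no read of length {length} near any start codon"
            )
        offsets[int(length)] = int(counts.idxmax())  # idxmax: smallest argmax
    return offsets, pd.DataFrame(profile_rows)


def assign_psites(
    reads: pd.DataFrame,
    offsets: dict | int = DEFAULT_OFFSET,
) -> pd.DataFrame:
    """P-site positions from 5' ends plus per-length (or fixed) offsets."""
    if isinstance(offsets, int):
        off = np.full(len(reads), offsets)
    else:
        off = reads["length"].map(offsets).to_numpy()
        if np.isnan(off.astype(float)).any():
            missing = sorted(
                set(reads.loc[pd.isna(reads["length"].map(offsets)), "length"])
            )
            raise QcError(f"no offset for read lengths {missing}")
    out = reads.copy()
    out["psite"] = reads["five_prime"] + off
    return out


def frame_periodicity(
    psites: pd.DataFrame,
    annotation: Annotation,
) -> tuple[float, float, float]:
    """Fractions of in-CDS P-sites in frames 0, 1, 2 relative to the CDS."""
    coding = _canonical_coding(annotation)
    sub = psites[psites["transcript_id"].isin(coding)]
    if sub.empty:
        raise QcError("no P-site on a canonical coding transcript")
    cds_start = sub["transcript_id"].map({k: t.cds_start for k, t in coding.items()})
    cds_end = sub["transcript_id"].map({k: t.cds_end for k, t in coding.items()})
    in_cds = (sub["psite"] >= cds_start) & (sub["psite"] < cds_end)
    if not in_cds.any():
        raise QcError("zero in-CDS P-sites; periodicity undefined")
    frames = ((sub.loc[in_cds, "psite"] - cds_start[in_cds]) % 3).to_numpy()
    n = frames.size
    return tuple(float((frames == f).sum()) / n for f in (0, 1, 2))


def region_and_length_metrics(
    psites: pd.DataFrame,
    annotation: Annotation,
) -> QcReport:
    """Region partitioning (cds/utr5/utr3) and read-length histogram.

    P-sites outside their transcript's bounds raise a record-level
    validation error.
    """
    coding = _canonical_coding(annotation)
    sub = psites[psites["transcript_id"].isin(coding)]
    if sub.empty:
        raise QcError("no P-site on a canonical coding transcript")
    counts = {"cds": 0, "utr5": 0, "utr3": 0}
    for tid, grp in sub.groupby("transcript_id"):
        t = coding[tid]
        for pos in grp["psite"]:
            counts[t.region_of(int(pos))] += 1
    total = sum(counts.values())
    report = QcReport(
        length_hist=dict(
            psites["length"].value_counts().sort_index().astype(int)
        ),
        region_fractions={k: v / total for k, v in counts.items()},
    )
    return report


def qc_report(
    reads: pd.DataFrame,
    annotation: Annotation,
    offsets: dict | int | None = None,
    min_len: int = MIN_READ_LENGTH,
    max_len: int = MAX_READ_LENGTH,
) -> QcReport:
    """Full QC: length filter, offset calibration, periodicity, regions."""
    kept = reads[(reads["length"] >= min_len) & (reads["length"] <= max_len)]
    if kept.empty:
        raise QcError(f"no read within the retained window [{min_len}, {max_len}]")
    if offsets is None:
        offsets, _ = calibrate_psite_offsets(kept, annotation)
    psites = assign_psites(kept, offsets)
    report = region_and_length_metrics(psites, annotation)
    report.offsets = offsets if isinstance(offsets, dict) else {
        int(length): int(offsets) for length in kept["length"].unique()
    }
    report.frame_fractions = frame_periodicity(psites, annotation)
    return report
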