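"""Transcript-model annotation.

Internally every transcript is represented in transcript coordinates
(0-based, half-open).  GTF input (1-based, closed, genomic) is projected
onto transcript coordinates at the boundary by walking the exon chain in
transcription order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class Transcript:
    """One transcript model in transcript coordinates.

    ``cds_start``/``cds_end`` delimit the coding region (half-open);
    both are ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "protein_coding"

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_length(self) -> int:
        return 0 if not self.coding else self.cds_end - self.cds_start

    def region_of(self, pos: int) -> str:
        """Region label ('utr5' | 'cds' | 'utr3') for a transcript position."""
        if pos < 0 or pos >= self.length:
            raise ValueError(
                f"position {pos} outside transcript {self.transcript_id} "
                f"of length {self.length}"
            )
        if not self.coding:
            return "noncoding"
        if pos < self.cds_start:
            return "utr5"
        if pos < self.cds_end:
            return "cds"
        return "utr3"


class Annotation:
    """A collection of transcript models with per-gene canonical choice.

    The canonical transcript of a gene is the one with the longest CDS,
    ties broken by lexicographically smallest transcript id.
    """

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts: dict[str, Transcript] = {
            t.transcript_id: t for t in transcripts
        }
        if len(self.transcripts) != len(transcripts):
            raise ValueError("duplicate transcript ids in annotation")
        self._canonical: dict[str, str] = {}
        by_gene: dict[str, list[Transcript]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gene, ts in by_gene.items():
            best = sorted(ts, key=lambda t: (-t.cds_length, t.transcript_id))[0]
            self._canonical[gene] = best.transcript_id
        self.genes = by_gene

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self.transcripts[transcript_id]

    def canonical(self, gene_id: str) -> Transcript:
        return self.transcripts[self._canonical[gene_id]]

    def gene_biotype(self, gene_id: str) -> str:
        if gene_id not in self.genes:
            raise KeyError(f"gene {gene_id} absent from annotation")
        return self.genes[gene_id][0].biotype

    @classmethod
    def from_gtf(cls, path: str) -> "Annotation":
        """Load transcript models from a GTF file.

        Exon records define the transcript chain; CDS records, where
        present, are projected into transcript coordinates.
        """
        import pyranges as pr

        df = pr.read_gtf(path).df
        if "gene_biotype" not in df.columns:
            df["gene_biotype"] = "protein_coding"
        transcripts = []
        for tid, sub in df.groupby("transcript_id", sort=True):
            exons = sub[sub.Feature == "exon"].sort_values("Start")
            if exons.empty:
                continue
            strand = exons.Strand.iloc[0]
            order = exons if strand == "+" else exons.iloc[::-1]
            # genomic (start, end) half-open blocks in transcription order
            blocks = [(s, e) for s, e in zip(order.Start, order.End)]
            length = sum(e - s for s, e in blocks)
            cds = sub[sub.Feature == "CDS"]
            cds_start = cds_end = None
            if not cds.empty:
                gstart, gend = int(cds.Start.min()), int(cds.End.max())
                cds_start = _to_transcript(blocks, strand, gstart, gend)[0]
                cds_end = _to_transcript(blocks, strand, gstart, gend)[1]
            transcripts.append(
                Transcript(
                    transcript_id=str(tid),
                    gene_id=str(sub.gene_id.iloc[0]),
                    length=int(length),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    biotype=str(sub.gene_biotype.iloc[0]),
                )
            )
        return cls(transcripts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "length": t.length,
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
                "biotype": t.biotype,
            }
            for t in self.transcripts.values()
        ]
        return pd.DataFrame(rows)


def _to_transcript(blocks, strand, gstart, gend):
    """Project a genomic half-open interval onto transcript coordinates."""
    offset = 0
    tstart = tend = None
    for s, e in blocks:
        if strand == "+":
            if s <= gstart < e:
                tstart = offset + (gstart - s)
            if s < gend <= e:
                tend = offset + (gend - s)
        else:
            if s < gend <= e:
                tstart = offset + (e - gend)
            if s <= gstart < e:
                tend = offset + (e - gstart)
        offset += e - s
    if tstart is None or tend is None:
        raise ValueError("interval not covered by exon chain")
    return tstart, tend


def write_gtf(annotation: Annotation, path: str, chrom_of=None) -> None:
    """Write single-exon GTF records for an in-memory annotation.

    Each transcript is placed on its own contig starting at genomic
    position 1 (GTF is 1-based, closed), which makes the genomic and
    transcript coordinate systems coincide up to the off-by-one shift.
    """
    lines = []
    for t in annotation.transcripts.values():
        chrom = chrom_of(t) if chrom_of else t.transcript_id
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{t.biotype}";'
        )
        for feature, s, e in _gtf_features(t):
            lines.append(
                f"{chrom}\ttranslatome\t{feature}\t{s}\t{e}\t.\t+\t.\t{attrs}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gtf_features(t: Transcript):
    yield "transcript", 1, t.length
    yield "exon", 1, t.length
    if t.coding:
        yield "CDS", t.cds_start + 1, t.cds_end
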