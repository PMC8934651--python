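"""Transcript models and coordinate arithmetic.

A transcript is modeled as a single contiguous genomic interval composed of a
5'UTR, a CDS and a 3'UTR on one strand.  Annotations frequently lack UTR
coordinates for verified ORFs; following standard practice for budding-yeast
CRAC analysis, missing UTRs are filled in with fixed default lengths
(25 nt upstream, 125 nt downstream of the CDS) and flagged as such.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open.  GFF3 input is 1-based inclusive
and converted on read; BED/bedGraph output is 0-based half-open.  Transcript
position 0 is the 5'-most base of the 5'UTR on the coding strand, so on the
minus strand transcript coordinates run antiparallel to the genome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_UTR5 = 25
DEFAULT_UTR3 = 125

#: value returned by coordinate maps for positions outside the transcript
OUT_OF_RANGE = -1


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent transcript annotations."""


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's transcript: genomic CDS interval plus UTR extents.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chrom : str
        Chromosome / contig name.
    strand : str
        ``"+"`` or ``"-"``.
    cds_start, cds_end : int
        CDS genomic interval, 0-based half-open.
    utr5_len, utr3_len : int
        UTR lengths in nt (transcript-space; strand-aware in the genome).
    utr5_default, utr3_default : bool
        True when the UTR length was filled in with the default rule (or
        truncated at a contig boundary) rather than annotated.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    utr5_len: int = 0
    utr3_len: int = 0
    utr5_default: bool = False
    utr3_default: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_end <= self.cds_start:
            raise AnnotationError(f"{self.gene_id}: empty or inverted CDS interval")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise AnnotationError(f"{self.gene_id}: negative UTR length")

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def length(self) -> int:
        """Transcript length = 5'UTR + CDS + 3'UTR."""
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def genomic_start(self) -> int:
        """Leftmost genomic coordinate of the transcript (0-based)."""
        up = self.utr5_len if self.strand == "+" else self.utr3_len
        return self.cds_start - up

    @property
    def genomic_end(self) -> int:
        """Rightmost genomic coordinate of the transcript, exclusive."""
        down = self.utr3_len if self.strand == "+" else self.utr5_len
        return self.cds_end + down


def transcript_to_genomic(t: TranscriptModel, tpos: int) -> int:
    """Map a transcript-space position to a genomic position.

    Returns :data:`OUT_OF_RANGE` when ``tpos`` falls outside ``[0, t.length)``.
    """
    if tpos < 0 or tpos >= t.length:
        return OUT_OF_RANGE
    if t.strand == "+":
        return t.genomic_start + tpos
    return t.genomic_end - 1 - tpos


def genomic_to_transcript(t: TranscriptModel, gpos: int) -> int:
    """Map a genomic position to transcript space (inverse of
    :func:`transcript_to_genomic` on its image)."""
    if gpos < t.genomic_start or gpos >= t.genomic_end:
        return OUT_OF_RANGE
    if t.strand == "+":
        return gpos - t.genomic_start
    return t.genomic_end - 1 - gpos


@dataclass
class TranscriptSet:
    """A collection of transcripts keyed by gene_id, with optional sequences.

    ``sequences`` maps gene_id to the transcript-space nucleotide sequence
    (5'->3' on the coding strand); ``alphabet`` records whether the stored
    sequences use U (RNA) or T (DNA).
    """

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    alphabet: str = "DNA"

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, gene_id: str) -> TranscriptModel:
        return self.transcripts[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.transcripts

    def add(self, t: TranscriptModel, sequence: str | None = None) -> None:
        if t.gene_id in self.transcripts:
            raise AnnotationError(f"duplicate gene_id: {t.gene_id}")
        if sequence is not None:
            if len(sequence) != t.length:
                raise AnnotationError(
                    f"{t.gene_id}: sequence length {len(sequence)} != "
                    f"transcript length {t.length}"
                )
            self.sequences[t.gene_id] = sequence
        self.transcripts[t.gene_id] = t

    def attach_genome(self, genome: Mapping[str, str]) -> None:
        """Extract transcript sequences from chromosome sequences.

        Minus-strand transcripts are reverse-complemented so that stored
        sequences are always 5'->3' in transcript orientation.
        """
        for t in self:
            chrom_seq = genome[t.chrom]
            sub = chrom_seq[t.genomic_start : t.genomic_end]
            if t.strand == "-":
                sub = str(Seq(sub).reverse_complement())
            if len(sub) != t.length:
                raise AnnotationError(
                    f"{t.gene_id}: transcript extends past end of {t.chrom}"
                )
            self.sequences[t.gene_id] = sub.upper()


@dataclass(frozen=True)
class AnnotationRecord:
    """A flat gene annotation: CDS interval plus optional annotated UTR lengths."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    utr5_len: int | None = None
    utr3_len: int | None = None


def build_transcript_set(
    records: Iterable[AnnotationRecord],
    default_utr5: int = DEFAULT_UTR5,
    default_utr3: int = DEFAULT_UTR3,
) -> TranscriptSet:
    """Build a :class:`TranscriptSet`, filling missing UTRs with defaults.

    Every output transcript carries both UTRs: a UTR absent from the input is
    extended by ``default_utr5`` / ``default_utr3`` nt in genomic space and
    flagged.  Extensions that would run past the start of the contig
    (position 0) are truncated silently but keep the default flag.

    Raises
    ------
    AnnotationError
        On a duplicate gene_id or a CDS whose length is not positive.
    """
    tset = TranscriptSet()
    for rec in records:
        utr5 = rec.utr5_len if rec.utr5_len is not None else default_utr5
        utr3 = rec.utr3_len if rec.utr3_len is not None else default_utr3
        utr5_default = rec.utr5_len is None
        utr3_default = rec.utr3_len is None
        # truncate at contig start; contig ends are not known here
        upstream = utr5 if rec.strand == "+" else utr3
        if rec.cds_start - upstream < 0:
            clipped = rec.cds_start
            if rec.strand == "+":
                utr5, utr5_default = clipped, True
            else:
                utr3, utr3_default = clipped, True
        tset.add(
            TranscriptModel(
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                strand=rec.strand,
                cds_start=rec.cds_start,
                cds_end=rec.cds_end,
                utr5_len=utr5,
                utr3_len=utr3,
                utr5_default=utr5_default,
                utr3_default=utr3_default,
            )
        )
    return tset


# ---------------------------------------------------------------------------
# I/O: GFF3 in, TSV transcript table in/out, FASTA sequences
# ---------------------------------------------------------------------------

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff3(path_or_buf) -> list[AnnotationRecord]:
    """Read flat gene/CDS/UTR features from a GFF3 file.

    Recognized feature types: ``CDS`` (required, one per gene),
    ``five_prime_UTR`` and ``three_prime_UTR`` (optional).  Features are
    grouped by the ``ID`` (or ``Parent``) attribute.  GFF3 coordinates are
    1-based inclusive and converted to 0-based half-open.
    """
    df = pd.read_csv(
        path_or_buf, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str, "start": int, "end": int},
    )
    genes: dict[str, dict] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        gid = _gff_attr(row.attributes, "ID") or _gff_attr(row.attributes, "Parent")
        if gid is None:
            raise AnnotationError(f"GFF record without ID/Parent attribute: {row}")
        gid = gid.split(".")[0] if row.type != "gene" else gid
        entry = genes.setdefault(gid, {"chrom": row.seqid, "strand": row.strand})
        if gid not in order:
            order.append(gid)
        if row.type == "CDS":
            entry["cds"] = (row.start - 1, row.end)
        elif row.type == "five_prime_UTR":
            entry["utr5"] = row.end - (row.start - 1)
        elif row.type == "three_prime_UTR":
            entry["utr3"] = row.end - (row.start - 1)
    records = []
    for gid in order:
        entry = genes[gid]
        if "cds" not in entry:
            raise AnnotationError(f"{gid}: no CDS feature in GFF input")
        records.append(
            AnnotationRecord(
                gene_id=gid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                cds_start=entry["cds"][0],
                cds_end=entry["cds"][1],
                utr5_len=entry.get("utr5"),
                utr3_len=entry.get("utr3"),
            )
        )
    return records


def write_transcript_table(tset: TranscriptSet, path_or_buf) -> None:
    """Write the transcript table as TSV (0-based half-open intervals)."""
    rows = [
        {
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "tx_start": t.genomic_start,
            "tx_end": t.genomic_end,
            "cds_start": t.cds_start,
            "cds_end": t.cds_end,
            "utr5_len": t.utr5_len,
            "utr3_len": t.utr3_len,
            "utr5_default": int(t.utr5_default),
            "utr3_default": int(t.utr3_default),
        }
        for t in tset
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)


def read_transcript_table(path_or_buf) -> TranscriptSet:
    """Read a transcript table written by :func:`write_transcript_table`."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"gene_id": str, "chrom": str})
    tset = TranscriptSet()
    for row in df.itertuples(index=False):
        tset.add(
            TranscriptModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                utr5_len=int(row.utr5_len),
                utr3_len=int(row.utr3_len),
                utr5_default=bool(row.utr5_default),
                utr3_default=bool(row.utr3_default),
            )
        )
    return tset


def read_fasta(path_or_buf) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    if isinstance(path_or_buf, (str,)):
        handle = open(path_or_buf)
    else:
        handle = path_or_buf
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not path_or_buf:
            handle.close()


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
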