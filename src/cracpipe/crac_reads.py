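"""CRAC read ingestion, PCR-duplicate collapse and cross-link pileups.

UV cross-linking leaves an amino-acid adduct ("scar") on the RNA at the
protein-contact nucleotide.  Reverse transcriptase skips bases at the scar,
so aligned CRAC reads carry deletions (and elevated substitutions) that
pinpoint cross-link sites.  This module turns aligned reads into
transcript-space :class:`CracRead` records, collapses PCR duplicates using
the insert sequence together with the random barcode nucleotides (UMI), and
accumulates per-position pileup tracks that keep coverage, deletion weight
and substitution counts separate.

Deletions inside repeats are ambiguous: deleting CU from CUCU yields the
same read for several placements.  Aligners left-align; to avoid a
systematic upstream bias in scar metaprofiles each deletion records its
leftmost equivalent placement plus the number of equivalent placements, and
pileups spread a total weight of 1 uniformly across them.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .transcriptome import TranscriptModel, TranscriptSet, genomic_to_transcript

logger = logging.getLogger(__name__)

DEFAULT_UMI_DELIM = "_"


@dataclass(frozen=True)
class DeletionRecord:
    """A deletion scar: leftmost equivalent placement, width, and the number
    of equivalent placements (ambiguity >= 1)."""

    left: int
    width: int
    ambiguity: int = 1

    def __post_init__(self) -> None:
        if self.width < 1 or self.ambiguity < 1:
            raise ValueError("deletion width and ambiguity must be >= 1")


@dataclass(frozen=True)
class Substitution:
    pos: int
    ref_base: str
    read_base: str


@dataclass(frozen=True)
class CracRead:
    """One aligned read in transcript space (0-based half-open interval)."""

    gene_id: str
    start: int
    end: int
    umi: str
    insert_seq: str
    deletions: tuple[DeletionRecord, ...] = ()
    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read interval is empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PileupTrack:
    """Per-position coverage, deletion weight and substitution counts for
    one transcript.  Each deletion record contributes total weight 1, spread
    uniformly over its equivalent placements."""

    gene_id: str
    length: int
    coverage: np.ndarray = field(default=None)  # type: ignore[assignment]
    deletion_weight: np.ndarray = field(default=None)  # type: ignore[assignment]
    substitution_count: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = np.zeros(self.length, dtype=np.int64)
        if self.deletion_weight is None:
            self.deletion_weight = np.zeros(self.length, dtype=np.float64)
        if self.substitution_count is None:
            self.substitution_count = np.zeros(self.length, dtype=np.int64)


# ---------------------------------------------------------------------------
# deletion ambiguity
# ---------------------------------------------------------------------------

def deletion_ambiguity(ref: str, pos: int, width: int) -> tuple[int, int]:
    """Left-align a deletion and count its equivalent placements.

    A deletion of ``width`` bases at reference position ``pos`` is equivalent
    to one at ``pos - 1`` iff ``ref[pos - 1] == ref[pos - 1 + width]`` (the
    flanking base can slide across the deleted block without changing the
    resulting sequence), and symmetrically to the right.

    Returns ``(leftmost_pos, n_placements)``.
    """
    left = pos
    while left > 0 and ref[left - 1] == ref[left - 1 + width]:
        left -= 1
    right = pos
    while right + width < len(ref) and ref[right] == ref[right + width]:
        right += 1
    return left, right - left + 1


# ---------------------------------------------------------------------------
# SAM parsing
# ---------------------------------------------------------------------------

def parse_umi(query_name: str, delim: str = DEFAULT_UMI_DELIM) -> str:
    """UMI = the read-name field after the last delimiter (pyCRAC-style
    random barcode nucleotides embedded in the read name)."""
    if delim in query_name:
        return query_name.rsplit(delim, 1)[1]
    return ""


class _TranscriptIndex:
    """Per-(chrom, strand) sorted interval lookup for transcript assignment."""

    def __init__(self, tset: TranscriptSet):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[TranscriptModel]]] = {}
        for t in tset:
            starts, models = self._by_key.setdefault((t.chrom, t.strand), ([], []))
            starts.append(t.genomic_start)
            models.append(t)
        for key, (starts, models) in self._by_key.items():
            order = sorted(range(len(starts)), key=lambda i: starts[i])
            self._by_key[key] = (
                [starts[i] for i in order],
                [models[i] for i in order],
            )

    def assign(self, chrom: str, strand: str, gstart: int, gend: int
               ) -> TranscriptModel | None:
        """Transcript with the longest overlap; ties by lexicographic gene_id."""
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return None
        starts, models = entry
        best: tuple[int, str] | None = None
        best_t = None
        i = bisect_right(starts, gend - 1)
        # scan left from the insertion point; stop once intervals cannot reach
        for j in range(i - 1, -1, -1):
            t = models[j]
            ov = min(gend, t.genomic_end) - max(gstart, t.genomic_start)
            if ov > 0:
                key = (-ov, t.gene_id)
                if best is None or key < best:
                    best, best_t = key, t
            elif t.genomic_end <= gstart and gstart - t.genomic_start > 10_000_000:
                break
        return best_t


def parse_sam(
    path,
    tset: TranscriptSet,
    umi_delim: str = DEFAULT_UMI_DELIM,
) -> list[CracRead]:
    """Convert aligned SAM records to transcript-space :class:`CracRead`\\ s.

    Reads are assigned to the same-strand transcript with the longest
    overlap.  The aligned strand must match the transcript strand (CRAC
    inserts are sense-strand).  Substitutions are taken from mismatches
    between the aligned read and the transcript sequence; deletions come
    from the CIGAR and are left-aligned with their ambiguity computed by
    sliding within the transcript sequence.  Unmapped records, records
    without a CIGAR, and reads overlapping no transcript are skipped (counts
    logged).
    """
    index = _TranscriptIndex(tset)
    reads: list[CracRead] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                n_skipped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            gstart, gend = aln.reference_start, aln.reference_end
            t = index.assign(aln.reference_name, strand, gstart, gend)
            if t is None:
                n_skipped += 1
                continue
            read = _to_transcript_read(aln, t, tset, umi_delim)
            if read is not None:
                reads.append(read)
            else:
                n_skipped += 1
    if n_skipped:
        logger.info("parse_sam: skipped %d records", n_skipped)
    return reads


def _to_transcript_read(
    aln: pysam.AlignedSegment,
    t: TranscriptModel,
    tset: TranscriptSet,
    umi_delim: str,
) -> CracRead | None:
    gstart, gend = aln.reference_start, aln.reference_end
    ts0 = genomic_to_transcript(t, gstart)
    ts1 = genomic_to_transcript(t, gend - 1)
    if ts0 < 0 or ts1 < 0:
        return None  # alignment pokes past the transcript extent
    start, end = (ts0, ts1 + 1) if t.strand == "+" else (ts1, ts0 + 1)

    # walk the CIGAR in genomic order, collecting (genomic_pos, op, len)
    seq = aln.query_sequence or ""
    qpos = 0
    gpos = gstart
    blocks: list[tuple[int, int, str]] = []  # (gpos, qpos, M-block bases)
    gdels: list[tuple[int, int]] = []  # (gpos, width)
    for op, ln in aln.cigartuples:
        if op == 0 or op == 7 or op == 8:  # M/=/X
            blocks.append((gpos, qpos, seq[qpos : qpos + ln]))
            gpos += ln
            qpos += ln
        elif op == 2:  # D
            gdels.append((gpos, ln))
            gpos += ln
        elif op == 1:  # I: insertion relative to reference, not profiled
            qpos += ln
        elif op == 4:  # S
            qpos += ln
        elif op == 3:  # N — spliced alignments are not expected
            gpos += ln

    ref = tset.sequences.get(t.gene_id)
    minus = t.strand == "-"

    # insert sequence in transcript orientation (soft clips removed)
    aligned = "".join(b for _, _, b in blocks)
    insert = str(Seq(aligned).reverse_complement()) if minus else aligned

    subs: list[Substitution] = []
    dels: list[DeletionRecord] = []
    if ref is not None:
        for gp, _, bases in blocks:
            for k, base in enumerate(bases):
                tp = genomic_to_transcript(t, gp + k)
                rb = ref[tp]
                qb = str(Seq(base).reverse_complement()) if minus else base
                if qb.upper() != rb.upper():
                    subs.append(Substitution(tp, rb, qb.upper()))
        for gp, width in gdels:
            if minus:
                tp = genomic_to_transcript(t, gp + width - 1)
            else:
                tp = genomic_to_transcript(t, gp)
            left, amb = deletion_ambiguity(ref, tp, width)
            dels.append(DeletionRecord(left=left, width=width, ambiguity=amb))
    else:
        for gp, width in gdels:
            tp = genomic_to_transcript(t, gp + width - 1 if minus else gp)
            dels.append(DeletionRecord(left=tp, width=width, ambiguity=1))

    subs.sort(key=lambda s: s.pos)
    dels.sort(key=lambda d: d.left)
    return CracRead(
        gene_id=t.gene_id,
        start=start,
        end=end,
        umi=parse_umi(aln.query_name, umi_delim),
        insert_seq=insert.upper(),
        deletions=tuple(dels),
        substitutions=tuple(subs),
    )


# ---------------------------------------------------------------------------
# duplicate collapse
# ---------------------------------------------------------------------------

def collapse_duplicates(reads: Iterable[CracRead]) -> list[CracRead]:
    """Collapse PCR duplicates: one representative per (insert_seq, UMI) pair.

    Two reads are duplicates only when both the insert sequence and the
    random barcode nucleotides are identical; the first read in input order
    represents each class, making the operation deterministic and idempotent.
    """
    seen: set[tuple[str, str]] = set()
    out: list[CracRead] = []
    for r in reads:
        key = (r.insert_seq, r.umi)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def build_pileup(reads: Iterable[CracRead], t: TranscriptModel) -> PileupTrack:
    """Accumulate coverage, deletion weight and substitutions along ``t``.

    Coverage += 1 over each read's [start, end); each deletion record adds
    1/ambiguity to every equivalent placement position; each substitution
    adds 1 at its position.  Reads sticking out of the transcript are
    clipped (logged).
    """
    track = PileupTrack(gene_id=t.gene_id, length=t.length)
    n_clipped = 0
    for r in reads:
        if r.gene_id != t.gene_id:
            raise ValueError(f"read for {r.gene_id} passed to pileup of {t.gene_id}")
        s, e = r.start, r.end
        if s < 0 or e > t.length:
            n_clipped += 1
            s, e = max(s, 0), min(e, t.length)
            if s >= e:
                continue
        track.coverage[s:e] += 1
        for d in r.deletions:
            lo = max(d.left, 0)
            hi = min(d.left + d.ambiguity, t.length)
            if hi > lo:
                track.deletion_weight[lo:hi] += 1.0 / d.ambiguity
        for sub in r.substitutions:
            if 0 <= sub.pos < t.length:
                track.substitution_count[sub.pos] += 1
    if n_clipped:
        logger.info("build_pileup(%s): clipped %d reads", t.gene_id, n_clipped)
    return track


def build_pileups(reads: Iterable[CracRead], tset: TranscriptSet
                  ) -> dict[str, PileupTrack]:
    """Group reads by gene and build one pileup per transcript with reads."""
    by_gene: dict[str, list[CracRead]] = {}
    for r in reads:
        by_gene.setdefault(r.gene_id, []).append(r)
    return {
        gid: build_pileup(rs, tset[gid]) for gid, rs in sorted(by_gene.items())
    }


def write_pileup_tsv(track: PileupTrack, path_or_buf) -> None:
    """Per-position TSV: position, coverage, deletion_weight, substitution_count."""
    pd.DataFrame(
        {
            "position": np.arange(track.length),
            "coverage": track.coverage,
            "deletion_weight": track.deletion_weight,
            "substitution_count": track.substitution_count,
        }
    ).to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph export
# ---------------------------------------------------------------------------

def export_bedgraph(
    track: PileupTrack,
    t: TranscriptModel,
    which: str = "coverage",
) -> list[tuple[str, int, int, float]]:
    """Back-map a pileup track to genomic bedGraph records.

    Adjacent positions with equal nonzero values are merged into one
    interval; zero stretches are omitted.  Output intervals are 0-based
    half-open on the genome, sorted by start.
    """
    values = {
        "coverage": track.coverage,
        "deletions": track.deletion_weight,
        "substitutions": track.substitution_count,
    }[which]
    # genomic position of each transcript base, then order genomically
    if t.strand == "+":
        gvals = np.asarray(values, dtype=float)
        g0 = t.genomic_start
    else:
        gvals = np.asarray(values, dtype=float)[::-1]
        g0 = t.genomic_start
    records: list[tuple[str, int, int, float]] = []
    run_start = 0
    for i in range(1, len(gvals) + 1):
        if i == len(gvals) or gvals[i] != gvals[run_start]:
            v = gvals[run_start]
            if v != 0:
                records.append((t.chrom, g0 + run_start, g0 + i, float(v)))
            run_start = i
    return records


def write_bedgraph(records: Sequence[tuple[str, int, int, float]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
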