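import random

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from cracpipe import (
    CracRead,
    DeletionRecord,
    PileupTrack,
    build_pileup,
    build_pileups,
    collapse_duplicates,
    deletion_ambiguity,
    export_bedgraph,
    parse_sam,
)
from cracpipe.transcriptome import TranscriptModel


def _read(gene="g", start=0, end=30, umi="ACGTAC", insert=None, dels=(),
          subs=()):
    if insert is None:
        insert = "A" * (end - start - sum(d.width for d in dels))
    return CracRead(gene, start, end, umi, insert, tuple(dels), tuple(subs))


# ---------------------------------------------------------------------------
# deletion ambiguity
# ---------------------------------------------------------------------------

def test_ambiguity_unique_context():
    assert deletion_ambiguity("AAGGTTCC", 2, 2) == (2, 1)


def test_ambiguity_cucu_repeat():
    # deleting CU from the CUCU run: three equivalent start placements
    # covering the 4-nt repeat region (U/T-equivalent DNA form)
    ref = "ACTCTG"
    left, amb = deletion_ambiguity(ref, 1, 2)
    assert (left, amb) == (1, 3)


def test_ambiguity_homopolymer():
    # UUUU -> UU: any of the three placements deletes two Ts
    assert deletion_ambiguity("ATTTTG", 1, 2) == (1, 3)


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGT", min_size=6, max_size=20),
       st.data())
def test_ambiguity_matches_string_deletion_oracle(ref, data):
    width = data.draw(st.integers(1, 2))
    pos = data.draw(st.integers(0, len(ref) - width))
    left, amb = deletion_ambiguity(ref, pos, width)
    target = ref[:pos] + ref[pos + width:]
    # oracle: every placement that yields the same string
    equiv = [p for p in range(len(ref) - width + 1)
             if ref[:p] + ref[p + width:] == target]
    # equivalent placements around pos form a contiguous run
    run = [pos]
    for p in range(pos - 1, -1, -1):
        if p in equiv and p == run[-1] - 1:
            run.append(p)
        else:
            break
    run2 = [pos]
    for p in range(pos + 1, len(ref) - width + 1):
        if p in equiv and p == run2[-1] + 1:
            run2.append(p)
        else:
            break
    expected = sorted(set(run) | set(run2))
    assert left == expected[0]
    assert amb == len(expected)


# ---------------------------------------------------------------------------
# duplicate collapse
# ---------------------------------------------------------------------------

def test_identical_insert_and_umi_collapse_to_one():
    reads = [_read() for _ in range(5)]
    assert len(collapse_duplicates(reads)) == 1


def test_distinct_umis_are_kept():
    reads = [_read(umi="AAAAAA"), _read(umi="CCCCCC")]
    assert len(collapse_duplicates(reads)) == 2


def test_distinct_inserts_are_kept():
    reads = [_read(insert="A" * 30), _read(insert="C" * 30)]
    assert len(collapse_duplicates(reads)) == 2


def test_collapse_matches_distinct_pair_oracle():
    rng = random.Random(99)
    inserts = ["".join(rng.choice("ACGT") for _ in range(10)) for _ in range(8)]
    umis = ["AAAAAA", "CCCCCC", "GGGGGG"]
    reads = [
        _read(start=0, end=10, insert=rng.choice(inserts),
              umi=rng.choice(umis))
        for _ in range(300)
    ]
    expected = len({(r.insert_seq, r.umi) for r in reads})
    out = collapse_duplicates(reads)
    assert len(out) == expected
    # idempotent, and first-in-order representative
    assert collapse_duplicates(out) == out
    # order-insensitive in size
    shuffled = reads[::-1]
    assert len(collapse_duplicates(shuffled)) == expected


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def _toy_transcript(length=100):
    return TranscriptModel("g", "chrI", "+", cds_start=1000,
                           cds_end=1000 + length, utr5_len=0, utr3_len=0)


def test_pileup_single_read_coverage():
    t = _toy_transcript()
    track = build_pileup([_read(start=10, end=40)], t)
    assert track.coverage.sum() == 30
    assert (track.coverage[10:40] == 1).all()


def test_pileup_spreads_ambiguous_deletion_weight():
    t = _toy_transcript()
    d = DeletionRecord(left=20, width=2, ambiguity=4)
    track = build_pileup([_read(start=10, end=40, dels=[d])], t)
    assert np.allclose(track.deletion_weight[20:24], 0.25)
    assert track.deletion_weight.sum() == pytest.approx(1.0)


def test_pileup_mass_conservation_simulated():
    rng = np.random.default_rng(5)
    t = _toy_transcript(500)
    reads = []
    n_dels = 0
    for _ in range(100):
        s = int(rng.integers(0, 460))
        e = s + int(rng.integers(20, 41))
        e = min(e, 500)
        dels = []
        if rng.random() < 0.4:
            amb = int(rng.integers(1, 5))
            dels = [DeletionRecord(left=s + 5, width=1, ambiguity=amb)]
            n_dels += 1
        reads.append(_read(start=s, end=e, dels=dels))
    track = build_pileup(reads, t)
    assert track.coverage.sum() == sum(r.end - r.start for r in reads)
    assert track.deletion_weight.sum() == pytest.approx(n_dels)


# ---------------------------------------------------------------------------
# bedGraph export
# ---------------------------------------------------------------------------

def test_bedgraph_empty_for_flat_zero():
    t = _toy_transcript()
    track = PileupTrack(gene_id="g", length=100)
    assert export_bedgraph(track, t) == []


def test_bedgraph_single_position_interval():
    t = _toy_transcript()
    track = PileupTrack(gene_id="g", length=100)
    track.coverage[7] = 3
    recs = export_bedgraph(track, t)
    assert recs == [("chrI", 1007, 1008, 3.0)]


@pytest.mark.parametrize("strand", ["+", "-"])
def test_bedgraph_per_base_expansion_oracle(strand):
    rng = np.random.default_rng(17)
    t = TranscriptModel("g", "chrI", strand, 1000, 1100, 0, 0)
    track = PileupTrack(gene_id="g", length=100)
    track.coverage[:] = rng.integers(0, 4, size=100)
    recs = export_bedgraph(track, t)
    # expand bedGraph back to per-base genomic values
    expanded = np.zeros(100)
    for chrom, s, e, v in recs:
        assert chrom == "chrI"
        expanded[s - 1000 : e - 1000] = v
    # oracle: directly map each transcript base to its genomic offset
    expected = np.zeros(100)
    from cracpipe.transcriptome import transcript_to_genomic
    for tpos in range(100):
        expected[transcript_to_genomic(t, tpos) - 1000] = track.coverage[tpos]
    assert np.array_equal(expanded, expected)
    # merged: no two adjacent records share a value
    for a, b in zip(recs, recs[1:]):
        assert a[2] < b[1] or a[3] != b[3]


# ---------------------------------------------------------------------------
# SAM parsing against the generator's ground truth
# ---------------------------------------------------------------------------

def test_parse_sam_reconstruction_oracle(small_bundle):
    """Reference + parsed deletion/substitution records must reproduce the
    SAM read sequence exactly (in transcript orientation)."""
    b = small_bundle
    reads = parse_sam(b.sam_path, b.tset)
    assert reads, "no reads parsed"
    with pysam.AlignmentFile(str(b.sam_path), "r") as sam:
        seq_by_name = {}
        for a in sam:
            s = a.query_sequence
            if a.is_reverse:
                comp = str.maketrans("ACGT", "TGCA")
                s = s.translate(comp)[::-1]
            seq_by_name.setdefault((s, a.query_name.rsplit("_", 1)[1]), 0)
    for r in reads[:1500]:
        ref = b.tset.sequences[r.gene_id]
        rebuilt = list(ref[r.start : r.end])
        for sub in r.substitutions:
            rebuilt[sub.pos - r.start] = sub.read_base
        # remove deletions right-to-left at their left-aligned placement
        for d in sorted(r.deletions, key=lambda d: -d.left):
            lo = d.left - r.start
            del rebuilt[lo : lo + d.width]
        assert "".join(rebuilt) == r.insert_seq
        assert (r.insert_seq, r.umi) in seq_by_name
        assert len(r.insert_seq) == (r.end - r.start) - sum(
            d.width for d in r.deletions)


def test_dedup_recovers_truth_family_count(small_bundle):
    b = small_bundle
    reads = parse_sam(b.sam_path, b.tset)
    deduped = collapse_duplicates(reads)
    truth_families = sum(g.n_unique_molecules for g in b.truth.genes.values())
    assert len(deduped) == truth_families


def test_pileups_cover_all_read_mass(small_bundle):
    b = small_bundle
    deduped = collapse_duplicates(parse_sam(b.sam_path, b.tset))
    pileups = build_pileups(deduped, b.tset)
    by_gene = {}
    for r in deduped:
        by_gene[r.gene_id] = by_gene.get(r.gene_id, 0) + r.length
    for gid, track in pileups.items():
        assert track.coverage.sum() == by_gene[gid]
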