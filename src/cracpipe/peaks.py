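"""Monte-Carlo FDR peak calling on pileup coverage.

The null model for a transcript is the observed set of (deduplicated) read
lengths placed uniformly at random within the transcript, repeated for a
configurable number of iterations.  For each coverage height ``h`` the
empirical FDR is the mean null fraction of positions with coverage >= h
divided by the observed fraction, capped at 1 and made monotone
non-increasing in ``h``.  Peaks are maximal runs of positions whose height
passes the FDR threshold; this mirrors the standard within-gene
randomization null used in CLIP/CRAC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crac_reads import PileupTrack
from .transcriptome import TranscriptModel, transcript_to_genomic

DEFAULT_FDR = 0.05
DEFAULT_ITERATIONS = 100


@dataclass(frozen=True)
class Peak:
    gene_id: str
    start: int
    end: int
    height: int
    fdr: float

    def __post_init__(self) -> None:
        if self.height < 1:
            raise ValueError("peak height must be >= 1")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("fdr must lie in [0, 1]")


def _null_tail_fractions(
    length: int,
    read_lengths: np.ndarray,
    max_height: int,
    iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean fraction of positions with null coverage >= h, for h=0..max_height."""
    tail = np.zeros(max_height + 1, dtype=float)
    diff = np.zeros(length + 1, dtype=np.int64)
    for _ in range(iterations):
        diff[:] = 0
        # uniform placement; reads longer than the transcript sit at 0, clipped
        span = np.maximum(length - read_lengths + 1, 1)
        starts = (rng.random(read_lengths.size) * span).astype(np.int64)
        ends = np.minimum(starts + read_lengths, length)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        cov = np.cumsum(diff[:-1])
        counts = np.bincount(np.minimum(cov, max_height), minlength=max_height + 1)
        tail += np.cumsum(counts[::-1])[::-1] / length
    return tail / iterations


def fdr_by_height(
    coverage: np.ndarray,
    read_lengths: Sequence[int],
    iterations: int = DEFAULT_ITERATIONS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Empirical FDR for each height 0..max(coverage).

    FDR(h) = mean null fraction of positions >= h over the observed
    fraction >= h, capped at 1; enforced monotone non-increasing in h.
    FDR(0) is 1 by definition.
    """
    if rng is None:
        rng = np.random.default_rng()
    length = coverage.size
    max_h = int(coverage.max())
    obs_counts = np.bincount(coverage, minlength=max_h + 1)
    obs_tail = np.cumsum(obs_counts[::-1])[::-1] / length  # fraction >= h
    null_tail = _null_tail_fractions(
        length, np.asarray(read_lengths, dtype=np.int64), max_h, iterations, rng
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_tail > 0, null_tail / obs_tail, 0.0)
    fdr = np.minimum(fdr, 1.0)
    fdr[0] = 1.0
    # monotone non-increasing with height
    return np.minimum.accumulate(fdr)


def call_peaks(
    track: PileupTrack,
    read_lengths: Sequence[int],
    fdr_max: float = DEFAULT_FDR,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator | None = None,
) -> list[Peak]:
    """Call enriched coverage peaks on one transcript.

    ``read_lengths`` must be the lengths of the deduplicated reads on this
    transcript (they parameterize the null).  Returns maximal runs of
    positions whose coverage height has FDR <= ``fdr_max``; each peak
    reports its max height and the FDR at that height.  Deterministic for a
    fixed seed.
    """
    coverage = np.asarray(track.coverage)
    if coverage.max(initial=0) == 0 or len(read_lengths) == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fdr = fdr_by_height(coverage, read_lengths, iterations=iterations, rng=rng)
    passing = fdr[coverage] <= fdr_max
    peaks: list[Peak] = []
    i = 0
    n = coverage.size
    while i < n:
        if passing[i]:
            j = i
            while j < n and passing[j]:
                j += 1
            h = int(coverage[i:j].max())
            peaks.append(Peak(track.gene_id, i, j, h, float(fdr[h])))
            i = j
        else:
            i += 1
    return peaks


def call_peaks_all(
    pileups: dict[str, PileupTrack],
    read_lengths_by_gene: dict[str, Sequence[int]],
    fdr_max: float = DEFAULT_FDR,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> list[Peak]:
    """Per-transcript peak calling over a pileup collection (one RNG stream,
    genes visited in sorted order for determinism)."""
    rng = np.random.default_rng(seed)
    out: list[Peak] = []
    for gid in sorted(pileups):
        lengths = read_lengths_by_gene.get(gid, [])
        out.extend(
            call_peaks(pileups[gid], lengths, fdr_max=fdr_max,
                       iterations=iterations, seed=rng)
        )
    return out


def top_peaks(peaks: Iterable[Peak], n: int = 100) -> list[Peak]:
    """The ``n`` highest peaks across transcripts, sorted descending by
    height; ties broken by lower FDR, then gene_id, then start."""
    ranked = sorted(peaks, key=lambda p: (-p.height, p.fdr, p.gene_id, p.start))
    return ranked[:n]


def peaks_to_bed(peaks: Iterable[Peak], tset) -> list[tuple]:
    """BED6 records (genomic coordinates; name=gene_id, score=height)."""
    rows = []
    for p in peaks:
        t: TranscriptModel = tset[p.gene_id]
        g1 = transcript_to_genomic(t, p.start)
        g2 = transcript_to_genomic(t, p.end - 1)
        lo, hi = min(g1, g2), max(g1, g2) + 1
        rows.append((t.chrom, lo, hi, p.gene_id, p.height, t.strand))
    return rows


def write_peaks_tsv(peaks: Iterable[Peak], path_or_buf) -> None:
    pd.DataFrame(
        [
            {"gene_id": p.gene_id, "start": p.start, "end": p.end,
             "height": p.height, "fdr": p.fdr}
            for p in peaks
        ]
    ).to_csv(path_or_buf, sep="\t", index=False)
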