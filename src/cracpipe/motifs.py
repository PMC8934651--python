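"""Degenerate-motif scanning and bipartite binding-site analysis.

The Ssd1-type binding element is bipartite: an upstream CCAACU half followed,
after a short spacer, by a pyrimidine-rich downstream half matching the
degenerate pattern CNYUCNYU (IUPAC: N = any base, Y = C/U).  This module
provides IUPAC scanning with U/T equivalence, the tandem-overlap counting
rule (a 12-nt CNYUCNYUCNYU run counts as two occurrences), bipartite-site
pairing under a spacer-length window, upstream-region surveys, deletion-scar
metaprofiles around motif hits, and a hypergeometric category-enrichment
test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crac_reads import PileupTrack

# IUPAC nucleotide codes, DNA alphabet (T; U is normalized to T on input)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

DOWNSTREAM_MOTIF = "CNYUCNYU"
UPSTREAM_MOTIF = "CCAACU"
DEFAULT_SPACER_MIN = 4
DEFAULT_SPACER_MAX = 10


class MotifError(ValueError):
    """Raised for invalid motif patterns."""


def _normalize(seq: str) -> str:
    """Uppercase and map RNA U to DNA T for matching."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC degenerate nucleotide pattern; matching is case-insensitive
    and U/T-equivalent."""

    pattern: str
    alphabet: str = "RNA"

    def __post_init__(self) -> None:
        norm = _normalize(self.pattern)
        for ch in norm:
            if ch not in IUPAC:
                raise MotifError(f"invalid IUPAC character {ch!r} in pattern")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def regex(self) -> re.Pattern:
        body = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]"
            for c in _normalize(self.pattern)
        )
        # lookahead so overlapping matches are all reported
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int
    pattern: str
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


@dataclass(frozen=True)
class BipartiteSite:
    """An upstream CCAACU hit paired with a downstream CNYUCNYU hit;
    ``spacer`` is the gap from the end of the upstream hit to the start of
    the downstream hit (half-open convention)."""

    seq_id: str
    upstream_hit: MotifHit
    downstream_hit: MotifHit

    @property
    def spacer(self) -> int:
        return self.downstream_hit.start - self.upstream_hit.end


def scan_motif(seq: str, motif: DegenerateMotif, seq_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) match positions, in ascending order."""
    norm = _normalize(seq)
    hits = []
    for m in motif.regex.finditer(norm):
        start = m.start()
        hits.append(
            MotifHit(seq_id=seq_id, start=start,
                     pattern=motif.pattern,
                     matched=seq[start : start + len(motif.pattern)])
        )
    return hits


def count_occurrences(
    seq: str, motif: DegenerateMotif, period: int | None = None
) -> int:
    """Count motif occurrences with the tandem-overlap rule.

    Overlapping matches inside a repeat are collapsed greedily: after
    accepting a match at position i, the next acceptable match must start at
    >= i + ``period`` (default: half the pattern length).  A tandem repeat
    spanning (k+1) periods therefore counts k occurrences — the 12-nt
    CNYUCNYUCNYU run counts as two CNYUCNYU occurrences.
    """
    if period is None:
        if len(motif) % 2 != 0:
            raise MotifError("default period requires an even pattern length")
        period = len(motif) // 2
    count = 0
    next_ok = 0
    for hit in scan_motif(seq, motif):
        if hit.start >= next_ok:
            count += 1
            next_ok = hit.start + period
    return count


def find_bipartite_sites(
    seq: str,
    upstream: DegenerateMotif | None = None,
    downstream: DegenerateMotif | None = None,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    seq_id: str = "",
) -> list[BipartiteSite]:
    """Pair downstream motif hits with their nearest qualifying upstream hit.

    A pair qualifies when the gap between the end of the upstream hit and
    the start of the downstream hit lies in [spacer_min, spacer_max].  Each
    downstream hit is paired at most once, with the nearest (smallest-gap)
    qualifying upstream hit, so tandem repeats do not inflate site counts.
    """
    if spacer_min > spacer_max:
        raise MotifError("spacer_min must be <= spacer_max")
    upstream = upstream or DegenerateMotif(UPSTREAM_MOTIF)
    downstream = downstream or DegenerateMotif(DOWNSTREAM_MOTIF)
    up_hits = scan_motif(seq, upstream, seq_id=seq_id)
    if not up_hits:
        return []
    sites = []
    for dh in scan_motif(seq, downstream, seq_id=seq_id):
        best = None
        for uh in up_hits:
            gap = dh.start - uh.end
            if spacer_min <= gap <= spacer_max and (best is None or gap < best[0]):
                best = (gap, uh)
        if best is not None:
            sites.append(BipartiteSite(seq_id=seq_id, upstream_hit=best[1],
                                       downstream_hit=dh))
    return sites


def survey_upstream(
    seqs: Mapping[str, str],
    motif: DegenerateMotif | None = None,
    window: int = 100,
    min_count: int = 2,
) -> pd.DataFrame:
    """Count motif occurrences in the 3'-most ``window`` nt of each upstream
    sequence and select genes with >= ``min_count`` occurrences.

    The upstream sequences must end immediately 5' of the start codon, so
    the window is the region closest to the start codon.  Returns a frame
    with columns gene_id, count, selected, short_sequence (flag for inputs
    shorter than the window).
    """
    motif = motif or DegenerateMotif(DOWNSTREAM_MOTIF)
    rows = []
    for gid in sorted(seqs):
        seq = seqs[gid]
        short = len(seq) < window
        region = seq[-window:]
        count = count_occurrences(region, motif)
        rows.append(
            {"gene_id": gid, "count": count, "selected": count >= min_count,
             "short_sequence": short}
        )
    return pd.DataFrame(rows)


def deletion_metaprofile(
    pileups: Mapping[str, PileupTrack],
    hits: Iterable[MotifHit],
    flank: int = 20,
) -> pd.DataFrame:
    """Sum deletion weight around motif hits, by offset from the motif start.

    For each hit, deletion weight at transcript positions
    [start - flank, start + flank) is accumulated at offsets relative to the
    motif start (negative = upstream of the motif).  Returns a frame with
    columns offset (range [-flank, flank)) and deletion_weight; total mass
    equals the deletion weight lying inside the flanks.
    """
    offsets = np.arange(-flank, flank)
    mass = np.zeros(2 * flank, dtype=float)
    for hit in hits:
        track = pileups.get(hit.seq_id)
        if track is None:
            continue
        lo = hit.start - flank
        for k, off in enumerate(offsets):
            pos = lo + k
            if 0 <= pos < track.length:
                mass[k] += track.deletion_weight[pos]
    return pd.DataFrame({"offset": offsets, "deletion_weight": mass})


def modal_offset(profile: pd.DataFrame) -> int | None:
    """Offset with the largest summed deletion weight (None if all zero)."""
    if profile["deletion_weight"].sum() == 0:
        return None
    return int(profile.loc[profile["deletion_weight"].idxmax(), "offset"])


def category_enrichment(
    selected: set[str], category: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric over-representation test of a gene category within a
    selected gene set.

    Returns (overlap count, upper-tail p-value): the probability of drawing
    at least the observed overlap when |selected| genes are drawn without
    replacement from the universe containing |category| category members.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe or not category <= universe:
        raise ValueError("selected and category must be subsets of the universe")
    overlap = len(selected & category)
    # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|category|, N=|selected|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(category),
                                 len(selected)))
    return overlap, min(p, 1.0)
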