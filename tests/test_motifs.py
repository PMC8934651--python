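import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cracpipe import (
    DegenerateMotif,
    PileupTrack,
    category_enrichment,
    count_occurrences,
    deletion_metaprofile,
    find_bipartite_sites,
    modal_offset,
    scan_motif,
    survey_upstream,
)
from cracpipe.motifs import IUPAC, MotifError, _normalize

CNYUCNYU = DegenerateMotif("CNYUCNYU")


def brute_force_scan(seq: str, pattern: str) -> list[int]:
    """Independent oracle: check every window against the IUPAC codes."""
    seq = _normalize(seq)
    pattern = _normalize(pattern)
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in IUPAC[c] for j, c in enumerate(pattern)):
            hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_scan_no_match():
    assert scan_motif("ACGUACGU", CNYUCNYU) == []


def test_scan_overlapping_hits():
    hits = scan_motif("CCUUCAUUCCUU", CNYUCNYU)
    assert [h.start for h in hits] == [0, 4]


def test_scan_case_and_ut_equivalence():
    rna = scan_motif("CCUUCAUUCCUU", CNYUCNYU)
    dna = scan_motif("ccttcattccTT", CNYUCNYU)
    assert [h.start for h in rna] == [h.start for h in dna]


def test_invalid_iupac_character_rejected():
    with pytest.raises(MotifError, match="Z"):
        DegenerateMotif("CZU")


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="ACGT", min_size=0, max_size=50),
       st.sampled_from(["CNYUCNYU", "CCAACU", "RYN", "AKUCAUU"]))
def test_scan_equals_brute_force_window_check(seq, pattern):
    got = [h.start for h in scan_motif(seq, DegenerateMotif(pattern))]
    assert got == brute_force_scan(seq, pattern)


# ---------------------------------------------------------------------------
# tandem counting
# ---------------------------------------------------------------------------

def test_tandem_repeat_counts_as_two():
    # a 12-nt tandem CNYUCNYUCNYU instance counts as two occurrences
    assert count_occurrences("CUCUCUCUCUCU", CNYUCNYU) == 2


def test_single_pattern_length_counts_once():
    assert count_occurrences("CUCUCUCU", CNYUCNYU) == 1


def interval_scheduling_count(seq: str, pattern: str, period: int) -> int:
    """Oracle: earliest-start greedy over brute-force hits with the same
    minimum-separation rule."""
    count, next_ok = 0, 0
    for start in brute_force_scan(seq, pattern):
        if start >= next_ok:
            count += 1
            next_ok = start + period
    return count


def test_count_matches_interval_scheduling_oracle():
    rng = np.random.default_rng(44)
    for _ in range(30):
        # pyrimidine-rich backgrounds so hits actually occur
        seq = "".join(rng.choice(list("CTCTAG"), size=200))
        got = count_occurrences(seq, CNYUCNYU)
        assert got == interval_scheduling_count(seq, "CNYUCNYU", 4)
        # count never exceeds the raw hit number
        assert got <= len(scan_motif(seq, CNYUCNYU))


# ---------------------------------------------------------------------------
# bipartite sites
# ---------------------------------------------------------------------------

def test_bipartite_site_at_window_lower_bound():
    sites = find_bipartite_sites("CCAACU" + "A" * 4 + "CUCUCUCU")
    assert len(sites) == 1
    assert sites[0].spacer == 4


def test_bipartite_spacer_past_window_rejected():
    assert find_bipartite_sites("CCAACU" + "A" * 11 + "CUCUCUCU") == []


def test_bipartite_requires_upstream_motif():
    assert find_bipartite_sites("GGGG" + "CUCUCUCU" + "GGGG") == []


def test_bipartite_subset_of_hit_product():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    seq = seq[:50] + "CCAACT" + "AAAAA" + "CTCTCTCT" + seq[69:]
    sites = find_bipartite_sites(seq)
    ups = {h.start for h in scan_motif(seq, DegenerateMotif("CCAACU"))}
    downs = {h.start for h in scan_motif(seq, CNYUCNYU)}
    for s in sites:
        assert s.upstream_hit.start in ups
        assert s.downstream_hit.start in downs
        assert 4 <= s.spacer <= 10


# ---------------------------------------------------------------------------
# upstream survey
# ---------------------------------------------------------------------------

def test_survey_selects_genes_with_two_window_hits():
    pad = "G" * 120
    seqs = {
        "in_window": pad + "CTCTCTCT" + "G" * 20 + "CTTTCTTT" + "G" * 10,
        "outside": "CTCTCTCT" + "G" * 142 + "CTTTCTTT" + "G" * 10,
        "short": "CTCTCTCTAACTTTCTTT",
    }
    df = survey_upstream(seqs, window=100, min_count=2).set_index("gene_id")
    assert bool(df.loc["in_window", "selected"])
    assert not bool(df.loc["outside", "selected"])  # one hit beyond -100
    assert bool(df.loc["short", "short_sequence"])
    assert bool(df.loc["short", "selected"])


# ---------------------------------------------------------------------------
# scar metaprofile
# ---------------------------------------------------------------------------

def _track_with_scar(gene, length, pos, weight=1.0):
    t = PileupTrack(gene_id=gene, length=length)
    t.deletion_weight[pos] = weight
    return t


def test_metaprofile_concentrates_at_known_offset():
    from cracpipe.motifs import MotifHit
    tracks = {"g1": _track_with_scar("g1", 200, 97, 2.0)}
    hits = [MotifHit("g1", 100, "CNYUCNYU", "CUCUCUCU")]
    prof = deletion_metaprofile(tracks, hits, flank=20)
    assert modal_offset(prof) == -3
    assert prof["deletion_weight"].sum() == pytest.approx(2.0)


def test_metaprofile_all_zero_without_deletions():
    from cracpipe.motifs import MotifHit
    tracks = {"g1": PileupTrack(gene_id="g1", length=200)}
    hits = [MotifHit("g1", 100, "CNYUCNYU", "CUCUCUCU")]
    prof = deletion_metaprofile(tracks, hits, flank=20)
    assert (prof["deletion_weight"] == 0).all()
    assert modal_offset(prof) is None


def test_metaprofile_conserves_in_flank_mass():
    from cracpipe.motifs import MotifHit
    rng = np.random.default_rng(13)
    track = PileupTrack(gene_id="g1", length=300)
    track.deletion_weight[:] = rng.random(300) * (rng.random(300) < 0.1)
    hits = [MotifHit("g1", 150, "CNYUCNYU", "CUCUCUCU")]
    prof = deletion_metaprofile({"g1": track}, hits, flank=25)
    assert prof["deletion_weight"].sum() == pytest.approx(
        track.deletion_weight[125:175].sum())


# ---------------------------------------------------------------------------
# category enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_exact_combinatorial_value():
    # drawing all 5 category members in 5 draws from 20: p = 1 / C(20,5)
    universe = {f"g{i}" for i in range(20)}
    category = {f"g{i}" for i in range(5)}
    overlap, p = category_enrichment(category, category, universe)
    assert overlap == 5
    assert p == pytest.approx(1 / 15504, rel=1e-9)


def test_zero_overlap_gives_p_one():
    universe = {f"g{i}" for i in range(20)}
    overlap, p = category_enrichment({"g10", "g11"}, {"g0"}, universe)
    assert overlap == 0
    assert p == pytest.approx(1.0)


def test_empty_universe_rejected():
    with pytest.raises(ValueError):
        category_enrichment(set(), set(), set())


def test_hypergeometric_matches_simulation_oracle():
    """Empirical tail frequency of the overlap under random draws matches
    the reported p within Monte-Carlo error."""
    rng = np.random.default_rng(2024)
    universe = list(range(30))
    category = set(range(8))
    n_sel, obs_overlap = 10, 5
    p = float(stats.hypergeom.sf(obs_overlap - 1, 30, 8, 10))
    draws = 20000
    hits = 0
    for _ in range(draws):
        sel = set(rng.choice(30, size=n_sel, replace=False))
        if len(sel & category) >= obs_overlap:
            hits += 1
    emp = hits / draws
    se = np.sqrt(p * (1 - p) / draws)
    assert abs(emp - p) < 4 * se + 1e-4
    # and our wrapper returns the same p
    uni = {f"g{i}" for i in universe}
    cat = {f"g{i}" for i in category}
    sel = {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(10, 17)}
    ov, pw = category_enrichment(sel, cat, uni)
    assert pw == pytest.approx(float(stats.hypergeom.sf(ov - 1, 30, 8, 10)))
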