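"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a small budding-yeast-like transcriptome in which a
fraction of genes carry bipartite binding sites (a concrete CCAACU
instantiation, a 4–10-nt spacer, then a concrete CNYUCNYU instantiation) in
their 5'UTRs; cross-linking reads concentrate at those sites and carry
deletion scars 2–4 nt upstream of the downstream motif start; PCR
duplicates share a UMI; RNA-seq abundances span orders of magnitude
(log-normal) with negative-binomial counting noise; and anisotropy
titrations are drawn from the quadratic ligand-depletion model.

Every artifact carries a ground-truth manifest so recovery tests can
compare pipeline output against what was embedded.  All randomness flows
from a single seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .binding import BindingModel, TitrationPoint, model_anisotropy
from .transcriptome import (
    AnnotationRecord,
    TranscriptModel,
    TranscriptSet,
    build_transcript_set,
    write_fasta,
)
from . import motifs as _motifs

BASES = np.array(list("ACGT"))
PYRIMIDINES = np.array(list("CT"))

#: default titration design: no-protein baseline plus a 2-fold dilution
#: series from 1000 nM (13 points), spanning all Kd values of interest
DEFAULT_TITRATION_NM = (0.0,) + tuple(1000.0 / 2**k for k in range(12))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark (defaults are the
    generator's standing conditions, not tuning knobs)."""

    n_genes: int = 200
    target_fraction: float = 0.1
    sites_per_target: tuple[int, int] = (1, 5)
    utr5_len_range: tuple[int, int] = (50, 400)
    utr3_len: int = 125
    cds_codon_range: tuple[int, int] = (100, 500)
    spacer_range: tuple[int, int] = (4, 10)
    background_reads_mean: float = 20.0
    occupancy_multiplier: float = 10.0
    scar_prob: float = 0.3
    scar_offset_range: tuple[int, int] = (-4, -2)
    scar_width_range: tuple[int, int] = (1, 2)
    substitution_prob: float = 0.05
    pcr_duplication_mean: float = 3.0
    umi_len: int = 6
    read_len_range: tuple[int, int] = (20, 40)
    rnaseq_depth: int = 200_000
    rnaseq_lognormal_sigma: float = 1.5
    rnaseq_dispersion: float = 0.05
    intergenic_gap: int = 200
    chrom: str = "chr_sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.target_fraction, self.scar_prob, self.substitution_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.sites_per_target, self.utr5_len_range,
                       self.spacer_range, self.read_len_range,
                       self.scar_offset_range, self.scar_width_range):
            if lo > hi:
                raise ValueError("ranges must be non-empty")


@dataclass
class SiteTruth:
    """Coordinates of one embedded bipartite site (transcript space)."""

    upstream_start: int   # start of the CCAACU instantiation
    downstream_start: int  # start of the CNYUCNYU instantiation
    spacer: int


@dataclass
class GeneTruth:
    is_target: bool
    abundance: float
    sites: list[SiteTruth] = field(default_factory=list)
    n_unique_molecules: int = 0
    scar_offsets: list[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def target_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.is_target}

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config) if self.config else None,
            "genes": {g: asdict(t) for g, t in self.genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _instantiate_downstream(rng: np.random.Generator) -> str:
    """A concrete CNYTCNYT instantiation (DNA alphabet)."""
    out = []
    for code in "CNYTCNYT":
        if code == "C":
            out.append("C")
        elif code == "T":
            out.append("T")
        elif code == "Y":
            out.append(str(rng.choice(PYRIMIDINES)))
        else:
            out.append(str(rng.choice(BASES)))
    return "".join(out)


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _build_utr5(
    rng: np.random.Generator, utr5_len: int, n_sites: int, cfg: SimulationConfig
) -> tuple[str, list[SiteTruth]] | None:
    """One attempt at a 5'UTR with ``n_sites`` embedded bipartite sites.

    Returns None when the scanner's nearest-upstream pairing would not
    recover exactly the embedded sites (accidental motif collisions)."""
    spacers = rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1,
                           size=n_sites)
    footprints = [6 + int(sp) + 8 for sp in spacers]
    min_gap = 12  # keeps embedded sites from interfering with each other
    needed = sum(footprints) + min_gap * n_sites
    if needed > utr5_len:
        return None
    # distribute the slack randomly between and around the sites
    slack = utr5_len - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=n_sites))
    seq_parts: list[str] = []
    sites: list[SiteTruth] = []
    pos = 0
    prev_cut = 0
    for i in range(n_sites):
        pad = int(cuts[i] - prev_cut) + (min_gap if i > 0 else 0)
        prev_cut = int(cuts[i])
        seq_parts.append(_rand_seq(rng, pad))
        pos += pad
        up = "CCAACT"
        spacer_seq = _rand_seq(rng, int(spacers[i]))
        down = _instantiate_downstream(rng)
        seq_parts.append(up + spacer_seq + down)
        sites.append(SiteTruth(upstream_start=pos,
                               downstream_start=pos + 6 + int(spacers[i]),
                               spacer=int(spacers[i])))
        pos += footprints[i]
    tail = utr5_len - pos
    seq_parts.append(_rand_seq(rng, tail - min_gap) if tail >= min_gap
                     else _rand_seq(rng, tail))
    if tail >= min_gap:
        seq_parts.append(_rand_seq(rng, min_gap))
    utr5 = "".join(seq_parts)
    assert len(utr5) == utr5_len

    # verify the scanner recovers exactly the embedded downstream starts
    found = _motifs.find_bipartite_sites(
        utr5, spacer_min=cfg.spacer_range[0], spacer_max=cfg.spacer_range[1]
    )
    found_pairs = {(s.upstream_hit.start, s.downstream_hit.start) for s in found}
    want_pairs = {(s.upstream_start, s.downstream_start) for s in sites}
    if not want_pairs <= found_pairs:
        return None
    # reject accidental CCAACU collisions that re-pair an embedded downstream
    for s in found:
        for w in sites:
            if (s.downstream_hit.start == w.downstream_start
                    and s.upstream_hit.start != w.upstream_start):
                return None
    return utr5, sites


def simulate_transcriptome(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TranscriptSet, dict[str, str], GroundTruth]:
    """Generate the genome, annotation and ground truth.

    Background sequence is i.i.d. uniform over ACGU; target genes (a
    ``target_fraction`` of all genes, chosen at random) carry 1–5 embedded
    bipartite sites in their 5'UTRs.  Genes are laid head-to-tail on a
    single chromosome with random-sequence gaps, on random strands.
    Returns (TranscriptSet with sequences attached, genome dict, truth).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_targets = int(round(cfg.n_genes * cfg.target_fraction))
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    is_target[rng.choice(cfg.n_genes, size=n_targets, replace=False)] = True
    abundances = rng.lognormal(mean=0.0, sigma=cfg.rnaseq_lognormal_sigma,
                               size=cfg.n_genes)

    truth = GroundTruth(config=cfg)
    records: list[AnnotationRecord] = []
    genome_parts: list[str] = [_rand_seq(rng, cfg.intergenic_gap)]
    gpos = cfg.intergenic_gap
    tx_seqs: dict[str, str] = {}

    for i in range(cfg.n_genes):
        gid = f"gene{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        cds_len = 3 * int(rng.integers(cfg.cds_codon_range[0],
                                       cfg.cds_codon_range[1] + 1))
        sites: list[SiteTruth] = []
        if is_target[i]:
            n_sites = int(rng.integers(cfg.sites_per_target[0],
                                       cfg.sites_per_target[1] + 1))
            while True:
                utr5_len = int(rng.integers(cfg.utr5_len_range[0],
                                            cfg.utr5_len_range[1] + 1))
                attempt = _build_utr5(rng, utr5_len, n_sites, cfg)
                if attempt is not None:
                    utr5_seq, sites = attempt
                    break
        else:
            utr5_len = int(rng.integers(cfg.utr5_len_range[0],
                                        cfg.utr5_len_range[1] + 1))
            utr5_seq = _rand_seq(rng, utr5_len)
        cds_seq = _rand_seq(rng, cds_len)
        utr3_seq = _rand_seq(rng, cfg.utr3_len)
        tseq = utr5_seq + cds_seq + utr3_seq

        gseq = str(Seq(tseq).reverse_complement()) if strand == "-" else tseq
        tx_start = gpos
        genome_parts.append(gseq)
        gpos += len(gseq)
        genome_parts.append(_rand_seq(rng, cfg.intergenic_gap))
        gpos += cfg.intergenic_gap

        if strand == "+":
            cds_start = tx_start + utr5_len
        else:
            cds_start = tx_start + cfg.utr3_len
        records.append(
            AnnotationRecord(gene_id=gid, chrom=cfg.chrom, strand=strand,
                             cds_start=cds_start, cds_end=cds_start + cds_len,
                             utr5_len=utr5_len, utr3_len=cfg.utr3_len)
        )
        tx_seqs[gid] = tseq
        truth.genes[gid] = GeneTruth(is_target=bool(is_target[i]),
                                     abundance=float(abundances[i]),
                                     sites=sites)

    genome = {cfg.chrom: "".join(genome_parts)}
    tset = build_transcript_set(records)
    tset.attach_genome(genome)
    for gid, t in tset.transcripts.items():
        assert tset.sequences[gid] == tx_seqs[gid]
    return tset, genome, truth


def write_gff3(tset: TranscriptSet, path) -> None:
    """GFF3 annotation (1-based inclusive) with UTR and CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tset:
            def feat(ftype, start, end):
                fh.write(
                    f"{t.chrom}\tcracpipe_sim\t{ftype}\t{start + 1}\t{end}\t.\t"
                    f"{t.strand}\t.\tID={t.gene_id}\n"
                )
            if t.strand == "+":
                if t.utr5_len:
                    feat("five_prime_UTR", t.genomic_start, t.cds_start)
                feat("CDS", t.cds_start, t.cds_end)
                if t.utr3_len:
                    feat("three_prime_UTR", t.cds_end, t.genomic_end)
            else:
                if t.utr3_len:
                    feat("three_prime_UTR", t.genomic_start, t.cds_start)
                feat("CDS", t.cds_start, t.cds_end)
                if t.utr5_len:
                    feat("five_prime_UTR", t.cds_end, t.genomic_end)


# ---------------------------------------------------------------------------
# CRAC reads
# ---------------------------------------------------------------------------

@dataclass
class _Molecule:
    gene_id: str
    start: int       # transcript space
    length: int
    del_pos: int | None = None   # transcript position of deletion start
    del_width: int = 0
    sub_pos: int | None = None
    sub_base: str = ""
    umi: str = ""

    def insert_seq(self, ref: str) -> str:
        s = list(ref[self.start : self.start + self.length])
        if self.sub_pos is not None:
            s[self.sub_pos - self.start] = self.sub_base
        if self.del_pos is not None:
            lo = self.del_pos - self.start
            del s[lo : lo + self.del_width]
        return "".join(s)


def _sample_molecule(
    rng: np.random.Generator,
    gid: str,
    t: TranscriptModel,
    ref: str,
    cfg: SimulationConfig,
    site: SiteTruth | None,
) -> tuple[_Molecule, int | None]:
    """One cross-linked RNA molecule; returns (molecule, scar_offset or None)."""
    L = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
    L = min(L, t.length)
    scar_offset = None
    if site is None:
        start = int(rng.integers(0, t.length - L + 1))
    else:
        ds = site.downstream_start
        # the read must cover the scar window and the motif start
        lo = max(0, ds + 4 - L)
        hi = min(ds - 5, t.length - L)
        if hi < lo:
            lo = hi = max(0, min(ds - 5, t.length - L))
        start = int(rng.integers(lo, hi + 1))
    mol = _Molecule(gene_id=gid, start=start, length=L)
    if site is not None and rng.random() < cfg.scar_prob:
        off = int(rng.integers(cfg.scar_offset_range[0],
                               cfg.scar_offset_range[1] + 1))
        width = int(rng.integers(cfg.scar_width_range[0],
                                 cfg.scar_width_range[1] + 1))
        dpos = site.downstream_start + off
        if start < dpos and dpos + width <= start + L:
            mol.del_pos, mol.del_width = dpos, width
            scar_offset = off
    if rng.random() < cfg.substitution_prob:
        # substitutions may not touch the deleted bases
        while True:
            sp = int(rng.integers(start, start + L))
            if mol.del_pos is None or not (mol.del_pos <= sp
                                           < mol.del_pos + mol.del_width):
                break
        old = ref[sp]
        choices = [b for b in "ACGT" if b != old]
        mol.sub_pos, mol.sub_base = sp, str(rng.choice(choices))
    mol.umi = _rand_seq(rng, cfg.umi_len)
    return mol, scar_offset


def _molecule_to_sam(
    mol: _Molecule, t: TranscriptModel, ref: str, header: pysam.AlignmentHeader,
    name: str,
) -> pysam.AlignedSegment:
    """Build the genomic SAM record for a transcript-space molecule."""
    # transcript-space cigar ops in transcript order
    if mol.del_pos is None:
        ops = [(0, mol.length)]
    else:
        m1 = mol.del_pos - mol.start
        m2 = mol.length - m1 - mol.del_width
        ops = [(0, m1), (2, mol.del_width), (0, m2)]
    seq_t = mol.insert_seq(ref)
    tx_end = mol.start + mol.length
    if t.strand == "+":
        gstart = t.genomic_start + mol.start
        cigar = ops
        seq = seq_t
    else:
        gstart = t.genomic_end - tx_end
        cigar = ops[::-1]
        seq = str(Seq(seq_t).reverse_complement())
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 16 if t.strand == "-" else 0
    a.reference_name = t.chrom
    a.reference_start = gstart
    a.mapping_quality = 60
    a.cigartuples = cigar
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def simulate_crac_reads(
    tset: TranscriptSet,
    truth: GroundTruth,
    cfg: SimulationConfig,
    sam_path,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Simulate cross-linking reads and write a genomic SAM file.

    Per gene, background molecules arrive at a Poisson rate proportional to
    abundance x length (so CRAC and RNA-seq TPM agree for unbound genes);
    target genes receive ``occupancy_multiplier`` times as many
    site-centred molecules, split across their embedded sites.  Each
    molecule carries a deletion scar with probability ``scar_prob`` at an
    offset drawn from ``scar_offset_range`` relative to the downstream
    motif start, and is replicated Poisson(pcr_duplication_mean)+1 times
    with the same UMI.  Updates ``truth`` with per-gene unique-molecule
    counts (distinct (insert, UMI) pairs) and realized scar offsets.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(tset.transcripts)
    w = np.array([truth.genes[g].abundance * tset[g].length for g in genes])
    w_mean = w.mean()

    genome_len = max(t.genomic_end for t in tset) + cfg.intergenic_gap
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": cfg.chrom, "LN": int(genome_len)}]}
    )
    n_rec = 0
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for gi, gid in enumerate(genes):
            t = tset[gid]
            ref = tset.sequences[gid]
            gt = truth.genes[gid]
            lam_bg = cfg.background_reads_mean * w[gi] / w_mean
            n_bg = int(rng.poisson(lam_bg))
            molecules: list[tuple[_Molecule, int | None]] = [
                _sample_molecule(rng, gid, t, ref, cfg, None)
                for _ in range(n_bg)
            ]
            if gt.is_target and gt.sites:
                n_site = int(rng.poisson(lam_bg * cfg.occupancy_multiplier))
                for _ in range(n_site):
                    site = gt.sites[int(rng.integers(len(gt.sites)))]
                    molecules.append(
                        _sample_molecule(rng, gid, t, ref, cfg, site))
            families = set()
            for mol, off in molecules:
                if off is not None:
                    gt.scar_offsets.append(off)
                families.add((mol.insert_seq(ref), mol.umi))
                n_copies = int(rng.poisson(cfg.pcr_duplication_mean)) + 1
                for _ in range(n_copies):
                    name = f"{gid}.m{n_rec}_{mol.umi}"
                    out.write(_molecule_to_sam(mol, t, ref, header, name))
                    n_rec += 1
            gt.n_unique_molecules = len(families)
    return truth


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    tset: TranscriptSet,
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts, two replicates by default.

    Expected counts are proportional to abundance x transcript length and
    scaled to ``rnaseq_depth`` reads per replicate; counting noise is
    gamma–Poisson with the configured dispersion (var = mu + disp * mu^2).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    genes = sorted(tset.transcripts)
    w = np.array([truth.genes[g].abundance * tset[g].length for g in genes])
    mu = cfg.rnaseq_depth * w / w.sum()
    data = {"gene_id": genes}
    disp = cfg.rnaseq_dispersion
    for rep in range(1, n_replicates + 1):
        if disp > 0:
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        else:
            lam = mu
        data[f"rep{rep}"] = rng.poisson(lam)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def simulate_titration(
    m: BindingModel,
    design: tuple[float, ...] = DEFAULT_TITRATION_NM,
    noise_sd: float | None = None,
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw anisotropy titration curves from the quadratic binding model.

    ``noise_sd`` defaults to 2% of the dynamic range (r1 - r0).  Returns a
    tidy frame (replicate, rec_conc_nM, anisotropy, sd) with sd set to the
    generating noise level.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = 0.02 * abs(m.r1 - m.r0)
    conc = np.asarray(design, dtype=float)
    ideal = model_anisotropy(m, conc)
    rows = []
    for rep in range(1, n_replicates + 1):
        noisy = ideal + (rng.normal(0.0, noise_sd, size=conc.size)
                         if noise_sd > 0 else 0.0)
        for c, r in zip(conc, noisy):
            rows.append({"replicate": rep, "rec_conc_nM": c,
                         "anisotropy": r, "sd": noise_sd})
    return pd.DataFrame(rows)


def titration_points(df: pd.DataFrame, replicate: int = 1) -> list[TitrationPoint]:
    sub = df[df["replicate"] == replicate]
    return [
        TitrationPoint(rec_conc=float(r.rec_conc_nM), r=float(r.anisotropy),
                       sd=float(r.sd) if "sd" in df.columns else None)
        for r in sub.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, out_dir) -> GroundTruth:
    """Emit every pipeline input into ``out_dir``: genome + transcript FASTA,
    GFF3, SAM, RNA-seq counts TSV, a titration TSV, and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    tset, genome, truth = simulate_transcriptome(cfg, rng)
    write_fasta(genome, out / "genome.fasta")
    write_fasta(tset.sequences, out / "transcripts.fasta")
    write_gff3(tset, out / "annotation.gff3")
    simulate_crac_reads(tset, truth, cfg, out / "crac.sam", rng)
    simulate_rnaseq(tset, truth, cfg, rng).to_csv(
        out / "rnaseq_counts.tsv", sep="\t", index=False)
    m = BindingModel(kd=8.0, r0=0.05, r1=0.25, probe_conc=20.0)
    simulate_titration(m, rng=rng).to_csv(
        out / "titration.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    return truth
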