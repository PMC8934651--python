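# Methods

## Transcript model and coordinates

Each gene is a single contiguous genomic interval: 5′UTR + CDS + 3′UTR on
one strand. Multi-isoform and spliced transcripts are out of scope —
cross-link pileups here are single-interval, and intron handling would add
no tested behavior at this scale. Internal coordinates are 0-based
half-open; GFF3 input is converted from 1-based inclusive; BED/bedGraph
output is 0-based half-open, matching each format's standard. Transcript
position 0 is the 5′-most base of the 5′UTR on the coding strand.

Annotations of verified ORFs frequently lack UTRs. Missing UTRs are filled
with **default lengths of 25 nt (5′) and 125 nt (3′)** — the standard
choice for budding-yeast CRAC work — flagged `utr*_default`, and extended
in genomic space (minus-strand extension happens genomically, then
coordinates flip). Extensions running past position 0 of the contig are
truncated silently but keep the flag. No clipping against neighboring
genes is performed; the synthetic genome keeps genes 200 nt apart so the
case never arises in the benchmark.

## Read processing

**Assignment.** Aligned SAM records (pysam) are assigned to the
same-strand transcript with the longest overlap; ties break
lexicographically by gene id. Only primary alignments are used. Records
without a CIGAR, unmapped records and reads overlapping no transcript are
skipped with logged counts.

**Duplicates.** Two reads are PCR duplicates only when both the insert
sequence and the random barcode nucleotides (UMI, parsed from the read
name after the last `_`, delimiter configurable) are identical. The first
read in input order represents each class, making collapse deterministic
and idempotent.

**Deletion ambiguity.** A deletion of width w at reference position p is
equivalent to one at p−1 iff `ref[p−1] == ref[p−1+w]` (and symmetrically
rightward). Aligners left-align, which would bias scar metaprofiles
upstream, so each deletion stores its leftmost placement plus the number
of equivalent placements and pileups spread total weight 1 uniformly
across them. Substitutions are taken from mismatches between aligned bases
and the transcript sequence (mismatches only; soft-clipped ends are not
counted). Insertions are retained in the alignment arithmetic but not
profiled as scars.

## Peak calling

The exact internals of the FDR peak callers used in published CRAC
pipelines are not specified beyond their intent, so the null is defined
here explicitly for reproducibility: for one transcript, the deduplicated
read lengths are placed uniformly at random (reads longer than the
transcript sit at position 0, clipped), 100 iterations by default. For
each height h,

FDR(h) = mean null fraction of positions with coverage ≥ h
         ÷ observed fraction with coverage ≥ h,

capped at 1 and made monotone non-increasing in h by a running minimum.
Peaks are maximal runs of positions whose height passes FDR ≤ 0.05
(minimum width 1 nt; adjacent qualifying positions merge), reported with
their max height and the FDR at that height. FDR is computed per
transcript, matching the per-gene randomization; the top-N filter
(default 100) ranks by height with ties broken by lower FDR then gene id.
One RNG stream seeds the whole multi-gene run, so output is bit-identical
given the seed.

## Motif analysis

Matching is IUPAC-based, case-insensitive and U/T-equivalent (everything
is normalized to DNA internally). Scanning reports all overlapping hits.

**Tandem counting.** The counting rule is defined by one worked case: a
12-nt tandem CNYUCNYUCNYU region counts as two CNYUCNYU occurrences. This
is generalized as a greedy left-to-right scan in which, after accepting a
match at i, the next acceptable match starts at ≥ i + period with
period = half the pattern length. The rule reproduces the worked case
((k+1)·period of repeat → k counts) and is well defined on arbitrary
sequences; it also collapses matches in different phases of a CU-repeat,
which a by-eye count might treat as distinct.

**Bipartite sites.** The spacer is measured end-of-CCAACU to
start-of-CNYUCNYU (half-open gap), window [4, 10] by default and
configurable — the source observation ("4–10 nt upstream") does not fix
the measurement convention, and a start-to-start convention would differ
by the 6-nt upstream motif length. Each downstream hit pairs with its
nearest qualifying upstream hit only, so tandem repeats do not
double-count sites.

**Upstream surveys** count occurrences (tandem rule) in the 3′-most
100 nt of start-codon-anchored upstream sequences and select genes with
≥ 2; shorter sequences use their full length and are flagged. **Category
enrichment** is an upper-tail hypergeometric test (scipy), replacing web
gene-ontology tools with an explicit, testable statistic.

**Scar metaprofiles** accumulate pileup deletion weight at offsets in
[−flank, flank) relative to each motif start (negative = upstream),
conserving the in-flank mass.

## Enrichment filter

TPM: rate_g = count_g/(length_g/1000), scaled to sum to 10⁶. Replicates
are averaged as TPM before filtering. A gene is a target iff
crac_tpm/rnaseq_tpm ≥ 4 and rnaseq_tpm ≥ 20; no pseudocount is used since
the TPM floor guarantees a nonzero denominator for every reported target.
An exact binomial upper-tail test with Benjamini–Hochberg adjustment is
available as an optional per-gene diagnostic; it is intentionally not a
substitute for shrinkage-based differential analysis, which is out of
scope.

## Binding model and fitting

The quadratic ligand-depletion isotherm (see README for the formula)
describes anisotropy when probe concentration [P] is comparable to K_D.
The discriminant is clamped at 0 against round-off. Model invariants —
r(0) = r0 exactly, saturation at r1, monotonicity for r1 > r0, and
first-order agreement with the hyperbolic form when [P] ≪ K_D — are
property-tested.

Fitting: residuals are weighted by 1/sd when per-point standard
deviations are present and weighting is requested (so the squared
objective uses 1/sd²; the functional form of "sd-based weighting" is a
package choice). K_D, r0 and r1 float by default; r1 can be fixed from a
saturating plateau. Initialization is multi-start with seven K_D starts
log-spaced over [min [Rec]/10, max [Rec]·10]; the best-objective solution
wins. Flat data, or a fitted K_D pinned at the start-grid boundary, is
reported as unidentifiable with no K_D. Standard errors come from the
Jacobian at the optimum. Fits require ≥ 4 points spanning a ≥10-fold
concentration range. The 15- and 30-min incubation series are treated as
independent datasets; no kinetic model is attempted.

## Synthetic benchmark: what it emulates and what it does not

The generator's defaults are the standing study conditions, not tuning
knobs:

- 200 genes on one chromosome, random strands, 200-nt random intergenic
  gaps; CDS 300–1500 nt; 5′UTRs 50–400 nt; 3′UTRs 125 nt. Background
  sequence is i.i.d. uniform ACGU — real genome composition is not
  emulated, and the analytic false-positive rate for bipartite sites
  (p = 1/1024 per position for CNYUCNYU, 1/4096 for CCAACU, 7 spacer
  positions) is computed for this composition.
- 10% of genes are targets carrying 1–5 embedded bipartite sites in their
  5′UTRs (concrete CCAACU + random 4–10-nt spacer + concrete CNYUCNYU
  instantiation); embeddings are re-drawn if an accidental motif would
  re-pair an embedded downstream hit.
- Cross-link molecules: background reads arrive Poisson with mean 20 per
  gene scaled by abundance × length (so CRAC TPM tracks RNA-seq TPM for
  unbound genes); target genes get a 10× occupancy multiplier of
  site-centred molecules. Read lengths are uniform 20–40 nt, a stand-in
  for sequencing-library insert sizes after adapter removal; the exact
  distribution is configurable. With probability 0.3 a site molecule
  carries a 1–2-nt deletion at an offset drawn uniformly from [−4, −2]
  relative to the downstream motif start; random substitutions occur at
  rate 0.05 per molecule. Each molecule is emitted Poisson(3)+1 times
  with the same 6-nt UMI.
- RNA-seq: log-normal abundances (σ = 1.5, spanning orders of magnitude),
  gamma–Poisson counts (dispersion 0.05), 2 replicates of 200 000 reads.
- Titrations: 13 points (0 plus a 2-fold dilution series from 1000 nM,
  spanning all benchmarked K_D values of 8–166 nM), probe 20 nM, Gaussian
  noise with sd = 2% of the dynamic range. The anisotropy endpoints
  r0 = 0.05, r1 = 0.25 are typical values for a Cy3-labelled probe; only
  K_D differs between the benchmark parameter sets.

Passing recovery tests on this benchmark shows the pipeline is internally
consistent and correctly inverts its own generative assumptions at
realistic signal-to-noise; it does not demonstrate robustness to
alignment artifacts, non-uniform base composition, transcript-boundary
ambiguity or structured background binding present in real libraries.

## Problem sizes and determinism

The default benchmark (200 genes, ~27k raw reads) runs the full pipeline
in a few seconds; peak-caller calibration uses 200 null transcripts × 100
Monte-Carlo iterations; binding recovery uses 100 replicate fits per
parameter set. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical seeds give byte-identical
generator output and bit-identical pipeline results.

## Known limitations

- Single-interval transcripts only; no 5′UTR introns, no isoforms.
- Reads spanning two genes are assigned wholly to the longest-overlap
  gene; no fractional assignment.
- Substitution scars are counted from aligned mismatches only.
- The top-N peak filter operates per dataset; pooling across conditions
  is left to the caller.
- The binomial enrichment diagnostic ignores biological replicate
  variance.
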