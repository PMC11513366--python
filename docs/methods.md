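# Methods

This note documents the models and conventions behind `cas9tiling`: what is
computed, which parameters matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open (BED convention). The two
printed-coordinate dialects are converted at the I/O boundary: region
strings (`chr1:68,423,822-68,454,954`) are 1-based inclusive, VCF positions
1-based. FASTA/FASTQ pass through Biopython; BED3/4, the BED6-like
exon/CDS transcript table and the headerless minimal 8-column VCF dialect
are parsed directly (they are deliberately desk-scale text files; only
site identity, QUAL and the INFO `AF=` key are consumed from VCF). All
readers accept gzip-compressed input.

## Guide model

A candidate is a 20-nt protospacer whose targeted strand is immediately
followed by an NGG PAM. SpCas9 cuts bluntly 3 bp 5' of the PAM; `cut_pos`
is the boundary between protospacer positions 17 and 18, stored as a
plus-strand coordinate (for a minus-strand site whose window starts at `i`
on the plus strand, the cut falls at `i + 6`). Windows containing N are
discarded rather than expanded.

Per-guide metrics:

* **GC%** — `100 · (#G + #C) / 20`.
* **Self-complementarity** — a 4-mer seed count: ordered protospacer
  position pairs `(i, j)` with `j ≥ i + 7` whose 4-mers are reverse
  complements (a hairpin seed with a ≥ 3 nt loop), plus protospacer 4-mers
  whose reverse complement occurs in the invariant crRNA backbone
  (`AGGCTAGTCCGT` by default). The seed length 4 follows the common
  guide-design heuristic of flagging complementary stretches of ≥ 4 bp.
* **Off-targets MM0–MM3** — the number of genomic sites (both strands, all
  records) with an intact NGG PAM whose 20-mer differs from the protospacer
  at exactly m positions, the on-target site (same record, footprint and
  strand) excluded. Computed with a vectorised sliding-window scan and
  tested against a naive per-window oracle. PAM degeneracy is exact (N
  matches nothing; a site containing N simply accumulates mismatches).
* **Efficiency** — a deterministic heuristic in [0, 1]:
  `0.5 + 0.2·[base20 = G] − 0.1·[base20 = T] + 0.1·[40 ≤ GC ≤ 70]
  − 0.2·[GC < 30 or GC > 80] − 0.15·[homopolymer ≥ 5] − 0.1·[self-comp > 0]`,
  clamped and quantised to 2 decimals. It rewards the PAM-proximal G and
  mid-range GC that empirical activity models consistently favour, but it
  is *not* a trained model; the scorer sits behind a plain function so a
  published model can be substituted. Published per-guide efficiency values
  are therefore not reproduced by this package.

The selection criteria are GC ∈ [30, 80] %, self-complementarity = 0, total
off-target sites over MM0–MM3 strictly below 10, efficiency ≥ 0.2. The
off-target criterion is read as a bound on the *total site count* (not the
mismatch count of one site), with the on-target occurrence excluded.

## Tiling design

The locus is optionally expanded by symmetric flanks (default 5,000 bp) and
partitioned into `n = ceil(length / block_size)` contiguous blocks
(default block 10,000 bp) with boundary `k` at
`start + round_half_up(k · length / n)`, so blocks differ by at most 1 bp.
Each block receives one pair: among criteria-passing minus-strand
candidates whose cut lies within ±`window` (default 1,500 bp, growing by
500 bp up to 5,000 bp if empty) of the block's left edge, the highest
efficiency wins, ties broken by distance to the edge and then
lexicographically by protospacer — a fully deterministic stand-in for the
manual "best overall parameters" selection such designs are usually made
by. The plus-strand guide is chosen symmetrically at the right edge.

Hard invariants, enforced after selection: every guide passes the criteria;
a pair's cuts are at most one block apart; adjacent cuts across the whole
design are < 10 kb apart (the spacing the tiling approach requires for
contiguous coverage). Violation raises `DesignError` rather than returning
a degraded design. On random references at GC 0.40 the candidate density
(~0.08 sites/bp over both strands) makes completion overwhelmingly likely;
references with exactly block-sized tiles are the tightest case because a
pair must then fit entirely inside its block.

Pool layouts: *bricklayer* places odd-indexed pairs in pool A and
even-indexed in pool B, so adjacent, overlapping pairs never share a pool;
*highway* pools are the strand classes (C = minus-cut guides, D = plus-cut
guides). Both partition the guide set exactly.

## Read simulator

Each of `n_molecules` (default 1,000) molecules is an independent copy of
the reference. Every guide cuts its molecule with probability equal to its
efficiency score — the score doubles as a capture probability, a modelling
choice, since cut efficiency is the quantity the criteria bound. Each
realised cut releases one read starting exactly at the cut: minus-strand
guides launch reads toward increasing coordinates, plus-strand guides
toward decreasing ones, matching a layout in which minus guides sit at
left block edges and plus guides at right edges so reads flow inward.
Read length is `min(lognormal(ln 8000, 0.6), distance to the next realised
cut, distance to the sequence end)` — the truncation models fragmentation
of the molecule by multiple RNPs. At most one background read per molecule
occurs with probability `background_rate` (default 0.01), uniformly placed,
random direction, truncated the same way.

Per-read quality is `max(0, Normal(12, 2.5))`; the pass filter keeps reads
with mean Q ≥ 9 (inclusive). FASTQ emission writes a flat per-base quality
and injects substitutions at the Phred rate `10^(−q/10)` under an explicit
seed; reverse reads are emitted as reverse complements. With a fixed seed
the simulator and both emitters are byte-reproducible.

Two consequences worth noting. Coverage decays monotonically (in
expectation) downstream of each cut, producing the sawtooth on-target
profile characteristic of Cas9 enrichment. And the *median* read length in
a tiled design sits below the 8 kb lognormal median, because cut spacing
(~7.8 kb for a 31 kb / 4-block design) truncates the upper tail; the length
model itself is validated on a single-guide geometry where truncation
cannot bite.

## Coverage QC

Depth is computed exactly from read intervals clipped to the region
(difference-array cumulative sum, tested against per-base membership
counting), so Σ depth = Σ clipped lengths holds identically. A read is
on-target when it intersects the region by ≥ 1 bp; N50 uses full read
lengths of on-target reads and is the standard largest L such that reads of
length ≥ L contain at least half of all bases. Percentages and mean depths
are rounded half-up to 2 decimals, the convention used in printed QC
tables (e.g. 59/71 → 83.10 %).

## Callset comparison

Matching is by the exact `(chrom, pos, ref, alt)` key with no indel
normalisation (left-alignment differences between callers will therefore
register as discordance — a real sensitivity of custom merge scripts,
deliberately not hidden). Concordance is `100 · |shared| / |B|` against the
designated reference callset B. Classification against a single transcript
model is a total partition: coding (inside the CDS span of an exon),
5'/3'UTR (exonic outside the CDS, side resolved by strand), intronic
(inside the transcript span, not exonic) and flanking; intronic and
flanking variants carry their distance to the nearest exon (first intronic
base = 1) so any "deep intronic" cutoff can be applied downstream. The
rarity filter keeps AF < 0.001, with missing AF treated as rare (absent
from population databases), and the low-quality tally counts QUAL < 10.

## Synthetic fixtures

References are i.i.d. draws at a configurable GC fraction (default 0.40,
length 31,133 bp) with optional planted 23-mer sites carrying an exact
number of protospacer mismatches and an intact PAM — recovered by the
off-target scan at precisely their stated level. The default transcript
layout is 14 exons / 13 introns spanning 21,133 bp (a ~3.5 kb mRNA with a
short 5'UTR and long 3'UTR), sized to echo a compact retinal-gene locus
sitting inside the 31 kb region with 5 kb on each side. Paired callsets
realise a configured structure — by default 69 reference-callset variants,
68 shared, 3 query-only with QUAL in [4, 9.9] (marginal false-positive
signature) — and a category mix over the query callset (default use case:
9 coding / 59 intronic / 3 3'UTR of 71).

What the fixtures do **not** emulate: real base composition and repeats
(i.i.d. bases undercount genomic off-targets relative to a real genome —
off-target criteria are exercised against planted sites, not human
paralogy), haplotypes and genotypes, indel representation ambiguity,
pore-level error structure (errors are uniform substitutions at the
per-read Phred rate) and library-preparation yield differences between
pool layouts. Passing tests therefore demonstrate correctness of the
computations and the stated model properties, not performance on patient
data.

## Numerical choices and degenerate inputs

Half-up rounding everywhere a printed-style percentage or boundary is
produced (`decimal`-based, not banker's rounding). Efficiency scores are
quantised to 2 decimals, making tie-breaks reproducible across platforms.
Tile boundaries use half-up rounding of `k·length/n`. Empty designs, empty
reference callsets, zero-length intervals, inverted regions, non-DNA
characters and overlapping planted sites all raise typed errors rather than
degrading silently. `read_n50` of k equal lengths is that length for any k.

## Known limitations

The efficiency surrogate is uncalibrated against experimental cleavage
data; off-target counting is exhaustive (fine to ~100 kb references, not a
genome-scale seed-and-extend search); no bulge-tolerant off-target model or
non-NGG PAM variants; QC consumes interval tables rather than BAM/CIGAR;
structural-variant comparison and functional annotation are out of scope.

## Acceptance script problem size

`scripts/acceptance.py` runs the design on one 31,133 bp reference
(GC 0.40) drawn from the given seed — the full locus size of the intended
use case, and small enough that the whole computation takes seconds. If a
draw happens to admit no invariant-satisfying design (rare at this GC), a
fresh reference is drawn from a derived seed, which cannot bias the
reported quantities: they are invariants every completed design satisfies
by construction.
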