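# Methods

This note documents the models and procedures implemented in `draftweaver`,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish.

## The repair model

The toolkit assumes a draft assembly of a (near-)clonal bacterial genome and
at least one finished genome of a close relative. Three empirical facts
underpin the procedures:

1. Contig ends that flank the same physical gap map to nearby, facing
   locations on a syntenic reference. The toolkit pairs ends whose best
   reference alignments lie on the same reference sequence within a
   separation ceiling, facing each other, and derives the gap size from the
   reference separation minus each end's unaligned tip (those tip bases are
   real sequence, not gap).
2. Assembler N-run lengths beyond the paired-end insert size are artifacts.
   Runs longer than 300 Ns are re-estimated from the reference-implied
   distance between their 300 bp flanks; when the flanks cannot be placed
   the run is set to exactly 300 — the library's maximum insert, which is
   the best available upper bound.
3. A k-mer occurring exactly once in the draft and once in the reference is
   an unambiguous coordinate anchor. Order and orientation of scaffolds
   follow from the median anchor coordinate and the majority anchor strand.

## Alignment engine

`homology.local_align` is an exact-word seeded local aligner: an inverted
index of forward-strand 11-mers over the subject database (N-containing
words excluded; the minus strand is searched by reverse-complementing the
query), seed clustering by diagonal, X-drop ungapped extension (drop 20),
then a banded affine-gap Smith–Waterman around the cluster's diagonals
(band half-width 32, band-limited memory). Scoring defaults are match +1,
mismatch −2, gap open 5, extend 2 (a gap of length L costs 5 + 2L).

The X-drop stage delimits the dynamic-programming window; its survivor
cutoff defaults to the bare seed score, i.e. every exact-seed cluster is
aligned. A more aggressive cutoff would be faster on repetitive data but
sacrifices the guarantee — verified against a full Smith–Waterman oracle in
the test suite — that the heuristic recovers the optimal local score
whenever query and subject share an exact word, even at 20% divergence.

E-values use the ungapped Karlin–Altschul form `E = K·m·n·e^(−λS)` with
λ = 1.28 per score unit and K = 0.46, as an approximation for gapped
scores; `n` is the total forward-strand length of the subject database
(the strand factor is absorbed into K). Only the downstream cutoff
(E ≤ 0.02) matters to the gap-closure consumers, so the approximation is
inconsequential: qualifying hits in practice sit scores of magnitude
hundreds above the cutoff score (~18 for a 300 bp query on a 500 kb
database).

A repeat guard flags queries whose qualifying hits fall into more than 5
distinct subject regions (regions closer than 100 bp are merged); flagged
ends never seed joins, since the closure procedure assumes near-unique
placements.

`homology.smith_waterman` — the full-dynamic-program oracle used by the
tests — is backed by Biopython's `PairwiseAligner` in local mode with the
same affine costs. It is never called by the search path.

## Gap closure rules and conventions

- End extraction: 300 bp (`end_len`) from each end of contigs **strictly**
  longer than 1 kb; the 1 kb and the 300-N thresholds below are strict
  inequalities, and boundary tests pin each.
- Separation is measured between the **inner boundaries** of the two
  reference alignments (the facing edges); pairs qualify at |separation| ≤
  `max_ref_separation` (default 1000; a pair at exactly 1000 qualifies,
  1001 does not).
- Orientation consistency: the side of each end and the strand of its hit
  determine the reference direction in which its gap lies; a pair qualifies
  only if the two directions face each other. Inconsistent pairs are logged,
  never joined.
- A negative implied gap (alignments overlapping on the reference) is
  floored at 0 and flagged.
- Overlap merges require an **exact** suffix–prefix match of at least 15 bp
  between reference-adjacent contigs, testing both orientations, at the
  maximal such overlap; one mismatch disqualifies a length.
- Shared-gene pairing requires the two ends' hits to cover **disjoint**
  portions of the same reference gene with consistent orientation; the
  proposed gap is the unaccounted gene bases between the portions (min 1).
- `apply_joins` consumes each contig end at most once, resolving conflicts
  by evidence rank (overlap merge > shared gene > reference adjacency),
  then score, then lexicographic contig id; an edge that would close a
  cycle is rejected, which breaks every cycle at its lowest-ranked edge.
- N-run resizing touches only runs strictly longer than 300; flank pairs
  must map to the same reference sequence, facing, within 50 kb (a ceiling
  chosen comfortably above the worst observed artifact run sizes;
  configurable). A reference-implied distance below 1 becomes a 1-N run
  with an overlap flag. Runs flush against a scaffold edge are left
  unchanged with a warning.

## Reordering and congruency

Anchoring uses double-stranded k-mer uniqueness (k = 25): a k-mer and its
reverse complement are one entity, counted across all scaffolds and both
strands; palindromic k-mers are never unique. This is the conservative
reading that guarantees unambiguous placement. Placement requires length
strictly over 1 kb and at least 3 anchors (`min_anchors`); orientation is
the strict majority anchor strand, with 50/50 ties left unplaced
("orientation tie"). Both choices are knobs; the defaults favour precision
over placement rate.

Congruency support is deliberately **per supporting contig**: a contig is
supported when ≥ 95% of its length is covered by ≥ 99%-identity local
alignments to a *single* contig of another assembly. This is what makes a
chimera detectable — each half of a chimera is fully covered somewhere, but
no honest contig contains both halves. The converse limitation is accepted
and documented: a correct contig whose counterpart happens to be split
across two contigs of the other assembly also reads as unsupported.
Contigs are tiled into 1 kb query chunks for alignment; coverage is the
union of tile hit intervals per candidate supporter. An assembly is marked
`cull` only when an unsupported contig is at least 10 kb (`large_cutoff`).

## Synteny and GC tracks

Dot plot points are unique-25-mer matches (double-stranded uniqueness on
both sides, perfect matches only), reported as forward-strand start
coordinates with a strand flag; an inverted segment appears as an
anti-diagonal run of minus-strand points. GC tracks use 10 kb windows with
5 kb steps by default (configurable; the values are a resolution choice,
not a biological one), half-open, final partial window included, N bases
excluded from numerator and denominator; skew is (G−C)/(G+C), defined as 0
and flagged when a window has no G or C.

## Promoter-box model

The motif model is an ungapped position log-odds profile rather than a full
profile HMM: the target boxes are essentially fixed-length (27 bp with rare
single-column deviations), and the biologically decisive steps are the bit
threshold and the CDS-distance filter, which the profile supports exactly.
A match/insert/delete HMM is a documented extension point.

Column probabilities are `(count + 0.5) / (n_nongap + 2)` (pseudocount 0.5
over 4 bases); log-odds are in bits against an explicit background, by
default the target genome's mononucleotide frequencies. Majority-gap
columns are dropped. Scanning scores every window on both strands;
same-strand hits whose starts differ by less than half the model length
collapse to the best. Absolute bit scores therefore depend on this
package's null model and are not comparable to other tools' bit scales —
only threshold semantics (≥ 3.0 bits by default) transfer.

"Within 500 bp of a CDS" means: a CDS start lies downstream of the box end
on the **same strand** at distance 0–500 inclusive, with distance measured
box-end → CDS-start along the strand. The nearest qualifying CDS and the
distance are recorded per hit.

## Read preparation and coverage

Trimming is keyed on read length (by default 4 bases off 36-mers, 6 off
76-mers) and precedes the ambiguity filter, so a read whose only N sits in
the trimmed tail survives. In paired mode a read is removed iff it or its
mate contains a non-ACGT base after trimming. The operation is idempotent.
Theoretical coverage is `round(reads × ends × length / genome_size)`,
rounded to the nearest integer because coverage folds are conventionally
reported as integers.

## The simulator, and what passing tests show

`simulate` draws i.i.d. bases at a target GC (default 0.6, bacterial-like),
then derives a reference by substitutions, 1–5 bp indels and optional
non-overlapping inversions; fragments the genome into contigs with recorded
adjacencies, gap sizes, optional duplicated junctions, shuffling and
reverse-complementation; corrupts scaffold N-runs to a wrong size (default
10,000 Ns) while recording the truth; and plants non-overlapping genes
(300–3,000 bp, one per genome slot so overlap is impossible) with motif
instances sampled from a profile 0–500 bp upstream of a subset of gene
starts. Every operation draws from a per-operation child stream of the
config seed, so one seed reproduces the whole bundle bit-exactly.

The i.i.d. background lacks repeats by design — the closure procedures
assume near-unique placements — so the round-trip results (100% adjacency
recall with exact gap sizes at zero divergence; full recall, zero accepted
false joins and ≤ 5 bp median gap error at 1% substitutions + 0.1% indels)
certify the machinery, not performance on repeat-rich genomes. A tandem
repeat knob (`repeat_copies`) exists to exercise the repeat-ambiguity
guard. Real drafts additionally contain collapsed repeats, coverage-driven
errors and chimeric contigs that the simulator models only via the
congruency fixtures.

Problem sizes in the shipped tests and acceptance script — 500 kb genomes
with 20 contigs for the closure round trips, 100 kb genomes for synteny and
motif recall, 200 aligner-oracle pairs — were chosen so the full
measurement battery completes in well under a minute while every rate is
estimated on at least ~20 events; all scale linearly if larger runs are
wanted. The candidate-search separation ceiling is set to the fixture's gap
range maximum (2000 bp) in the round-trip runs, since a threshold below the
largest simulated gap would exclude those adjacencies by construction; the
default 1 kb ceiling and its strict boundary are pinned by dedicated tests.

## Known limitations

- Karlin–Altschul parameters are ungapped approximations applied to gapped
  scores; E-values near the 0.02 cutoff are approximate (irrelevant at the
  score separations the closure rules operate at, but worth knowing).
- The banded aligner can split one biological alignment into two hits when
  indel drift exceeds the band; consumers use best-hit logic and are
  insensitive to this.
- Reordering places each scaffold independently by median anchor position;
  it does not detect rearrangements between draft and reference, and a
  scaffold spanning a true rearrangement breakpoint is placed at the median
  of its two segments.
- Shared-gene pairing is nucleotide-level; diverged genes detectable only
  as protein homology will not pair.
- The congruency verdict inherits fragmentation sensitivity as described
  above.
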