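# draftweaver

Reference-assisted improvement of draft bacterial genome assemblies.

A high-quality *draft* genome — the practical endpoint of most short-read
bacterial sequencing projects — arrives as dozens to hundreds of contigs with
unknown order, unknown orientation, physical gaps of unknown size, and
scaffold N-runs whose lengths are assembler artifacts. When a finished genome
of a close relative exists, almost all of these defects can be repaired *in
silico*. `draftweaver` packages that repair procedure as a reusable toolkit:

- **Gap candidate discovery** — extract 300 bp ends of every contig longer
  than 1 kb, align them to one or more reference genomes with a seeded local
  aligner, and pair ends that hit the same reference sequence no more than
  1 kb apart with facing orientations. Each pair is evidence that the two
  contigs flank the same physical gap, with an implied gap size.
- **Contig joining** — three evidence classes, applied in rank order:
  exact suffix–prefix overlaps of ≥ 15 bp between reference-adjacent contigs
  (the assembler's low-coverage extension failure), ends carrying partial
  coding regions of a common reference gene, and plain reference adjacency.
- **N-run resizing** — runs of more than 300 Ns are corrected to the
  reference-implied distance between their flanks, or capped at 300 (the
  paired-end library's maximum insert) when the flanks cannot be placed.
- **Reference-guided reordering** — scaffolds are ordered and oriented by
  the median reference coordinate of their unique 25-mer anchors
  (double-stranded uniqueness, perfect matches only).
- **Assembly congruency** — contigs of one assembly unsupported by every
  other assembly of the same reads flag chimeras; assemblies with large
  unsupported contigs are marked for culling.
- **Synteny dot plots and GC tracks** — unique-25-mer match coordinates
  between two genomes, and windowed GC% / GC-skew ((G−C)/(G+C)) tracks.
- **Promoter-box scanning** — a position log-odds profile (bits against the
  target genome's base frequencies) trained from aligned boxes, scanned on
  both strands with a bit threshold, and filtered to boxes within 500 bp
  upstream of a CDS start on the same strand (the hrp-box configuration).
- **Read preparation & coverage** — length-keyed 3′ trimming, ambiguity
  filtering (pairwise in paired mode), and theoretical fold coverage
  `reads × ends × length / genome size`.
- **A truth-known simulator** — genomes, diverged references
  (substitutions, indels, inversions), fragmented assemblies with recorded
  adjacencies and gap sizes, corrupted N-runs, planted genes and motifs —
  so every procedure above is testable without downloading anything.

The aligner is a self-contained seeded local search: exact 11-mer seeding on
both strands, X-drop ungapped extension, banded affine-gap Smith–Waterman
(match +1, mismatch −2, gap open 5, extend 2), and Karlin–Altschul E-values
`E = K·m·n·e^(−λS)` (λ = 1.28, K = 0.46). The default E-value cutoff for all
gap evidence is 0.02.

## Worked example

Simulate a 120 kb genome, a 1%-diverged reference, and a six-contig draft
with known gaps, then find and close the gaps:

```sh
$ cat sim.yaml
seed: 5
genome_len: 120000
n_contigs: 6
gap_range: [0, 800]
sub_rate: 0.01
indel_rate: 0.001
shuffle: true
n_rc: 2

$ draftweaver simulate --config sim.yaml --out fx/
fixture bundle -> fx

$ draftweaver gapfind --contigs fx/contigs.fa --ref fx/reference.fa --out cands.tsv
5 candidates -> cands.tsv

$ head -3 cands.tsv
contig_a  side_a  contig_b  side_b  reference  ref_a         ref_b         separation  implied_gap  overlap  evalue_a  evalue_b
c0001     right   c0002     left    reference  19412..19711  20339..20638  627         627          0        6.1e-157  6.1e-157
c0003     left    c0004     right   reference  59633..59932  60506..60805  573         573          0        2.84e-155 1.31e-158
```

All five physical gaps between the six contigs are recovered; the implied
gap sizes (627, 573, …) are the reference-separation of the facing end
alignments minus their unaligned tips, and here equal the simulator's true
gap sizes. Joining and resizing then rebuild scaffolds:

```sh
$ draftweaver join --contigs fx/contigs.fa --ref fx/reference.fa --out layout.agp --out-fasta scaf.fa
5 joins accepted, 0 rejected -> layout.agp

$ draftweaver resize --scaffolds fx/scaffolds_corrupted.fa --ref fx/reference.fa \
      --out resized.fa --report resize.tsv
5 runs -> resized.fa
$ head -3 resize.tsv
scaffold    start  old_n  new_n  rule       overlap
scaffold_1  19700  10000  627    reference  0
scaffold_1  49400  10000  190    reference  0
```

Every corrupted 10,000-N run is restored to its true size by the
`reference` rule. Reordering recovers the genome order and orientation of
all six contigs, including the two the simulator reverse-complemented:

```sh
$ draftweaver reorder --scaffolds fx/contigs.fa --ref fx/reference.fa --out placement.tsv
6 placed, 0 unplaced -> placement.tsv
```

Other entry points: `draftweaver stats | readprep | coverage | align |
congruency | dotplot | gctracks | scan` (see `--help` for each). All
thresholds above are fields of a single `Thresholds` object and are
command-line flags where relevant.

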