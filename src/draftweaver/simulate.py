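"""Truth-known synthetic fixtures for the whole pipeline.

The simulator emulates the situation the reference-assisted procedures
assume: a bacterial-sized genome with i.i.d. composition (so 25-mers are
essentially all unique), a diverged relative of it usable as a reference
(substitutions, small indels, optional inversions), a fragmented draft
assembly whose true adjacencies and gap sizes are known, scaffolds whose
N-runs have been corrupted to a wrong size, and planted genes and promoter
boxes.  Every operation is deterministic given the config seed; each step
draws from its own child stream so fixtures are reproducible op-by-op.

The i.i.d. background deliberately lacks repeats — the procedures assume
near-unique placements — but a tandem-duplication knob exists to exercise
the repeat-ambiguity guards.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Assembly, Contig, GeneFeature, revcomp
from .motifs import ProfileModel

log = logging.getLogger("draftweaver")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# child-stream keys, one per operation
_OP_GENOME, _OP_DIVERGE, _OP_FRAGMENT, _OP_PLANT, _OP_CORRUPT = range(5)


@dataclass
class SimConfig:
    """Parameters of a synthetic fixture; ``seed`` is mandatory."""

    seed: int
    genome_len: int = 500_000
    gc: float = 0.6
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    indel_len_max: int = 5
    n_inversions: int = 0
    inversion_len: tuple[int, int] = (5000, 15000)
    fragment_plan: Optional[list[tuple[int, int]]] = None  # (contig_len, gap_after)
    n_contigs: int = 20
    gap_range: tuple[int, int] = (0, 2000)
    overlap_bp: int = 0
    shuffle: bool = False
    n_rc: int = 0
    n_genes: int = 0
    n_motifs: int = 0
    repeat_copies: int = 0      # tandem copies of a segment, to stress the repeat guard
    repeat_len: int = 5000

    def __post_init__(self) -> None:
        for r in (self.gc, self.sub_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, op: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), op])


@dataclass
class TruthTable:
    """Ground truth of a fixture; internally consistent by construction."""

    genome_len: int = 0
    true_adjacencies: list[tuple[str, str, int, int]] = field(default_factory=list)  # (left, right, gap, overlap)
    true_order_orientation: list[tuple[str, str]] = field(default_factory=list)      # genome order
    true_nrun_sizes: list[tuple[str, int, int]] = field(default_factory=list)        # (scaffold, start, true size)
    planted_genes: list[GeneFeature] = field(default_factory=list)
    planted_motif_sites: list[dict] = field(default_factory=list)
    divergence_map: dict = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        """Adjacency gaps plus contig lengths (minus duplicated junctions)
        must sum to the genome length."""
        if not self.true_adjacencies or not self.contig_lengths:
            return
        total = sum(self.contig_lengths.values())
        total += sum(gap - ov for _, _, gap, ov in self.true_adjacencies)
        if total != self.genome_len:
            raise AssertionError(f"truth inconsistent: {total} != genome length {self.genome_len}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_genes"] = [dataclasses.asdict(g) for g in self.planted_genes]
        return d


def simulate_genome(config: SimConfig) -> str:
    """i.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    rng = config.rng(_OP_GENOME)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    codes = rng.choice(4, size=config.genome_len, p=p)  # A C G T
    genome = _BASES[codes].tobytes().decode("ascii")
    if config.repeat_copies > 1:
        seg_start = config.genome_len // 3
        seg = genome[seg_start : seg_start + config.repeat_len]
        genome = genome + seg * (config.repeat_copies - 1)
    return genome


def diverge(genome: str, config: SimConfig) -> tuple[str, dict]:
    """Apply substitutions, indels, then non-overlapping inversions.

    Returns the diverged reference and a map with collinear blocks
    ``(genome_start, genome_end, ref_start, ref_end)`` recorded before
    inversion, the inversion intervals in reference coordinates, and event
    counts.
    """
    rng = config.rng(_OP_DIVERGE)
    n = len(genome)
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    sub_pos = np.nonzero(rng.random(n) < config.sub_rate)[0]
    lut = {ord(a): [ord(b) for b in "ACGT" if b != a] for a in "ACGT"}
    for pos in sub_pos.tolist():
        codes[pos] = lut[int(codes[pos])][rng.integers(3)]
    mutated = codes.tobytes().decode("ascii")

    blocks: list[tuple[int, int, int, int]] = []
    parts: list[str] = []
    g_cursor = r_cursor = 0
    indel_pos = np.nonzero(rng.random(n) < config.indel_rate)[0]
    for pos in indel_pos.tolist():
        if pos < g_cursor:
            continue
        seg = mutated[g_cursor:pos]
        parts.append(seg)
        blocks.append((g_cursor, pos, r_cursor, r_cursor + len(seg)))
        r_cursor += len(seg)
        length = int(rng.integers(1, config.indel_len_max + 1))
        if rng.random() < 0.5:  # insertion into the reference
            ins = _BASES[rng.choice(4, size=length)].tobytes().decode("ascii")
            parts.append(ins)
            r_cursor += length
            g_cursor = pos
        else:  # deletion from the reference
            g_cursor = min(n, pos + length)
    seg = mutated[g_cursor:]
    parts.append(seg)
    blocks.append((g_cursor, n, r_cursor, r_cursor + len(seg)))
    ref = "".join(parts)

    inversions: list[tuple[int, int]] = []
    for _ in range(config.n_inversions):
        placed = False
        for _attempt in range(200):
            length = int(rng.integers(config.inversion_len[0], config.inversion_len[1] + 1))
            if length >= len(ref):
                continue
            start = int(rng.integers(0, len(ref) - length))
            if all(start + length <= s or e <= start for s, e in inversions):
                inversions.append((start, start + length))
                placed = True
                break
        if not placed:
            raise ValueError("could not place non-overlapping inversions; reduce n_inversions")
    ref_arr = list(ref)
    for s, e in inversions:
        ref_arr[s:e] = revcomp("".join(ref_arr[s:e]))
    ref = "".join(ref_arr)
    dmap = {
        "blocks": blocks,
        "inversions": sorted(inversions),
        "n_substitutions": int(sub_pos.size),
        "n_indels": len(blocks) - 1,
    }
    return ref, dmap


def fragment(genome: str, config: SimConfig) -> tuple[Assembly, TruthTable]:
    """Cut a genome into contigs separated by deleted (physical) gaps.

    Explicit plans list ``(contig_len, gap_after)`` pairs (the last gap is
    ignored); otherwise ``n_contigs`` roughly equal contigs are cut with
    gaps drawn uniformly from ``gap_range``.  With ``overlap_bp`` set,
    zero-gap junctions are duplicated on both flanking contigs (the
    low-coverage-extension failure mode that exact overlap merging targets).
    Contigs are optionally shuffled and a random subset reverse-complemented;
    the truth table records adjacencies, true gap sizes and the genome
    order/orientation.
    """
    rng = config.rng(_OP_FRAGMENT)
    n = len(genome)
    if config.fragment_plan is not None:
        plan = [(int(c), int(g)) for c, g in config.fragment_plan]
    else:
        gaps = [int(rng.integers(config.gap_range[0], config.gap_range[1] + 1)) for _ in range(config.n_contigs - 1)]
        remaining = n - sum(gaps)
        if remaining < config.n_contigs:
            raise ValueError("fragment plan exceeds genome length")
        base = remaining // config.n_contigs
        lengths = [base] * config.n_contigs
        lengths[-1] += remaining - base * config.n_contigs
        plan = [(lengths[i], gaps[i] if i < len(gaps) else 0) for i in range(config.n_contigs)]
    if sum(c for c, _ in plan) + sum(g for _, g in plan[:-1]) > n:
        raise ValueError("fragment plan exceeds genome length")

    truth = TruthTable(genome_len=n)
    contigs: list[Contig] = []
    cursor = 0
    for i, (clen, gap) in enumerate(plan):
        cid = f"c{i + 1:04d}"
        start = cursor
        if i > 0 and config.overlap_bp and plan[i - 1][1] == 0:
            start -= config.overlap_bp  # duplicated junction
        seq = genome[start : cursor + clen]
        contigs.append(Contig(cid, seq))
        truth.contig_lengths[cid] = len(seq)
        truth.true_order_orientation.append((cid, "+"))
        if i < len(plan) - 1:
            ov = config.overlap_bp if (config.overlap_bp and gap == 0) else 0
            truth.true_adjacencies.append((cid, f"c{i + 2:04d}", gap, ov))
        cursor += clen + gap

    if config.n_rc:
        flip = set(rng.choice(len(contigs), size=min(config.n_rc, len(contigs)), replace=False).tolist())
        contigs = [
            Contig(c.id, revcomp(c.seq)) if i in flip else c for i, c in enumerate(contigs)
        ]
        truth.true_order_orientation = [
            (cid, "-" if i in flip else "+") for i, (cid, _) in enumerate(truth.true_order_orientation)
        ]
    order = list(range(len(contigs)))
    if config.shuffle:
        rng.shuffle(order)
    assembly = Assembly((contigs[i] for i in order), label="simulated_contigs")
    truth.validate()
    return assembly, truth


def build_scaffold(
    contigs: Assembly,
    truth: TruthTable,
    scaffold_id: str = "scaffold_1",
) -> tuple[Assembly, TruthTable]:
    """Join the fragmented contigs in genome order with true-size N-runs.

    Zero-size gaps produce no run.  The truth table is updated with the run
    positions and true sizes (the negative-control fixture for resizing).
    """
    by_id = {c.id: c.seq for c in contigs}
    orient = dict(truth.true_order_orientation)
    pieces: list[str] = []
    truth.true_nrun_sizes = []
    pos = 0
    order = [cid for cid, _ in truth.true_order_orientation]
    for i, cid in enumerate(order):
        seq = by_id[cid] if orient[cid] == "+" else revcomp(by_id[cid])
        pieces.append(seq)
        pos += len(seq)
        if i < len(order) - 1:
            gap = truth.true_adjacencies[i][2]
            if gap > 0:
                truth.true_nrun_sizes.append((scaffold_id, pos, gap))
                pieces.append("N" * gap)
                pos += gap
    return Assembly([Contig(scaffold_id, "".join(pieces))], label="scaffolds"), truth


def corrupt_nruns(
    scaffolds: Assembly,
    truth: TruthTable,
    rule: str = "fixed:10000",
) -> tuple[Assembly, TruthTable]:
    """Replace every N-run with a wrong-size run, keeping the truth.

    ``rule`` is ``fixed:<n>`` (every run becomes n Ns, emulating
    assembler-artifact gap sizes) or ``exact`` (sizes kept — negative
    control).  ``truth.true_nrun_sizes`` is rewritten with the run positions
    in the corrupted coordinates and the original true sizes.
    """
    from .gapclose import find_nruns

    if rule == "exact":
        return scaffolds, truth
    if not rule.startswith("fixed:"):
        raise ValueError(f"unknown corruption rule {rule!r}")
    wrong = int(rule.split(":", 1)[1])
    new_truth_runs: list[tuple[str, int, int]] = []
    out = Assembly(label=scaffolds.label)
    for scaf in scaffolds:
        runs = find_nruns({scaf.id: scaf.seq})
        pieces: list[str] = []
        cursor = 0
        new_pos = 0
        for run in runs:
            pieces.append(scaf.seq[cursor : run.start])
            new_pos += run.start - cursor
            new_truth_runs.append((scaf.id, new_pos, run.length))
            pieces.append("N" * wrong)
            new_pos += wrong
            cursor = run.start + run.length
        pieces.append(scaf.seq[cursor:])
        out.add(Contig(scaf.id, "".join(pieces)))
    truth.true_nrun_sizes = new_truth_runs
    return out, truth


def plant_features(
    genome: str,
    config: SimConfig,
    profile: ProfileModel | None = None,
    seq_id: str = "genome",
) -> tuple[str, list[GeneFeature], list[dict]]:
    """Plant non-overlapping genes and, optionally, upstream motif instances.

    Genes (uniform lengths 300-3000, random strands) are placed one per
    equal-width slot so they can never overlap and always leave room for an
    upstream box.  Motif instances sampled from the profile's column
    distributions are written 0-500 bp upstream of the starts of a random
    subset of genes, on the gene's strand.  Returns the modified genome, the
    gene features (1-based) and the truth records of planted sites.
    """
    rng = config.rng(_OP_PLANT)
    n = len(genome)
    if config.n_genes == 0:
        return genome, [], []
    slot = n // config.n_genes
    L = profile.length if profile is not None else 0
    pad = 600 + L
    if slot < 3000 + 2 * pad:
        raise ValueError("genome too short for the requested number of genes")
    genes: list[GeneFeature] = []
    for i in range(config.n_genes):
        glen = int(rng.integers(300, 3001))
        lo = i * slot + pad
        hi = (i + 1) * slot - pad - glen
        start0 = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(seq_id, start0 + 1, start0 + glen, strand, f"gene{i + 1:03d}"))

    sites: list[dict] = []
    seq = genome
    if profile is not None and config.n_motifs:
        chosen = rng.choice(len(genes), size=min(config.n_motifs, len(genes)), replace=False)
        for gi in sorted(chosen.tolist()):
            g = genes[gi]
            dist = int(rng.integers(0, 501))
            instance = profile.sample(rng)
            if g.strand == "+":
                box_end = (g.start - 1) - dist
                box_start = box_end - L
                planted = instance
            else:
                box_start = g.end + dist
                box_end = box_start + L
                planted = revcomp(instance)
            seq = seq[:box_start] + planted + seq[box_end:]
            sites.append(
                {
                    "seq_id": seq_id,
                    "start": box_start,
                    "end": box_end,
                    "strand": g.strand,
                    "distance": dist,
                    "gene": g.feature_id,
                    "instance": instance,
                }
            )
    return seq, genes, sites
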