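"""Reference-guided ordering/orientation of scaffolds and assembly congruency.

Ordering replaces whole-genome alignment with unique-k-mer median placement:
a 25-mer occurring exactly once (double-stranded) in the scaffold set and
exactly once in the reference is an unambiguous coordinate anchor.  A
scaffold longer than 1 kb with at least ``min_anchors`` anchors is placed at
the median reference coordinate of its anchors, oriented by the majority
anchor strand.

Congruency checking flags contigs of one assembly that no other assembly
supports; an assembly with a large unsupported contig is marked for culling,
the classical guard against chimeric Velvet-style misassemblies.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._kmers import unique_kmer_arrays
from .homology import ScoringScheme, build_seed_index, local_align
from .model import Assembly, Thresholds

log = logging.getLogger("draftweaver")


@dataclass
class AnchorSet:
    """Unique k-mer anchors of one scaffold onto the reference.

    Each anchor is ``(scaffold_pos, reference_id, reference_pos, strand)``
    with 0-based forward-strand start coordinates on both sides.
    """

    scaffold_id: str
    anchors: list[tuple[int, str, int, str]]
    k: int


@dataclass
class PlacementDecision:
    scaffold_id: str
    placed: bool
    reference_id: str = ""
    position: float = -1.0   # median reference coordinate of the anchors
    orientation: str = "+"
    n_anchors: int = 0
    reason_if_unplaced: str = ""


def anchor_scaffolds(
    scaffolds: Assembly | Mapping[str, str],
    reference: Assembly | Mapping[str, str],
    k: int = 25,
) -> list[AnchorSet]:
    """Anchor scaffolds to a reference via double-stranded-unique k-mers.

    A k-mer anchors only if it occurs exactly once across the whole scaffold
    set and exactly once in the reference (counting both strands; a k-mer
    equal to another's reverse complement is not unique, and N-containing
    k-mers are excluded).  Anchor strand is ``-`` when the scaffold k-mer
    matches the reverse strand of the reference.
    """
    if k < 15:
        raise ValueError("k must be >= 15 for unique anchoring")
    scaf_seqs = {c.id: c.seq for c in scaffolds} if isinstance(scaffolds, Assembly) else dict(scaffolds)
    ref_seqs = {c.id: c.seq for c in reference} if isinstance(reference, Assembly) else dict(reference)
    s_canon, s_sidx, s_pos, s_fwd, s_ids = unique_kmer_arrays(scaf_seqs, k)
    r_canon, r_sidx, r_pos, r_fwd, r_ids = unique_kmer_arrays(ref_seqs, k)
    _, ia, ib = np.intersect1d(s_canon, r_canon, assume_unique=True, return_indices=True)
    anchors: dict[str, list[tuple[int, str, int, str]]] = {sid: [] for sid in scaf_seqs}
    for si, ri in zip(ia.tolist(), ib.tolist()):
        strand = "+" if s_fwd[si] == r_fwd[ri] else "-"
        anchors[s_ids[s_sidx[si]]].append((int(s_pos[si]), r_ids[r_sidx[ri]], int(r_pos[ri]), strand))
    out = []
    for sid in scaf_seqs:
        out.append(AnchorSet(sid, sorted(anchors[sid]), k))
    log.info("anchor_scaffolds: %d anchors over %d scaffolds", sum(len(a.anchors) for a in out), len(out))
    return out


def reorder_scaffolds(
    anchorsets: Sequence[AnchorSet],
    scaffold_lengths: Mapping[str, int],
    thresholds: Thresholds | None = None,
) -> tuple[list[PlacementDecision], list[PlacementDecision]]:
    """Order and orient scaffolds by their anchor medians.

    Returns ``(ordered, unplaced)``.  Placement requires scaffold length
    strictly greater than ``min_len_reorder`` and at least ``min_anchors``
    anchors on a single reference sequence; orientation is the strict
    majority anchor strand (a 50/50 tie is unplaced).  The ordered list is
    sorted by (reference_id, position), ties broken by descending scaffold
    length then id.
    """
    th = thresholds or Thresholds()
    ordered: list[PlacementDecision] = []
    unplaced: list[PlacementDecision] = []
    for aset in anchorsets:
        sid = aset.scaffold_id
        length = scaffold_lengths[sid]
        if length <= th.min_len_reorder:
            unplaced.append(PlacementDecision(sid, False, n_anchors=len(aset.anchors),
                                              reason_if_unplaced=f"length {length} <= {th.min_len_reorder}"))
            continue
        if not aset.anchors:
            unplaced.append(PlacementDecision(sid, False, reason_if_unplaced="no anchors"))
            continue
        by_ref: dict[str, list[tuple[int, str]]] = {}
        for _spos, rid, rpos, strand in aset.anchors:
            by_ref.setdefault(rid, []).append((rpos, strand))
        rid = max(by_ref, key=lambda r: (len(by_ref[r]), r))
        anchors = by_ref[rid]
        if len(anchors) < th.min_anchors:
            unplaced.append(PlacementDecision(sid, False, n_anchors=len(anchors),
                                              reason_if_unplaced=f"only {len(anchors)} anchors (< {th.min_anchors})"))
            continue
        plus = sum(1 for _, s in anchors if s == "+")
        minus = len(anchors) - plus
        if plus == minus:
            unplaced.append(PlacementDecision(sid, False, n_anchors=len(anchors),
                                              reason_if_unplaced="orientation tie"))
            continue
        ordered.append(
            PlacementDecision(
                sid,
                True,
                reference_id=rid,
                position=float(statistics.median(p for p, _ in anchors)),
                orientation="+" if plus > minus else "-",
                n_anchors=len(anchors),
            )
        )
    ordered.sort(key=lambda d: (d.reference_id, d.position, -scaffold_lengths[d.scaffold_id], d.scaffold_id))
    log.info("reorder_scaffolds: %d placed, %d unplaced", len(ordered), len(unplaced))
    return ordered, unplaced


def reference_adjacency_pairs(ordered: Sequence[PlacementDecision]) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Consecutive (id, orientation) pairs of the ordered layout, per reference."""
    pairs = []
    for a, b in zip(ordered, ordered[1:]):
        if a.reference_id == b.reference_id:
            pairs.append(((a.scaffold_id, a.orientation), (b.scaffold_id, b.orientation)))
    return pairs


# ---------------------------------------------------------------------------
# congruency


@dataclass
class ContigSupport:
    assembly_label: str
    contig_id: str
    length: int
    supported: bool
    best_support_fraction: float
    supporting_assembly: str = ""


@dataclass
class CongruencyReport:
    contigs: list[ContigSupport] = field(default_factory=list)
    verdicts: dict[str, str] = field(default_factory=dict)          # label -> keep | cull
    offending: dict[str, list[str]] = field(default_factory=dict)  # label -> contig ids


def congruency_report(
    assemblies: Sequence[Assembly],
    large_cutoff: int = 10000,
    min_cov: float = 0.95,
    min_ident: float = 0.99,
    scoring: ScoringScheme | None = None,
    tile: int = 1000,
) -> CongruencyReport:
    """Mutual-support check between independent assemblies of the same data.

    A contig is supported when at least ``min_cov`` of its length is covered
    by local alignments of identity at least ``min_ident`` to a *single*
    contig of at least one *other* assembly — per-contig support is what
    makes a chimera (two distant regions concatenated) detectable, since no
    honest contig elsewhere contains both of its halves.  An assembly is
    marked ``cull`` when any of its contigs of at least ``large_cutoff`` bp
    is unsupported by every other assembly.  Contigs are tiled into
    ``tile``-bp query chunks and the covered fraction is the union of tile
    hit intervals against each candidate supporting contig.
    """
    if len(assemblies) < 2:
        raise ValueError("congruency requires at least 2 assemblies")
    labels = [a.label or f"assembly_{i}" for i, a in enumerate(assemblies)]
    if len(set(labels)) != len(labels):
        raise ValueError("assemblies must have distinct labels")
    indexes = [build_seed_index(a) for a in assemblies]
    report = CongruencyReport(verdicts={lab: "keep" for lab in labels}, offending={lab: [] for lab in labels})
    for i, asm in enumerate(assemblies):
        for contig in asm:
            best_frac, best_lab = 0.0, ""
            for j, other_index in enumerate(indexes):
                if j == i:
                    continue
                frac = _coverage_fraction(contig.seq, other_index, min_ident, scoring, tile)
                if frac > best_frac:
                    best_frac, best_lab = frac, labels[j]
            supported = best_frac >= min_cov
            report.contigs.append(ContigSupport(labels[i], contig.id, len(contig), supported, best_frac, best_lab))
            if not supported and len(contig) >= large_cutoff:
                report.verdicts[labels[i]] = "cull"
                report.offending[labels[i]].append(contig.id)
    return report


def _coverage_fraction(seq: str, index, min_ident: float, scoring, tile: int) -> float:
    """Best covered fraction of *seq* by hits to any single subject contig."""
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for off in range(0, len(seq), tile):
        chunk = seq[off : off + tile]
        if len(chunk) < index.word_size:
            continue
        for h in local_align(chunk, index, scoring=scoring, max_evalue=1e-3):
            if h.identity >= min_ident:
                by_subject.setdefault(h.subject_id, []).append((off + h.q_start, off + h.q_end))
    best = 0.0
    for covered in by_subject.values():
        covered.sort()
        total = 0
        cur_s, cur_e = covered[0]
        for s, e in covered[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        best = max(best, total / len(seq))
    return best
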