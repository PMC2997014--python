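"""Gap-closure logic: contig-end extraction, reference-mediated gap candidates,
overlap and shared-gene joins, join application, and N-run resizing.

The procedure mirrors the classical reference-assisted improvement of a draft
bacterial assembly: 300 bp ends of every contig longer than 1 kb are aligned
to one or more reference genomes; two ends hitting the same reference
sequence no more than 1 kb apart, facing each other, are evidence that their
contigs flank a physical gap.  Oversized N-runs (longer than 300) are resized
to the reference-implied distance between their flanks, or capped at 300 —
the maximum insert of the paired-end library — when the flanks cannot be
placed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .homology import (
    AlignmentHit,
    ScoringScheme,
    SeedIndex,
    build_seed_index,
    is_repeat_ambiguous,
    local_align,
)
from .model import (
    Assembly,
    Contig,
    ContigPart,
    GapRecord,
    GeneFeature,
    Scaffold,
    Thresholds,
    revcomp,
)

log = logging.getLogger("draftweaver")

_NRUN = re.compile(r"[Nn]+")


@dataclass(frozen=True)
class ContigEnd:
    """A terminal stretch of a contig, stored in contig-forward orientation."""

    contig_id: str
    side: str  # left | right
    seq: str
    start: int  # source interval on the contig, 0-based half-open
    end: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.contig_id, self.side)


@dataclass
class GapCandidate:
    """Evidence that two contig ends flank the same physical gap."""

    end_a: ContigEnd
    end_b: ContigEnd
    reference_id: str
    ref_interval_a: tuple[int, int]
    ref_interval_b: tuple[int, int]
    strand_a: str
    strand_b: str
    separation: int          # signed inner-boundary distance on the reference
    implied_gap: int         # >= 0; see `overlap`
    overlap: bool            # True when the implied distance was negative
    evalue_a: float
    evalue_b: float
    orientation_consistent: bool = True


@dataclass
class JoinProposal:
    """A claim that two contig ends are adjacent, with its evidence class."""

    kind: str                 # overlap_merge | shared_gene | reference_adjacency
    contig_a: str
    side_a: str
    contig_b: str
    side_b: str
    score: float
    gap: Optional[GapRecord] = None
    merge_overlap: int = 0    # exact duplicated-junction length for overlap_merge
    evidence: str = ""

    RANK = {"overlap_merge": 3, "shared_gene": 2, "reference_adjacency": 1}

    def __post_init__(self) -> None:
        if self.kind not in self.RANK:
            raise ValueError(f"unknown join kind {self.kind!r}")
        if self.kind == "overlap_merge":
            if self.gap is not None:
                raise ValueError("overlap_merge must not carry a gap record")
            if self.merge_overlap < 1:
                raise ValueError("overlap_merge needs a positive overlap")
        elif self.gap is None or self.gap.n_count < 1:
            raise ValueError(f"{self.kind} join requires a gap record with n_count >= 1")


@dataclass(frozen=True)
class NRun:
    """A maximal run of N characters inside a scaffold sequence."""

    scaffold_id: str
    start: int  # 0-based
    length: int


# ---------------------------------------------------------------------------
# end extraction and candidate discovery


def extract_ends(assembly: Assembly, thresholds: Thresholds | None = None) -> list[ContigEnd]:
    """300 bp (``end_len``) ends of every contig strictly longer than 1 kb."""
    th = thresholds or Thresholds()
    ends: list[ContigEnd] = []
    for contig in assembly:
        n = len(contig)
        if n <= th.min_contig_for_ends:
            continue
        span = min(th.end_len, n)
        ends.append(ContigEnd(contig.id, "left", contig.seq[:span], 0, span))
        ends.append(ContigEnd(contig.id, "right", contig.seq[n - span :], n - span, n))
    log.info("extract_ends: %d ends from %d contigs", len(ends), len(assembly))
    return ends


def _gap_direction(side: str, strand: str) -> int:
    """Reference direction (+1 right / -1 left) in which the gap lies
    beyond this end's alignment."""
    return 1 if (side == "right") == (strand == "+") else -1


def _tip_overhang(end_side: str, hit: AlignmentHit, end_len: int) -> int:
    """Unaligned bases between the alignment and the gap-facing tip."""
    return end_len - hit.q_end if end_side == "right" else hit.q_start


def best_end_hits(
    ends: Sequence[ContigEnd],
    index: SeedIndex,
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
) -> dict[tuple[str, str], AlignmentHit]:
    """Best qualifying reference hit per end; repeat-ambiguous ends skipped."""
    th = thresholds or Thresholds()
    best: dict[tuple[str, str], AlignmentHit] = {}
    for end in ends:
        hits = local_align(end.seq, index, scoring=scoring, max_evalue=th.max_evalue, query_id=f"{end.contig_id}:{end.side}")
        if not hits:
            continue
        if is_repeat_ambiguous(hits, th.max_hit_regions):
            log.info("best_end_hits: %s:%s is repeat-ambiguous, skipped", end.contig_id, end.side)
            continue
        best[end.key] = hits[0]
    return best


def find_gap_candidates(
    ends: Sequence[ContigEnd],
    reference_db: SeedIndex | Assembly | Mapping[str, str],
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
) -> list[GapCandidate]:
    """Pair contig ends whose best hits face each other on the same reference.

    A pair qualifies when both ends have a non-ambiguous best hit with
    E-value at most ``max_evalue`` on the same reference sequence, the two
    alignments face each other with inner-boundary separation of at most
    ``max_ref_separation`` (in absolute value), and the ends belong to
    different contigs.  The implied gap subtracts the unaligned tip overhang
    of each end; a negative implied distance is floored at 0 and flagged as
    an overlap.
    """
    th = thresholds or Thresholds()
    index = reference_db if isinstance(reference_db, SeedIndex) else build_seed_index(reference_db, th.word_size)
    hits = best_end_hits(ends, index, th, scoring)
    placed = [e for e in ends if e.key in hits]
    candidates: list[GapCandidate] = []
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            ea, eb = placed[i], placed[j]
            if ea.contig_id == eb.contig_id:
                continue
            ha, hb = hits[ea.key], hits[eb.key]
            if ha.subject_id != hb.subject_id:
                continue
            # leftmost on the reference first
            if ha.s_start + ha.s_end > hb.s_start + hb.s_end:
                ea, eb, ha, hb = eb, ea, hb, ha
            separation = hb.s_start - ha.s_end
            if abs(separation) > th.max_ref_separation:
                continue
            facing = _gap_direction(ea.side, ha.strand) == 1 and _gap_direction(eb.side, hb.strand) == -1
            if not facing:
                log.info(
                    "find_gap_candidates: %s:%s / %s:%s share %s but orientations are inconsistent",
                    ea.contig_id, ea.side, eb.contig_id, eb.side, ha.subject_id,
                )
                continue
            implied = separation - _tip_overhang(ea.side, ha, len(ea.seq)) - _tip_overhang(eb.side, hb, len(eb.seq))
            candidates.append(
                GapCandidate(
                    end_a=ea,
                    end_b=eb,
                    reference_id=ha.subject_id,
                    ref_interval_a=(ha.s_start, ha.s_end),
                    ref_interval_b=(hb.s_start, hb.s_end),
                    strand_a=ha.strand,
                    strand_b=hb.strand,
                    separation=separation,
                    implied_gap=max(0, implied),
                    overlap=implied < 0,
                    evalue_a=ha.evalue,
                    evalue_b=hb.evalue,
                )
            )
    candidates.sort(key=lambda c: (max(c.evalue_a, c.evalue_b), c.end_a.contig_id, c.end_b.contig_id))
    log.info("find_gap_candidates: %d candidates from %d placed ends", len(candidates), len(placed))
    return candidates


def candidates_to_proposals(candidates: Iterable[GapCandidate]) -> list[JoinProposal]:
    """Convert gap candidates into reference_adjacency join proposals."""
    out = []
    for c in candidates:
        out.append(
            JoinProposal(
                kind="reference_adjacency",
                contig_a=c.end_a.contig_id,
                side_a=c.end_a.side,
                contig_b=c.end_b.contig_id,
                side_b=c.end_b.side,
                score=-max(c.evalue_a, c.evalue_b),
                gap=GapRecord(max(1, c.implied_gap), kind="physical_gap_closed",
                              evidence=f"ref={c.reference_id} sep={c.separation}"),
                evidence=c.reference_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# overlap merging


def _oriented(seq: str, orientation: str) -> str:
    return seq if orientation == "+" else revcomp(seq)


def _max_exact_overlap(a: str, b: str, min_overlap: int) -> int:
    """Length of the maximal exact suffix(a)/prefix(b) overlap >= min_overlap, else 0."""
    for L in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return 0


def merge_overlaps(
    assembly: Assembly,
    layout_adjacency: Iterable,
    thresholds: Thresholds | None = None,
) -> list[JoinProposal]:
    """Propose exact suffix-prefix merges for reference-adjacent contig pairs.

    ``layout_adjacency`` lists pairs that long-range reference synteny puts
    next to each other, either as ``(id_a, id_b)`` (both orientations of each
    contig are tried) or ``((id_a, ori_a), (id_b, ori_b))``.  A merge is
    proposed at the maximal exact overlap of at least ``min_overlap`` (15)
    bases — a single mismatch disqualifies an overlap length.
    """
    th = thresholds or Thresholds()
    proposals: list[JoinProposal] = []
    for pair in layout_adjacency:
        (ida, oa), (idb, ob) = [p if isinstance(p, tuple) else (p, None) for p in pair]
        combos = [(x, y) for x in ((oa,) if oa else "+-") for y in ((ob,) if ob else "+-")]
        best = 0
        best_combo = None
        for x, y in combos:
            L = _max_exact_overlap(_oriented(assembly[ida].seq, x), _oriented(assembly[idb].seq, y), th.min_overlap)
            if L > best:
                best, best_combo = L, (x, y)
        if not best:
            continue
        x, y = best_combo
        proposals.append(
            JoinProposal(
                kind="overlap_merge",
                contig_a=ida,
                side_a="right" if x == "+" else "left",
                contig_b=idb,
                side_b="left" if y == "+" else "right",
                score=float(best),
                merge_overlap=best,
                evidence=f"exact_overlap={best}",
            )
        )
    log.info("merge_overlaps: %d proposals", len(proposals))
    return proposals


# ---------------------------------------------------------------------------
# shared-gene pairing


def pair_by_shared_gene(
    ends: Sequence[ContigEnd],
    reference_genes: Sequence[GeneFeature],
    reference_db: SeedIndex | Assembly | Mapping[str, str],
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
) -> list[JoinProposal]:
    """Join ends whose hits cover disjoint portions of the same reference gene.

    The proposed gap is the number of unaccounted gene bases between the two
    hit intervals (minimum 1).
    """
    th = thresholds or Thresholds()
    index = reference_db if isinstance(reference_db, SeedIndex) else build_seed_index(reference_db, th.word_size)
    hits = best_end_hits(ends, index, th, scoring)
    placed = [e for e in ends if e.key in hits]
    proposals: list[JoinProposal] = []
    for gene in reference_genes:
        g_lo, g_hi = gene.start - 1, gene.end  # 0-based half-open
        on_gene = []
        for e in placed:
            h = hits[e.key]
            if h.subject_id != gene.seq_id:
                continue
            lo, hi = max(h.s_start, g_lo), min(h.s_end, g_hi)
            if lo < hi:
                on_gene.append((e, h, lo, hi))
        for i in range(len(on_gene)):
            for j in range(i + 1, len(on_gene)):
                (ea, ha, la, ra), (eb, hb, lb, rb) = on_gene[i], on_gene[j]
                if ea.contig_id == eb.contig_id:
                    continue
                if la + ra > lb + rb:
                    (ea, ha, la, ra), (eb, hb, lb, rb) = (eb, hb, lb, rb), (ea, ha, la, ra)
                if lb < ra:  # overlapping portions of the gene
                    continue
                facing = _gap_direction(ea.side, ha.strand) == 1 and _gap_direction(eb.side, hb.strand) == -1
                if not facing:
                    continue
                proposals.append(
                    JoinProposal(
                        kind="shared_gene",
                        contig_a=ea.contig_id,
                        side_a=ea.side,
                        contig_b=eb.contig_id,
                        side_b=eb.side,
                        score=float(min(ha.score, hb.score)),
                        gap=GapRecord(max(1, lb - ra), kind="physical_gap_closed",
                                      evidence=f"gene={gene.feature_id}"),
                        evidence=gene.feature_id,
                    )
                )
    log.info("pair_by_shared_gene: %d proposals", len(proposals))
    return proposals


# ---------------------------------------------------------------------------
# join application


@dataclass
class JoinReport:
    accepted: list[JoinProposal] = field(default_factory=list)
    rejected: list[tuple[JoinProposal, str]] = field(default_factory=list)


def apply_joins(assembly: Assembly, proposals: Sequence[JoinProposal]) -> tuple[list[Scaffold], JoinReport]:
    """Greedily apply join proposals and emit scaffolds.

    Each contig end is consumed at most once.  Conflicts are resolved by
    evidence rank (overlap_merge > shared_gene > reference_adjacency), then
    by score, then lexicographically; an edge that would close a cycle is
    rejected, which breaks every cycle at its lowest-ranked edge.
    """
    for p in proposals:
        for cid in (p.contig_a, p.contig_b):
            if cid not in assembly:
                raise ValueError(f"join proposal references unknown contig {cid!r}")

    parent: dict[str, str] = {cid: cid for cid in assembly.ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ordered = sorted(
        proposals,
        key=lambda p: (-p.RANK[p.kind], -p.score, p.contig_a, p.contig_b, p.side_a, p.side_b),
    )
    used: set[tuple[str, str]] = set()
    adjacency: dict[tuple[str, str], tuple[str, str, JoinProposal]] = {}
    report = JoinReport()
    for p in ordered:
        ka, kb = (p.contig_a, p.side_a), (p.contig_b, p.side_b)
        if ka in used or kb in used:
            report.rejected.append((p, "end already consumed by a higher-ranked join"))
            continue
        if find(p.contig_a) == find(p.contig_b):
            report.rejected.append((p, "would close a cycle"))
            continue
        used.update((ka, kb))
        adjacency[ka] = (p.contig_b, p.side_b, p)
        adjacency[kb] = (p.contig_a, p.side_a, p)
        parent[find(p.contig_a)] = find(p.contig_b)
        report.accepted.append(p)

    # assemble chains into scaffolds
    components: dict[str, list[str]] = {}
    for cid in assembly.ids:
        components.setdefault(find(cid), []).append(cid)
    scaffolds: list[Scaffold] = []
    for idx, members in enumerate(sorted(components.values(), key=min), start=1):
        sid = f"scaffold_{idx:05d}"
        if len(members) == 1:
            scaffolds.append(Scaffold(sid, [ContigPart(members[0], "+")]))
            continue
        terminals = sorted(
            cid for cid in members
            if (cid, "left") not in adjacency or (cid, "right") not in adjacency
        )
        start = terminals[0]
        orientation = "+" if (start, "right") in adjacency else "-"
        parts: list = []
        cid, ori = start, orientation
        entering_trim = 0
        while True:
            contig_len = len(assembly[cid])
            part = ContigPart(cid, ori)
            if entering_trim:
                if ori == "+":
                    part = ContigPart(cid, ori, start=entering_trim)
                else:
                    part = ContigPart(cid, ori, end=contig_len - entering_trim)
            parts.append(part)
            exit_end = "right" if ori == "+" else "left"
            nxt = adjacency.get((cid, exit_end))
            if nxt is None:
                break
            ncid, nside, prop = nxt
            if prop.kind == "overlap_merge":
                entering_trim = prop.merge_overlap
            else:
                parts.append(GapRecord(prop.gap.n_count, prop.gap.kind, prop.gap.evidence))
                entering_trim = 0
            cid, ori = ncid, "+" if nside == "left" else "-"
        scaffolds.append(Scaffold(sid, parts))
    log.info("apply_joins: %d accepted, %d rejected, %d scaffolds", len(report.accepted), len(report.rejected), len(scaffolds))
    return scaffolds, report


# ---------------------------------------------------------------------------
# N-run handling


def find_nruns(scaffolds: Assembly | Mapping[str, str]) -> list[NRun]:
    """Maximal runs of N (case-insensitive) in each scaffold sequence."""
    seqs = {c.id: c.seq for c in scaffolds} if isinstance(scaffolds, Assembly) else dict(scaffolds)
    runs = []
    for sid, seq in seqs.items():
        for m in _NRUN.finditer(seq):
            runs.append(NRun(sid, m.start(), m.end() - m.start()))
    return runs


@dataclass
class ResizeRecord:
    scaffold_id: str
    start: int
    old_n: int
    new_n: int
    rule: str  # reference | cap | boundary | untouched
    overlap: bool = False


def resize_nruns(
    scaffolds: Assembly | Mapping[str, str],
    reference_db: SeedIndex | Assembly | Mapping[str, str],
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
) -> tuple[Assembly, list[ResizeRecord]]:
    """Resize oversized N-runs against a reference.

    Only runs strictly longer than ``nrun_min_to_touch`` (300) are modified.
    For each, the 300 bp flanks on either side are aligned to the reference:
    when both flanks have qualifying, non-ambiguous hits on the same
    reference sequence, facing each other, separated by at most
    ``resize_max_separation``, the run is set to the reference-implied inner
    distance (floored at 1 with an overlap flag); otherwise the run is
    reduced to exactly ``nrun_cap`` (300) Ns.  A run flush against a scaffold
    boundary is left unchanged with a warning.
    """
    th = thresholds or Thresholds()
    index = reference_db if isinstance(reference_db, SeedIndex) else build_seed_index(reference_db, th.word_size)
    seqs = {c.id: c.seq for c in scaffolds} if isinstance(scaffolds, Assembly) else dict(scaffolds)
    report: list[ResizeRecord] = []
    out = Assembly(label="resized")
    for sid, seq in seqs.items():
        pieces: list[str] = []
        cursor = 0
        for run in find_nruns({sid: seq}):
            new_n = run.length
            rule = "untouched"
            overlap = False
            if run.length > th.nrun_min_to_touch:
                left = seq[max(0, run.start - th.end_len) : run.start]
                right = seq[run.start + run.length : run.start + run.length + th.end_len]
                if not left or not right:
                    rule = "boundary"
                    log.warning("resize_nruns: %s run at %d flush against a boundary, unchanged", sid, run.start)
                else:
                    new_n, rule, overlap = _resize_one(left, right, index, th, scoring)
            if rule not in ("untouched", "boundary"):
                report.append(ResizeRecord(sid, run.start, run.length, new_n, rule, overlap))
            else:
                report.append(ResizeRecord(sid, run.start, run.length, run.length, rule, overlap))
                new_n = run.length
            pieces.append(seq[cursor : run.start])
            pieces.append("N" * new_n)
            cursor = run.start + run.length
        pieces.append(seq[cursor:])
        out.add(Contig(sid, "".join(pieces)))
    log.info("resize_nruns: %d runs processed", len(report))
    return out, report


def _resize_one(left: str, right: str, index: SeedIndex, th: Thresholds, scoring) -> tuple[int, str, bool]:
    ends = [
        ContigEnd("flank", "right", left, 0, len(left)),   # gap lies right of the left flank
        ContigEnd("flank2", "left", right, 0, len(right)),
    ]
    hits = best_end_hits(ends, index, th, scoring)
    ha, hb = hits.get(("flank", "right")), hits.get(("flank2", "left"))
    if ha is None or hb is None or ha.subject_id != hb.subject_id:
        return th.nrun_cap, "cap", False
    if ha.s_start + ha.s_end > hb.s_start + hb.s_end:
        # region maps reverse-complemented: the right flank is leftmost on the reference
        ha, hb = hb, ha
        ea, eb = ends[1], ends[0]
    else:
        ea, eb = ends[0], ends[1]
    facing = _gap_direction(ea.side, ha.strand) == 1 and _gap_direction(eb.side, hb.strand) == -1
    separation = hb.s_start - ha.s_end
    if not facing or abs(separation) > th.resize_max_separation:
        return th.nrun_cap, "cap", False
    implied = separation - _tip_overhang(ea.side, ha, len(ea.seq)) - _tip_overhang(eb.side, hb, len(eb.seq))
    if implied < 1:
        return 1, "reference", True
    return implied, "reference", False
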