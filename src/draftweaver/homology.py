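"""Seeded local nucleotide similarity search with Karlin-Altschul E-values.

This is the engine behind gap-candidate discovery, N-run resizing and
shared-gene pairing: an exact inverted word index over the subject database,
X-drop ungapped seed extension, then a banded affine-gap Smith-Waterman
around surviving seed clusters.  E-values use the ungapped Karlin-Altschul
form ``E = K * m * n * exp(-lambda * S)`` as an approximation for gapped
scores; only the downstream cutoff (0.02 by default) matters to consumers.

:func:`smith_waterman` is the independent full-dynamic-program oracle
(Biopython's PairwiseAligner) used to validate the heuristic in the test
suite; it is never called by the search path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import banded_sw, xdrop_ungapped
from ._kmers import encode
from .model import Assembly, revcomp

log = logging.getLogger("draftweaver")


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring with affine gaps and Karlin-Altschul parameters.

    A gap of length L costs ``-(gap_open) - L * (-gap_extend)`` score units,
    i.e. 5 + 2L with the defaults, mirroring common nucleotide-search
    defaults.  ``lam`` is per score unit.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    K: float = 0.46
    xdrop: int = 20
    band: int = 32

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def gap_first(self) -> int:
        """Cost of the first gap base (positive): open + extend."""
        return -(self.gap_open + self.gap_extend)

    @property
    def gap_ext(self) -> int:
        return -self.gap_extend


@dataclass(frozen=True)
class AlignmentHit:
    """A local similarity match on the forward strands of both sequences.

    ``strand`` is the strand of the subject relative to the query; intervals
    are 0-based half-open regardless of strand.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    score: int
    evalue: float
    mismatches: int = 0
    gap_opens: int = 0
    length: int = 0


class SeedIndex:
    """Exact inverted index of forward-strand words of a subject database.

    Words containing N are never indexed.  Minus-strand matches are found by
    querying with the reverse complement of the query, which is equivalent to
    indexing both strands.
    """

    def __init__(self, subjects: Mapping[str, str], word_size: int = 11):
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.word_size = word_size
        self.subjects = dict(subjects)
        self.db_len = sum(len(s) for s in self.subjects.values())
        self._codes = {sid: encode(seq) for sid, seq in self.subjects.items()}
        self.words: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.subjects.items():
            for i in range(len(seq) - word_size + 1):
                w = seq[i : i + word_size]
                if "N" in w:
                    continue
                self.words.setdefault(w, []).append((sid, i))

    def codes(self, sid: str) -> np.ndarray:
        return self._codes[sid]


def build_seed_index(subjects: Assembly | Mapping[str, str], word_size: int = 11) -> SeedIndex:
    """Build a :class:`SeedIndex` from an Assembly or an id->sequence mapping."""
    if isinstance(subjects, Assembly):
        subjects = {c.id: c.seq for c in subjects}
    return SeedIndex(subjects, word_size=word_size)


def evalue(score: float, query_len: int, db_len: int, scoring: ScoringScheme) -> float:
    """Karlin-Altschul expectation ``K * m * n * exp(-lambda * S)``."""
    if min(query_len, db_len) <= 0:
        raise ValueError("query_len and db_len must be positive")
    return scoring.K * query_len * db_len * math.exp(-scoring.lam * score)


def _cluster_seeds(seeds: list[tuple[int, int]], band: int, qlen: int) -> list[list[tuple[int, int]]]:
    """Group (diag, spos) seeds into clusters of nearby diagonals/positions."""
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    for d, spos in seeds:
        placed = False
        for cl in clusters:
            d0, s0 = cl[-1]
            if abs(d - d0) <= band and abs(spos - s0) <= qlen + 2 * band:
                cl.append((d, spos))
                placed = True
                break
        if not placed:
            clusters.append([(d, spos)])
    return clusters


def local_align(
    query: str,
    index: SeedIndex,
    scoring: ScoringScheme | None = None,
    max_evalue: float = 0.02,
    query_id: str = "query",
    min_ungapped: int | None = None,
) -> list[AlignmentHit]:
    """Seeded banded local alignment of *query* against the indexed subjects.

    Pipeline: exact word seeding on both strands, X-drop ungapped extension
    of each seed cluster (the default survivor cutoff keeps every exact-seed
    cluster), banded gapped Smith-Waterman around the cluster's diagonals,
    merge of overlapping same-strand hits keeping the best score, E-value
    filtering, and a deterministic sort by ascending E-value then descending
    score.
    """
    scoring = scoring or ScoringScheme()
    w = index.word_size
    qlen = len(query)
    if qlen < w:
        log.warning("local_align: query %r shorter than word size; no hits", query_id)
        return []
    if min_ungapped is None:
        min_ungapped = w * scoring.match
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query.upper()), ("-", revcomp(query.upper()))):
        qcodes = encode(qseq)
        per_subject: dict[str, list[tuple[int, int, int]]] = {}
        for i in range(qlen - w + 1):
            word = qseq[i : i + w]
            if "N" in word:
                continue
            for sid, spos in index.words.get(word, ()):
                per_subject.setdefault(sid, []).append((spos - i, spos, i))
        for sid, raw in per_subject.items():
            scodes = index.codes(sid)
            n = len(scodes)
            clusters = _cluster_seeds([(d, s) for d, s, _ in raw], scoring.band, qlen)
            qpos_by_seed = {(d, s): q for d, s, q in raw}
            for cl in clusters:
                best_ungapped = 0
                for d, spos in cl:
                    qpos = qpos_by_seed[(d, spos)]
                    sc, _, _ = xdrop_ungapped(qcodes, scodes, qpos, spos, w, scoring.match, scoring.mismatch, scoring.xdrop)
                    best_ungapped = max(best_ungapped, sc)
                if best_ungapped < min_ungapped:
                    continue
                s_min = min(s for _, s in cl)
                s_max = max(s for _, s in cl)
                win_lo = max(0, s_min - qlen - scoring.band)
                win_hi = min(n, s_max + w + qlen + scoring.band)
                dlo = min(d for d, _ in cl) - win_lo - scoring.band
                dhi = max(d for d, _ in cl) - win_lo + scoring.band
                # keep the band width bounded even for pathological seed chains
                dhi = min(dhi, dlo + qlen + 4 * scoring.band)
                (score, qs, qe, ss, se, nmatch, nmm, ngap, alen) = banded_sw(
                    qcodes,
                    scodes[win_lo:win_hi],
                    scoring.match,
                    scoring.mismatch,
                    scoring.gap_first,
                    scoring.gap_ext,
                    dlo,
                    dhi,
                )
                if score <= 0:
                    continue
                s_start, s_end = ss + win_lo, se + win_lo
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        subject_id=sid,
                        q_start=qs,
                        q_end=qe,
                        s_start=s_start,
                        s_end=s_end,
                        strand=strand,
                        identity=nmatch / alen if alen else 0.0,
                        score=int(score),
                        evalue=evalue(score, qlen, index.db_len, scoring),
                        mismatches=nmm,
                        gap_opens=ngap,
                        length=alen,
                    )
                )
    hits = _merge_overlapping(hits)
    hits = [h for h in hits if h.evalue <= max_evalue]
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id, h.s_start))
    return hits


def _merge_overlapping(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose subject interval overlaps a better same-strand hit."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.evalue, h.subject_id, h.s_start)):
        redundant = any(
            k.subject_id == h.subject_id
            and k.strand == h.strand
            and h.s_start < k.s_end
            and k.s_start < h.s_end
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


def distinct_subject_regions(hits: Sequence[AlignmentHit], merge_gap: int = 100) -> int:
    """Number of distinct subject regions the hits fall into (strand-blind)."""
    regions = 0
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append((h.s_start, h.s_end))
    for ivs in by_subject.values():
        ivs.sort()
        end = -(10**18)
        for s, e in ivs:
            if s > end + merge_gap:
                regions += 1
            end = max(end, e)
    return regions


def is_repeat_ambiguous(hits: Sequence[AlignmentHit], max_regions: int = 5) -> bool:
    """Repeat guard: significant hits scattered over many subject regions.

    The closure procedure assumes near-unique placements; a query hitting
    more than ``max_regions`` distinct regions must not seed joins.
    """
    return distinct_subject_regions(hits) > max_regions


def smith_waterman(a: str, b: str, scoring: ScoringScheme | None = None):
    """Full O(|a||b|) optimal local alignment (test oracle).

    Backed by Biopython's PairwiseAligner in local mode with the same affine
    costs as the heuristic.  Returns ``(score, (q_start, q_end, s_start,
    s_end))``; the intervals are None when the best score is 0.  Use on
    sequences of at most a few kb.
    """
    from Bio import Align

    scoring = scoring or ScoringScheme()
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_first
    aligner.extend_gap_score = -scoring.gap_ext
    score = aligner.score(a, b)
    if score <= 0:
        return 0, None
    aln = aligner.align(a, b)[0]
    q_blocks, s_blocks = aln.aligned[0], aln.aligned[1]
    intervals = (int(q_blocks[0][0]), int(q_blocks[-1][1]), int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return int(score), intervals


def hits_to_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """12-column tab-separated export, 1-based inclusive.

    Minus-strand hits follow the usual convention of a reversed subject
    interval (s_start > s_end).
    """
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity:.2f}\t{h.length}\t{h.mismatches}"
                f"\t{h.gap_opens}\t{h.q_start + 1}\t{h.q_end}\t{ss}\t{se}\t{h.evalue:.3g}\t{h.score}\n"
            )
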