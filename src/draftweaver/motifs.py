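"""Promoter-box profile training and genome scanning.

The model is an ungapped position log-odds profile (in bits, against an
explicit background of mononucleotide frequencies) trained from a gapped
alignment of confirmed boxes — the hrp-box recognized by HrpL-family sigma
factors being the motivating case.  Scanning scores every window on both
strands and keeps hits above a bit threshold; a biological filter then
retains only boxes lying within a fixed distance upstream of a CDS start on
the same strand, the configuration in which such promoter boxes act.

Absolute bit values depend on the null model and are not comparable across
tools; only the relative threshold semantics are portable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from ._kmers import encode
from .model import Assembly, GeneFeature, revcomp

log = logging.getLogger("draftweaver")

_BASES = "ACGT"


@dataclass
class MotifAlignment:
    """Equal-length aligned box sequences over {A,C,G,T,-}."""

    sequences: list[str]
    name: str = "motif"

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("motif alignment needs at least 2 sequences")
        self.sequences = [s.upper() for s in self.sequences]
        width = len(self.sequences[0])
        if any(len(s) != width for s in self.sequences):
            raise ValueError("aligned sequences must have equal length")
        if any(set(s) - set("ACGT-") for s in self.sequences):
            raise ValueError("alignment characters must be in {A,C,G,T,-}")
        for col in range(width):
            if all(s[col] == "-" for s in self.sequences):
                raise ValueError(f"column {col} is all gaps")


@dataclass
class ProfileModel:
    """Position log-odds profile in bits."""

    length: int
    log_odds: np.ndarray       # (length, 4) bits
    probabilities: np.ndarray  # (length, 4) column base probabilities
    background: dict[str, float]
    pseudocount: float
    name: str = "motif"

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one motif instance from the per-column distributions."""
        return "".join(
            _BASES[rng.choice(4, p=self.probabilities[i] / self.probabilities[i].sum())]
            for i in range(self.length)
        )


@dataclass
class MotifHit:
    seq_id: str
    start: int   # 0-based half-open genome coordinates of the box
    end: int
    strand: str
    bits: float
    nearest_cds: Optional[str] = None
    distance: Optional[int] = None


def genome_background(genome) -> dict[str, float]:
    """Mononucleotide frequencies of a genome (N excluded)."""
    seq = "".join(c.seq for c in genome) if isinstance(genome, Assembly) else genome
    counts = {b: seq.count(b) for b in _BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return {b: c / total for b, c in counts.items()}


def train_profile(
    alignment: MotifAlignment,
    pseudocount: float = 0.5,
    background: Mapping[str, float] | None = None,
) -> ProfileModel:
    """Train a position log-odds profile from an aligned box set.

    Column probabilities are ``(count + pseudocount) / (n_nongap + 4 *
    pseudocount)``; log-odds are in bits against the background (uniform by
    default; in practice the target genome's mononucleotide frequencies).
    Columns that are majority-gap are dropped with a log message.
    """
    bg = dict(background) if background else {b: 0.25 for b in _BASES}
    if abs(sum(bg.values()) - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    n_seqs = len(alignment.sequences)
    width = len(alignment.sequences[0])
    kept_probs = []
    dropped = 0
    for col in range(width):
        chars = [s[col] for s in alignment.sequences]
        n_gap = chars.count("-")
        if n_gap * 2 > n_seqs:
            dropped += 1
            continue
        n_nongap = n_seqs - n_gap
        probs = np.array(
            [(chars.count(b) + pseudocount) / (n_nongap + 4 * pseudocount) for b in _BASES]
        )
        kept_probs.append(probs)
    if dropped:
        log.info("train_profile: dropped %d majority-gap columns", dropped)
    probabilities = np.vstack(kept_probs)
    bg_vec = np.array([bg[b] for b in _BASES])
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probabilities / bg_vec)
    return ProfileModel(len(kept_probs), log_odds, probabilities, bg, pseudocount, name=alignment.name)


def _window_scores(seq: str, model: ProfileModel) -> np.ndarray:
    """Score of every forward window; -inf for windows containing N."""
    codes = encode(seq)
    L = model.length
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    lom = np.hstack([model.log_odds, np.full((L, 1), -np.inf)])  # column 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lom[np.arange(L)[None, :], windows].sum(axis=1)


def scan(genome, model: ProfileModel, min_bits: float = 3.0, seq_id: str | None = None) -> list[MotifHit]:
    """Scan both strands of a genome with a profile.

    Every window is scored as the sum of per-column bits; hits at or above
    ``min_bits`` are reported with forward-strand coordinates.  Overlapping
    same-strand hits whose starts differ by less than half the model length
    collapse to the best-scoring one.
    """
    if isinstance(genome, Assembly):
        out: list[MotifHit] = []
        for c in genome:
            out.extend(scan(c.seq, model, min_bits=min_bits, seq_id=c.id))
        return out
    seq = genome.upper()
    sid = seq_id or "genome"
    n = len(seq)
    L = model.length
    hits: list[MotifHit] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        scores = _window_scores(s, model)
        for i in np.nonzero(scores >= min_bits)[0].tolist():
            start = i if strand == "+" else n - i - L
            hits.append(MotifHit(sid, start, start + L, strand, float(scores[i])))
    hits = _collapse(hits, L)
    hits.sort(key=lambda h: (h.start, h.strand))
    log.info("scan: %d hits >= %.2f bits on %s", len(hits), min_bits, sid)
    return hits


def _collapse(hits: list[MotifHit], L: int) -> list[MotifHit]:
    kept: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.bits, h.start, h.strand)):
        clash = any(k.strand == h.strand and abs(k.start - h.start) < L / 2 for k in kept)
        if clash:
            log.debug("scan: collapsed hit at %d (%s)", h.start, h.strand)
        else:
            kept.append(h)
    return kept


def filter_near_cds(
    hits: Sequence[MotifHit],
    genes: Sequence[GeneFeature],
    max_dist: int = 500,
) -> list[MotifHit]:
    """Keep hits with a same-strand CDS start 0..max_dist bp downstream.

    Distance is measured from the box end to the CDS start along the strand
    (inclusive at ``max_dist``); boxes downstream of the start or on the
    opposite strand are removed.  The nearest qualifying CDS is recorded.
    """
    out: list[MotifHit] = []
    for h in hits:
        best: tuple[int, str] | None = None
        for g in genes:
            if g.seq_id != h.seq_id or g.strand != h.strand:
                continue
            if g.strand == "+":
                dist = (g.start - 1) - h.end
            else:
                dist = h.start - g.end
            if 0 <= dist <= max_dist and (best is None or dist < best[0]):
                best = (dist, g.feature_id)
        if best is not None:
            out.append(MotifHit(h.seq_id, h.start, h.end, h.strand, h.bits, nearest_cds=best[1], distance=best[0]))
    log.info("filter_near_cds: %d of %d hits within %d bp of a CDS", len(out), len(hits), max_dist)
    return out


def hits_to_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tstart\tend\tstrand\tbits\tcds_id\tdistance\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start + 1}\t{h.end}\t{h.strand}\t{h.bits:.2f}"
                f"\t{h.nearest_cds or '.'}\t{h.distance if h.distance is not None else '.'}\n"
            )
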