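"""Core data model for draft-assembly improvement.

Sequences live in plain Python strings over the alphabet ``{A, C, G, T, N}``.
All internal coordinates are 0-based half-open; the I/O layer converts to the
1-based inclusive conventions of GFF3 and AGP at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

log = logging.getLogger("draftweaver")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
# Any IUPAC ambiguity code other than N is degraded to N on ingest.
_IUPAC_TO_N = re.compile(r"[RYSWKMBDHV]")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, context: str = "") -> str:
    """Uppercase *seq* and map non-ACGTN IUPAC codes to N.

    The number of degraded characters is logged; anything outside the IUPAC
    nucleotide alphabet raises ``ValueError``.
    """
    up = seq.upper().replace("U", "T")
    up, n_mapped = _IUPAC_TO_N.subn("N", up)
    if n_mapped:
        log.warning("%s: mapped %d ambiguous IUPAC characters to N", context or "sequence", n_mapped)
    bad = set(up) - _VALID
    if bad:
        raise ValueError(f"{context}: invalid sequence characters {sorted(bad)!r}")
    return up


@dataclass(frozen=True)
class Contig:
    """A gapless assembled sequence."""

    id: str
    seq: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


class Assembly:
    """An ordered collection of uniquely named contigs."""

    def __init__(self, contigs: Iterable[Contig] = (), label: str = ""):
        self.label = label
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._contigs[contig.id] = contig

    def __len__(self) -> int:
        return len(self._contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __contains__(self, cid: str) -> bool:
        return cid in self._contigs

    def __getitem__(self, cid: str) -> Contig:
        return self._contigs[cid]

    @property
    def ids(self) -> list[str]:
        return list(self._contigs)

    def total_bases(self) -> int:
        return sum(len(c) for c in self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Assembly({self.label!r}, {len(self)} contigs, {self.total_bases()} bp)"


@dataclass
class GapRecord:
    """A gap inside a scaffold, rendered as ``n_count`` Ns.

    ``kind`` distinguishes sequence gaps (size believed known) from closed
    physical gaps (size inferred in silico) per the standard draft-genome
    vocabulary.
    """

    n_count: int
    kind: str = "unknown"  # sequence_gap | physical_gap_closed | unknown
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.n_count < 1:
            raise ValueError("gap n_count must be >= 1")
        if self.kind not in ("sequence_gap", "physical_gap_closed", "unknown"):
            raise ValueError(f"unknown gap kind {self.kind!r}")


@dataclass
class ContigPart:
    """An oriented (sub-)interval of a contig placed in a scaffold."""

    contig_id: str
    orientation: str = "+"  # + | -
    start: int = 0          # 0-based half-open on the contig forward strand
    end: Optional[int] = None  # None = contig length

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")

    def resolve_end(self, contig_len: int) -> int:
        return contig_len if self.end is None else self.end


@dataclass
class Scaffold:
    """Ordered, oriented contig parts separated by gap records.

    Invariants: parts start and end with a ContigPart, ContigParts and
    GapRecords alternate (no two consecutive gaps), and every referenced
    contig must exist in the companion assembly when sequence is rendered.
    """

    id: str
    parts: list  # alternating ContigPart / GapRecord

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"scaffold {self.id!r}: empty part list")
        if not isinstance(self.parts[0], ContigPart) or not isinstance(self.parts[-1], ContigPart):
            raise ValueError(f"scaffold {self.id!r}: must start and end with a contig part")
        for a, b in zip(self.parts, self.parts[1:]):
            if isinstance(a, GapRecord) and isinstance(b, GapRecord):
                raise ValueError(f"scaffold {self.id!r}: consecutive gap records")

    def contig_parts(self) -> list[ContigPart]:
        return [p for p in self.parts if isinstance(p, ContigPart)]

    def sequence(self, assembly: Assembly) -> str:
        """Render the scaffold sequence; gaps become runs of N."""
        out: list[str] = []
        for p in self.parts:
            if isinstance(p, GapRecord):
                out.append("N" * p.n_count)
            else:
                contig = assembly[p.contig_id]
                seg = contig.seq[p.start:p.resolve_end(len(contig))]
                out.append(seg if p.orientation == "+" else revcomp(seg))
        return "".join(out)


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level feature (typically a CDS) in 1-based inclusive coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"feature {self.feature_id!r}: bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read, optionally paired via ``mate_id``."""

    id: str
    seq: str
    qual: Optional[str] = None
    mate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class StatsReport:
    """Assembly length statistics (N50 by the descending-cumulative rule)."""

    n_contigs_over: dict[int, int]
    total_bases: int
    largest: int
    n50_size: int
    n50_number: int


@dataclass
class Thresholds:
    """Single source of truth for every numeric rule of the pipeline.

    Defaults encode the published procedure: 300 bp contig ends taken from
    contigs strictly longer than 1 kb, E-value at most 0.02, reference
    separation at most 1 kb, exact overlaps of at least 15 bp, N-runs capped
    at 300 (touching only runs strictly longer than 300), unique 25-mers for
    synteny/placement, 3.0-bit motif threshold, and a 500 bp CDS window.
    """

    end_len: int = 300
    min_contig_for_ends: int = 1000      # strict >
    max_evalue: float = 0.02
    max_ref_separation: int = 1000
    min_overlap: int = 15
    nrun_cap: int = 300
    nrun_min_to_touch: int = 300         # strict >
    k_synteny: int = 25
    min_bits: float = 3.0
    cds_window: int = 500
    min_len_reorder: int = 1000          # strict >
    min_anchors: int = 3
    # knobs the published procedure leaves open
    word_size: int = 11
    resize_max_separation: int = 50000
    max_hit_regions: int = 5             # repeat-ambiguity guard
    congruency_large_cutoff: int = 10000
    congruency_min_cov: float = 0.95
    congruency_min_ident: float = 0.99
    gc_window: int = 10000
    gc_step: int = 5000
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"threshold {name} must be positive, got {value!r}")


__all__ = [
    "Assembly",
    "Contig",
    "ContigPart",
    "GapRecord",
    "GeneFeature",
    "ReadRecord",
    "Scaffold",
    "StatsReport",
    "Thresholds",
    "normalize_sequence",
    "revcomp",
]
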