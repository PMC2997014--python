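"""Short-read preparation and coverage arithmetic.

Implements the read-cleaning rules used ahead of de novo assembly: fixed-length
3' trimming keyed on read length, then removal of any read containing an
ambiguous base — in paired mode, removal of the whole pair if either mate has
one.  Coverage is the classical fold estimate reads x ends x length / genome.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .model import ReadRecord

log = logging.getLogger("draftweaver")

_UNAMBIGUOUS = frozenset("ACGT")


def trim_and_filter_reads(
    reads: Sequence[ReadRecord],
    trim_last: Mapping[int, int] | None = None,
    paired: bool = False,
) -> list[ReadRecord]:
    """Trim 3' bases by read length, then drop reads with ambiguous bases.

    ``trim_last`` maps read length -> number of terminal bases to remove
    (e.g. ``{36: 4, 76: 6}``); lengths not in the map are left untrimmed, so
    the operation is idempotent.  Trimming happens before the ambiguity
    filter.  In paired mode every read must have a resolvable mate and a read
    is removed iff it *or* its mate contains a non-ACGT character after
    trimming.
    """
    trim_last = dict(trim_last or {})
    trimmed: list[ReadRecord] = []
    for r in reads:
        cut = trim_last.get(len(r.seq), 0)
        if cut:
            r = ReadRecord(r.id, r.seq[:-cut], r.qual[:-cut] if r.qual else None, r.mate_id)
        trimmed.append(r)

    if not paired:
        kept = [r for r in trimmed if set(r.seq) <= _UNAMBIGUOUS]
        log.info("trim_and_filter_reads: %d in, %d kept (single)", len(reads), len(kept))
        return kept

    by_id = {r.id: r for r in trimmed}
    orphans = sorted(r.id for r in trimmed if r.mate_id is None or r.mate_id not in by_id)
    if orphans:
        raise ValueError(f"paired mode: reads without a mate: {orphans}")
    bad = {r.id for r in trimmed if not set(r.seq) <= _UNAMBIGUOUS}
    kept = [r for r in trimmed if r.id not in bad and r.mate_id not in bad]
    log.info("trim_and_filter_reads: %d in, %d kept (paired)", len(reads), len(kept))
    return kept


def theoretical_coverage(
    read_count: int,
    ends_per_record: int,
    read_len_after_trim: int,
    genome_size: int,
) -> int:
    """Theoretical fold coverage, rounded to the nearest integer.

    ``read_count`` counts sequencing records (pairs count once with
    ``ends_per_record=2``).  ``genome_size`` must be positive.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if min(ends_per_record, read_len_after_trim) <= 0 or read_count < 0:
        raise ValueError("arguments must be positive (read_count may be 0)")
    return round(read_count * ends_per_record * read_len_after_trim / genome_size)
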