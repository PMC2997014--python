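"""Assembly length statistics."""

from __future__ import annotations

import logging
from typing import Iterable

from .model import Assembly, StatsReport

log = logging.getLogger("draftweaver")


def length_stats(assembly: Assembly, cutoffs: Iterable[int] = (100, 1000)) -> StatsReport:
    """N50 and basic size statistics of an assembly.

    N50 size is the length of the contig at which the cumulative sum of
    lengths, sorted descending, first reaches at least half the total; the
    N50 number is how many contigs that takes (ties resolved by the first
    contig reaching half-total).
    """
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    lengths = sorted((len(c) for c in assembly), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50_size = lengths[0]
    n50_number = 1
    for i, length in enumerate(lengths, start=1):
        cum += length
        if cum >= half:
            n50_size, n50_number = length, i
            break
    report = StatsReport(
        n_contigs_over={c: sum(1 for x in lengths if x > c) for c in cutoffs},
        total_bases=total,
        largest=lengths[0],
        n50_size=n50_size,
        n50_number=n50_number,
    )
    log.info("length_stats: %d contigs, %d bp, N50 %d bp / %d contigs", len(lengths), total, n50_size, n50_number)
    return report
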