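"""Unique-k-mer synteny dot plots and windowed GC%/GC-skew tracks.

A dot plot point is a 25-mer occurring exactly once (double-stranded) in each
of two genomes; plotting the forward-strand start coordinates of every
matching pair visualizes long-range synteny, with inverted segments appearing
as anti-diagonal runs of minus-strand points.  GC skew ``(G-C)/(G+C)``
typically changes sign at the replication origin and terminus and doubles as
a sanity check on reference-guided reordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._kmers import decode_kmer, unique_kmer_arrays
from .model import Assembly

log = logging.getLogger("draftweaver")


@dataclass(frozen=True)
class DotPlotPoint:
    x: int        # start coordinate in genome A (0-based forward strand)
    y: int        # start coordinate in genome B
    strand: str   # '-' when the match is to the reverse strand of B


@dataclass(frozen=True)
class TrackWindow:
    start: int    # 0-based half-open
    end: int
    gc_fraction: float
    gc_skew: float
    skew_defined: bool = True  # False when the window has no G or C


def _as_seq(genome) -> str:
    if isinstance(genome, Assembly):
        return "".join(c.seq for c in genome)
    return genome


def unique_kmers(genome, k: int = 25) -> dict[str, int]:
    """Map of k-mers occurring exactly once in the genome to their start.

    Uniqueness is double-stranded: forward occurrences of a k-mer and of its
    reverse complement together must count exactly 1.  Palindromic and
    N-containing k-mers never qualify.  Keys are the forward-strand k-mer
    strings at the recorded position.
    """
    seq = _as_seq(genome)
    if len(seq) < k:
        log.warning("unique_kmers: sequence shorter than k=%d", k)
        return {}
    _canon, _sidx, pos, fwd, _ids = unique_kmer_arrays({"g": seq}, k)
    return {decode_kmer(int(f), k): int(p) for f, p in zip(fwd, pos)}


def dotplot_points(genomeA, genomeB, k: int = 25) -> list[DotPlotPoint]:
    """Matches between unique k-mers of two genomes (perfect matches only).

    One point per k-mer unique in A that is also unique in B, on either
    strand; coordinates are forward-strand starts in both genomes, sorted by
    (x, y).
    """
    seq_a, seq_b = _as_seq(genomeA), _as_seq(genomeB)
    a_canon, _ai, a_pos, a_fwd, _ = unique_kmer_arrays({"a": seq_a}, k)
    b_canon, _bi, b_pos, b_fwd, _ = unique_kmer_arrays({"b": seq_b}, k)
    _, ia, ib = np.intersect1d(a_canon, b_canon, assume_unique=True, return_indices=True)
    points = [
        DotPlotPoint(int(a_pos[i]), int(b_pos[j]), "+" if a_fwd[i] == b_fwd[j] else "-")
        for i, j in zip(ia.tolist(), ib.tolist())
    ]
    points.sort(key=lambda p: (p.x, p.y))
    log.info("dotplot_points: %d points (k=%d)", len(points), k)
    return points


def points_to_tsv(points: Iterable[DotPlotPoint], path) -> None:
    """Write points as a 1-based x/y/strand table (the plot's contract)."""
    with open(path, "w") as fh:
        fh.write("x\ty\tstrand\n")
        for p in points:
            fh.write(f"{p.x + 1}\t{p.y + 1}\t{p.strand}\n")


def plot_dotplot(points: Iterable[DotPlotPoint], path, title: str = "") -> None:
    """Optional scatter rendering of the points table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs_p = [p.x for p in points if p.strand == "+"]
    ys_p = [p.y for p in points if p.strand == "+"]
    xs_m = [p.x for p in points if p.strand == "-"]
    ys_m = [p.y for p in points if p.strand == "-"]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(xs_p, ys_p, s=1, c="tab:blue", label="+")
    ax.scatter(xs_m, ys_m, s=1, c="tab:red", label="-")
    ax.set_xlabel("genome A (bp)")
    ax.set_ylabel("genome B (bp)")
    if title:
        ax.set_title(title)
    ax.legend(markerscale=8)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gc_tracks(genome, window: int = 10000, step: int = 5000) -> list[TrackWindow]:
    """Sliding-window GC fraction and GC skew.

    Windows are 0-based half-open; the final partial window is included.  N
    bases count in neither numerator nor denominator.  Skew is
    ``(G - C) / (G + C)``, defined as 0 (and flagged) when a window has no G
    or C.
    """
    if not window >= step >= 1:
        raise ValueError("require window >= step >= 1")
    seq = _as_seq(genome)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_g = np.concatenate(([0], np.cumsum(arr == ord("G"))))
    is_c = np.concatenate(([0], np.cumsum(arr == ord("C"))))
    is_acgt = np.concatenate(([0], np.cumsum(np.isin(arr, [ord(b) for b in "ACGT"]))))
    out: list[TrackWindow] = []
    for start in range(0, len(seq), step):
        end = min(start + window, len(seq))
        g = int(is_g[end] - is_g[start])
        c = int(is_c[end] - is_c[start])
        denom = int(is_acgt[end] - is_acgt[start])
        gc = (g + c) / denom if denom else 0.0
        skew = (g - c) / (g + c) if g + c else 0.0
        out.append(TrackWindow(start, end, gc, skew, skew_defined=(g + c) > 0))
        if end == len(seq):
            break
    return out


def tracks_to_bed(tracks: Iterable[TrackWindow], chrom: str, path_gc, path_skew) -> None:
    """Write GC% and skew as BED-like 4-column files for circular plotters."""
    with open(path_gc, "w") as g, open(path_skew, "w") as s:
        for t in tracks:
            g.write(f"{chrom}\t{t.start}\t{t.end}\t{t.gc_fraction:.6f}\n")
            s.write(f"{chrom}\t{t.start}\t{t.end}\t{t.gc_skew:.6f}\n")
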