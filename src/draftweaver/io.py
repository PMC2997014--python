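"""Standard-format I/O: FASTA/FASTQ via Biopython, GFF3 and AGP v2.1 readers/writers.

Files are 1-based inclusive where the format says so; everything handed to the
rest of the package is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Assembly,
    Contig,
    ContigPart,
    GapRecord,
    GeneFeature,
    ReadRecord,
    Scaffold,
    normalize_sequence,
)

log = logging.getLogger("draftweaver")

PathLike = Union[str, Path]


def read_fasta(path: PathLike, label: str = "") -> Assembly:
    """Read a multi-FASTA into an :class:`Assembly`.

    Record order is preserved, sequences are uppercased, non-ACGTN IUPAC
    codes become N (logged), and the id is the header token before the first
    whitespace.  Duplicate ids, empty files and empty records are hard errors.
    """
    path = Path(path)
    assembly = Assembly(label=label or path.stem)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        assembly.add(Contig(rec.id, normalize_sequence(seq, context=f"{path}:{rec.id}"), provenance=str(path)))
    if len(assembly) == 0:
        raise ValueError(f"{path}: no FASTA records")
    log.info("read_fasta: %s -> %d contigs, %d bp", path, len(assembly), assembly.total_bases())
    return assembly


def write_fasta(assembly: Assembly, path: PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in assembly]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: PathLike, mate_of: PathLike | None = None) -> list[ReadRecord]:
    """Read one FASTQ file, or a pair of files record-by-record mated."""
    reads = [
        ReadRecord(rec.id, str(rec.seq).upper(), qual="".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if mate_of is None:
        return reads
    mates = read_fastq(mate_of)
    if len(mates) != len(reads):
        raise ValueError("paired FASTQ files differ in record count")
    out = []
    for r1, r2 in zip(reads, mates):
        out.append(ReadRecord(r1.id + "/1", r1.seq, r1.qual, mate_id=r2.id + "/2"))
        out.append(ReadRecord(r2.id + "/2", r2.seq, r2.qual, mate_id=r1.id + "/1"))
    return out


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: PathLike, feature_types: tuple[str, ...] = ("CDS",)) -> list[GeneFeature]:
    """Read GFF3 rows of the requested types (default CDS) as GeneFeatures.

    Coordinates are kept 1-based inclusive as in the format.  A ``##FASTA``
    trailer is tolerated and ignored; a row with start > end is an error
    naming the offending line.
    """
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 row")
            seq_id, _source, ftype, start, end, _score, strand, _phase = cols[:8]
            if ftype not in feature_types:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            attrs = cols[8] if len(cols) > 8 else ""
            fid = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
                    break
            feats.append(GeneFeature(seq_id, start_i, end_i, strand if strand in "+-" else "+", fid or f"{ftype}_{lineno}"))
    log.info("read_gff: %s -> %d %s features", path, len(feats), "/".join(feature_types))
    return feats


def write_gff(features: Iterable[GeneFeature], path: PathLike, source: str = "draftweaver", ftype: str = "CDS") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f"{f.seq_id}\t{source}\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.feature_id}\n")


# ---------------------------------------------------------------------------
# AGP v2.1


def write_layout(scaffolds: list[Scaffold], contigs: Assembly, path_agp: PathLike, path_fasta: PathLike | None = None) -> None:
    """Write scaffolds as AGP v2.1 plus (optionally) the rendered FASTA.

    Component lines carry orientation; gap lines use component type N with
    gap_type ``scaffold`` and linkage ``yes``.  ``read_layout(write_layout(S))``
    round-trips bit-exactly.
    """
    with open(path_agp, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for scaf in scaffolds:
            pos = 0
            for part_no, part in enumerate(scaf.parts, start=1):
                if isinstance(part, GapRecord):
                    fh.write(
                        f"{scaf.id}\t{pos + 1}\t{pos + part.n_count}\t{part_no}\tN\t{part.n_count}"
                        f"\tscaffold\tyes\talign_genus\n"
                    )
                    pos += part.n_count
                else:
                    if part.orientation not in "+-":
                        raise ValueError(f"scaffold {scaf.id}: bad orientation {part.orientation!r}")
                    end = part.resolve_end(len(contigs[part.contig_id]))
                    span = end - part.start
                    fh.write(
                        f"{scaf.id}\t{pos + 1}\t{pos + span}\t{part_no}\tW\t{part.contig_id}"
                        f"\t{part.start + 1}\t{end}\t{part.orientation}\n"
                    )
                    pos += span
    if path_fasta is not None:
        scaffolded = Assembly((Contig(s.id, s.sequence(contigs)) for s in scaffolds), label="scaffolds")
        write_fasta(scaffolded, path_fasta)


def read_layout(path_agp: PathLike) -> list[Scaffold]:
    """Read AGP v2.1 back into Scaffold objects (inverse of :func:`write_layout`)."""
    scaffolds: dict[str, list] = {}
    with open(path_agp) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            sid, ctype = cols[0], cols[4]
            parts = scaffolds.setdefault(sid, [])
            if ctype in ("N", "U"):
                parts.append(GapRecord(int(cols[5]), kind="unknown", evidence=cols[8] if len(cols) > 8 else ""))
            else:
                parts.append(ContigPart(cols[5], orientation=cols[8], start=int(cols[6]) - 1, end=int(cols[7])))
    return [Scaffold(sid, parts) for sid, parts in scaffolds.items()]


__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_gff",
    "write_gff",
    "write_layout",
    "read_layout",
]
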