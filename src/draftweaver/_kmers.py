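"""Vectorized integer k-mer machinery shared by the anchoring and synteny code.

k-mers up to k=31 are packed into int64 (2 bits per base).  A k-mer containing
N is invalid.  "Double-stranded" uniqueness treats a k-mer and its reverse
complement as the same entity: the canonical form is the smaller of the two
integers, and a palindromic k-mer (equal to its own reverse complement) is
never unique because each occurrence counts on both strands.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_table(seq: str, k: int):
    """Return (fwd, rc, canon, valid) int64 arrays for every k-window of *seq*.

    ``valid`` is False for windows containing a non-ACGT character.  Empty
    arrays are returned when the sequence is shorter than k.
    """
    if k > 31:
        raise ValueError("k must be <= 31 to fit in int64")
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty, np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    fwd = windows @ weights
    rc = (3 - windows) @ weights[::-1].copy()
    valid = (windows < 4).all(axis=1)
    canon = np.minimum(fwd, rc)
    return fwd, rc, canon, valid


def unique_kmer_arrays(seqs: Mapping[str, str], k: int):
    """Double-stranded-unique k-mers across a set of sequences.

    Returns ``(canon, seq_idx, pos, fwd, seq_ids)`` where ``canon`` is sorted
    ascending and contains each canonical k-mer integer occurring exactly
    once across all sequences and strands (palindromes excluded);
    ``seq_ids[seq_idx[i]]`` and ``pos[i]`` locate it, and ``fwd[i]`` is the
    forward-strand integer at that position.
    """
    seq_ids = list(seqs)
    canon_parts, pos_parts, sid_parts, fwd_parts = [], [], [], []
    for idx, sid in enumerate(seq_ids):
        fwd, rc, canon, valid = kmer_table(seqs[sid], k)
        if not canon.size:
            continue
        keep = valid & (fwd != rc)
        positions = np.nonzero(keep)[0]
        canon_parts.append(canon[keep])
        fwd_parts.append(fwd[keep])
        pos_parts.append(positions.astype(np.int64))
        sid_parts.append(np.full(positions.size, idx, dtype=np.int32))
    if not canon_parts:
        e64 = np.empty(0, dtype=np.int64)
        return e64, np.empty(0, dtype=np.int32), e64, e64, seq_ids
    canon_all = np.concatenate(canon_parts)
    pos_all = np.concatenate(pos_parts)
    sid_all = np.concatenate(sid_parts)
    fwd_all = np.concatenate(fwd_parts)
    vals, first, counts = np.unique(canon_all, return_index=True, return_counts=True)
    singletons = counts == 1
    idx = first[singletons]
    return vals[singletons], sid_all[idx], pos_all[idx], fwd_all[idx], seq_ids


def decode_kmer(value: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[value & 3])
        value >>= 2
    return "".join(reversed(bases))
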