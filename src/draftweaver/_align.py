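"""Numba kernels for the seeded local aligner.

``banded_sw`` is a banded affine-gap Smith-Waterman with traceback restricted
to diagonals ``j - i`` in ``[dlo, dhi]`` (DP indices; diagonal of the aligned
pair ``q[i-1] ~ s[j-1]``).  Storage is band-limited: cell (i, j) lives at
column ``c = j - i - dlo`` of row i, so memory is rows x band width rather
than rows x subject length.  Gap costs follow the search-tool convention: a
gap of length L costs ``gap_first + (L-1) * gap_ext`` where ``gap_first``
already includes the first extension (open 5 / extend 2 -> gap_first 7,
gap_ext 2).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def xdrop_ungapped(q, s, qpos, spos, w, match, mismatch, xdrop):
    """Two-way ungapped extension of an exact w-mer seed with an X-drop rule.

    Returns (score, q_lo, q_hi) half-open extents on the query; the subject
    extent follows the same diagonal.
    """
    score = w * match
    best = score
    # right
    i, j = qpos + w, spos + w
    hi = qpos + w
    run = score
    while i < len(q) and j < len(s):
        run += match if (q[i] == s[j] and q[i] < 4) else mismatch
        i += 1
        j += 1
        if run > best:
            best = run
            hi = i
        if best - run > xdrop:
            break
    # left
    run = best
    i, j = qpos - 1, spos - 1
    lo = qpos
    top = best
    while i >= 0 and j >= 0:
        run += match if (q[i] == s[j] and q[i] < 4) else mismatch
        if run > top:
            top = run
            lo = i
        if top - run > xdrop:
            break
        i -= 1
        j -= 1
    return top, lo, hi


@njit(cache=True)
def banded_sw(q, s, match, mismatch, gap_first, gap_ext, dlo, dhi):
    """Banded affine local alignment with traceback.

    Returns (score, qs, qe, ss, se, matches, mismatches, gap_opens, aln_len);
    intervals are 0-based half-open.  A non-positive best score returns
    zeros.

    In band coordinates a cell (i, c) is DP cell (i, j = i + dlo + c):
    the diagonal predecessor is (i-1, c), the left (gap consuming subject)
    predecessor is (i, c-1) and the up (gap consuming query) predecessor is
    (i-1, c+1).
    """
    m, n = len(q), len(s)
    W = dhi - dlo + 1
    H = np.zeros((m + 1, W), dtype=np.int32)
    E = np.full((m + 1, W), NEG, dtype=np.int32)
    F = np.full((m + 1, W), NEG, dtype=np.int32)
    # pointers: ph 0 stop, 1 diag, 2 E (gap consuming subject), 3 F
    ph = np.zeros((m + 1, W), dtype=np.uint8)
    pe = np.zeros((m + 1, W), dtype=np.uint8)  # 1 = opened from H
    pf = np.zeros((m + 1, W), dtype=np.uint8)
    best = 0
    bi = 0
    bc = 0
    for i in range(1, m + 1):
        clo = 1 - i - dlo
        chi = n - i - dlo
        if clo < 0:
            clo = 0
        if chi > W - 1:
            chi = W - 1
        for c in range(clo, chi + 1):
            if c > 0:
                e_open = H[i, c - 1] - gap_first
                e_ext = E[i, c - 1] - gap_ext
            else:
                e_open = NEG
                e_ext = NEG
            if e_open >= e_ext:
                E[i, c] = e_open
                pe[i, c] = 1
            else:
                E[i, c] = e_ext
                pe[i, c] = 0
            if c < W - 1:
                f_open = H[i - 1, c + 1] - gap_first
                f_ext = F[i - 1, c + 1] - gap_ext
            else:
                f_open = NEG
                f_ext = NEG
            if f_open >= f_ext:
                F[i, c] = f_open
                pf[i, c] = 1
            else:
                F[i, c] = f_ext
                pf[i, c] = 0
            j = i + dlo + c
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                sub = match
            else:
                sub = mismatch
            # H[i-1, c] is DP cell (i-1, j-1); at the band edge of row i-1
            # that cell was never computed and holds 0, which is exactly the
            # local-alignment restart value.
            diag = H[i - 1, c] + sub
            h = 0
            p = 0
            if diag >= h:
                h = diag
                p = 1
            if E[i, c] > h:
                h = E[i, c]
                p = 2
            if F[i, c] > h:
                h = F[i, c]
                p = 3
            H[i, c] = h
            ph[i, c] = p
            if h > best:
                best = h
                bi = i
                bc = c
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i, c = bi, bc
    matches = 0
    mismatches = 0
    gap_opens = 0
    aln_len = 0
    while i > 0:
        j = i + dlo + c
        if j <= 0 or H[i, c] <= 0:
            break
        p = ph[i, c]
        if p == 0:
            break
        if p == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            aln_len += 1
            i -= 1
        elif p == 2:
            gap_opens += 1
            while True:
                opened = pe[i, c] == 1
                aln_len += 1
                c -= 1
                if opened:
                    break
        else:
            gap_opens += 1
            while True:
                opened = pf[i, c] == 1
                aln_len += 1
                i -= 1
                c += 1
                if opened:
                    break
    j = i + dlo + c
    return best, i, bi, j, bi + dlo + bc, matches, mismatches, gap_opens, aln_len
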