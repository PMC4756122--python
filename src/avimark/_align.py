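"""Pairwise DNA alignment kernels (numba-jitted Gotoh dynamic programming).

Conventions used throughout the package:

* scoring: ``match``/``mismatch`` per column; a gap of length ``n`` costs
  ``gap_open + n * gap_extend`` (all penalties negative).
* a column counts as a match only when both symbols are identical *and*
  unambiguous (A/C/G/T); any IUPAC ambiguity code scores as a mismatch.
* coordinates are 0-based, half-open.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# IUPAC nucleotide alphabet; A/C/G/T get codes 0-3, every ambiguity code a
# distinct code >= 4 so that "identical symbol" is well defined but only
# unambiguous identity scores as a match.
IUPAC = "ACGTRYSWKMBDHVN"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(IUPAC):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMPLEMENT = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))

NEG_INF = np.int64(-(10**12))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes; raises on non-IUPAC symbols."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = sorted({c for c in seq.upper() if c not in IUPAC})
        raise ValueError(f"non-IUPAC symbols in sequence: {bad}")
    return arr


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@njit(cache=False)
def _score(a: np.uint8, b: np.uint8, match: np.int64, mismatch: np.int64) -> np.int64:
    if a == b and a < 4:
        return match
    return mismatch


@njit(cache=False)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):
    """Local (Smith-Waterman) affine-gap fill; returns matrices + best cell."""
    m, n = a.size, b.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    first = gap_open + gap_extend  # cost of a length-1 gap
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + first
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + first
            F[i, j] = f if f > fo else fo
            diag = H[i - 1, j - 1] + _score(a[i - 1], b[j - 1], match, mismatch)
            h = diag
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=False)
def _sw_traceback(a, b, H, E, F, bi, bj, match, mismatch, gap_open, gap_extend):
    """Trace the optimal local path back from (bi, bj).

    Returns (a_start, b_start, n_matches, n_cols, path arrays). Path arrays
    hold, per alignment column from the end, the consumed indices of a and b
    (-1 for a gap).
    """
    first = gap_open + gap_extend
    cap = a.size + b.size
    pa = np.empty(cap, dtype=np.int64)
    pb = np.empty(cap, dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E (gap in a), 2=F (gap in b)
    n_matches = 0
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + _score(a[i - 1], b[j - 1], match, mismatch)
            if H[i, j] == diag:
                pa[k] = i - 1
                pb[k] = j - 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    n_matches += 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            pa[k] = -1
            pb[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] + first:
                state = 0
            j -= 1
        else:
            pa[k] = i - 1
            pb[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] + first:
                state = 0
            i -= 1
    return i, j, n_matches, k, pa[:k][::-1], pb[:k][::-1]


@njit(cache=False)
def _nw_fill(a, b, match, mismatch, gap_open, gap_extend):
    """Global fill with free end gaps in both sequences (overlap alignment)."""
    m, n = a.size, b.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + first
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + first
            F[i, j] = f if f > fo else fo
            h = H[i - 1, j - 1] + _score(a[i - 1], b[j - 1], match, mismatch)
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            # free end gaps: first row/column stay 0 (loop starts at 1), and
            # interior cells may restart only via the borders, not 0-clamping
            H[i, j] = h
    return H, E, F


@njit(cache=False)
def _nw_traceback(a, b, H, E, F, match, mismatch, gap_open, gap_extend):
    m, n = a.size, b.size
    # best end on last row or last column (free trailing gaps)
    best = H[m, n]
    bi, bj = m, n
    for i in range(m + 1):
        if H[i, n] > best:
            best, bi, bj = H[i, n], i, n
    for j in range(n + 1):
        if H[m, j] > best:
            best, bi, bj = H[m, j], m, j
    first = gap_open + gap_extend
    cap = m + n
    pa = np.empty(cap, dtype=np.int64)
    pb = np.empty(cap, dtype=np.int64)
    k = 0
    # trailing free gaps
    for i in range(m - 1, bi - 1, -1):
        pa[k] = i
        pb[k] = -1
        k += 1
    for j in range(n - 1, bj - 1, -1):
        pa[k] = -1
        pb[k] = j
        k += 1
    i, j = bi, bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            diag = H[i - 1, j - 1] + _score(a[i - 1], b[j - 1], match, mismatch)
            if H[i, j] == diag:
                pa[k] = i - 1
                pb[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            pa[k] = -1
            pb[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] + first:
                state = 0
            j -= 1
        else:
            pa[k] = i - 1
            pb[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] + first:
                state = 0
            i -= 1
    # leading free gaps
    while i > 0:
        pa[k] = i - 1
        pb[k] = -1
        k += 1
        i -= 1
    while j > 0:
        pa[k] = -1
        pb[k] = j - 1
        k += 1
        j -= 1
    return best, pa[:k][::-1], pb[:k][::-1]


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -2,
                   gap_open: int = -5, gap_extend: int = -2):
    """Best local alignment of ``a`` vs ``b``.

    Returns a dict with score, half-open spans on both sequences, the number
    of matching columns, total alignment columns, and the column path.
    """
    ca, cb = encode(a), encode(b)
    if ca.size == 0 or cb.size == 0:
        return {"score": 0, "a_start": 0, "a_end": 0, "b_start": 0,
                "b_end": 0, "n_matches": 0, "n_cols": 0, "path": ([], [])}
    H, E, F, best, bi, bj = _sw_fill(ca, cb, match, mismatch, gap_open, gap_extend)
    a0, b0, n_matches, n_cols, pa, pb = _sw_traceback(
        ca, cb, H, E, F, bi, bj, match, mismatch, gap_open, gap_extend)
    return {"score": int(best), "a_start": int(a0), "a_end": int(bi),
            "b_start": int(b0), "b_end": int(bj),
            "n_matches": int(n_matches), "n_cols": int(n_cols),
            "path": (pa, pb)}


def overlap_align(a: str, b: str, match: int = 1, mismatch: int = -2,
                  gap_open: int = -5, gap_extend: int = -2):
    """Global alignment with free end gaps in both sequences.

    Returns (score, pa, pb) where pa/pb give per-column consumed indices
    (-1 for gap) covering both sequences end to end.
    """
    ca, cb = encode(a), encode(b)
    if ca.size == 0 or cb.size == 0:
        pa = np.concatenate([np.arange(ca.size), np.full(cb.size, -1)])
        pb = np.concatenate([np.full(ca.size, -1), np.arange(cb.size)])
        return 0, pa.astype(np.int64), pb.astype(np.int64)
    H, E, F = _nw_fill(ca, cb, match, mismatch, gap_open, gap_extend)
    score, pa, pb = _nw_traceback(ca, cb, H, E, F, match, mismatch,
                                  gap_open, gap_extend)
    return int(score), pa, pb


def identity_over_shorter(a: str, b: str, **scoring) -> float:
    """CD-HIT-style identity: matching columns / length of the shorter
    sequence, from an overlap alignment."""
    if not a or not b:
        return 0.0
    _, pa, pb = overlap_align(a, b, **scoring)
    ea, eb = encode(a), encode(b)
    matches = 0
    for ia, ib in zip(pa, pb):
        if ia >= 0 and ib >= 0 and ea[ia] == eb[ib] and ea[ia] < 4:
            matches += 1
    return matches / min(len(a), len(b))
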