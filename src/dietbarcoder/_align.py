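"""Low-level alignment kernels (numba-compiled).

Implements the semi-global (end-gap free) dynamic-programming alignment that
underlies every identity computation in the package, plus the ungapped
overlap search used for paired-end merging.

Scoring is fixed: match +1, mismatch -1, gap -1; leading/trailing gaps on
either sequence are free.  Identity is matches / alignment-columns over the
aligned core (free end overhangs excluded), so internal gaps count as
mismatch columns and a single substitution on an L-mer gives (L-1)/L.

The DP objective is lexicographic — maximize score, then matches, then
minimize aligned columns — so the (matches, columns) pair at the optimum is
unique and identity is well-defined and symmetric even when several
alignments share the optimal score.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# nucleotide encoding: A C G T N -> 0 1 2 3 4 ; anything else -> 4
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _LUT[ord(_ch)] = _i
    _LUT[ord(_ch.lower())] = _i

GAP_CODE = np.int32(-2)
UNCOVERED = np.int32(-1)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,other=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@njit(cache=True)
def _fill(a, b):  # pragma: no cover - exercised via wrappers
    """Lexicographic DP: maximize score, then matches, then minimize columns.

    Returns (S, M, C, P): score/matches/columns of the best aligned core
    ending at each cell, and the chosen move (1 diag, 2 up, 3 left).
    """
    n, m = a.shape[0], b.shape[0]
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    C = np.zeros((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            is_match = 1 if (ai == b[j - 1] and ai < 4) else 0
            bs = S[i - 1, j - 1] + (1 if is_match else -1)
            bm = M[i - 1, j - 1] + is_match
            bc = C[i - 1, j - 1] + 1
            ptr = 1
            us, um, uc = S[i - 1, j] - 1, M[i - 1, j], C[i - 1, j] + 1
            if _better(us, um, uc, bs, bm, bc):
                bs, bm, bc, ptr = us, um, uc, 2
            ls, lm, lc = S[i, j - 1] - 1, M[i, j - 1], C[i, j - 1] + 1
            if _better(ls, lm, lc, bs, bm, bc):
                bs, bm, bc, ptr = ls, lm, lc, 3
            S[i, j], M[i, j], C[i, j], P[i, j] = bs, bm, bc, ptr
    return S, M, C, P


@njit(cache=True)
def _better(s1, m1, c1, s2, m2, c2):  # pragma: no cover
    if s1 != s2:
        return s1 > s2
    if m1 != m2:
        return m1 > m2
    return c1 < c2


@njit(cache=True)
def _best_end(S, M, C):  # pragma: no cover
    n = S.shape[0] - 1
    m = S.shape[1] - 1
    bi, bj = n, 0
    for j in range(1, m + 1):
        if _better(S[n, j], M[n, j], C[n, j], S[bi, bj], M[bi, bj], C[bi, bj]):
            bi, bj = n, j
    for i in range(0, n + 1):
        if _better(S[i, m], M[i, m], C[i, m], S[bi, bj], M[bi, bj], C[bi, bj]):
            bi, bj = i, m
    return bi, bj


@njit(cache=True)
def _align_counts(a, b):  # pragma: no cover
    S, M, C, _ = _fill(a, b)
    bi, bj = _best_end(S, M, C)
    return M[bi, bj], C[bi, bj], S[bi, bj]


@njit(cache=True)
def _align_map(a, b):  # pragma: no cover
    """Map each position of b to the aligned position of a.

    Returns an int32 array of len(b): index into a, or -1 (outside the
    aligned span of a/b) or -2 (aligned to a gap in a).
    """
    S, M, C, P = _fill(a, b)
    bi, bj = _best_end(S, M, C)
    mapping = np.full(b.shape[0], -1, dtype=np.int32)
    i, j = bi, bj
    while i > 0 and j > 0:
        p = P[i, j]
        if p == 1:
            mapping[j - 1] = i - 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            mapping[j - 1] = -2
            j -= 1
    return mapping


def semiglobal_identity(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Identity fraction and aligned length of the semi-global alignment."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty-input")
    if a.shape[0] == b.shape[0] and np.array_equal(a, b) and a.max() < 4:
        return 1.0, int(a.shape[0])
    matches, columns, _ = _align_counts(a, b)
    if columns == 0:
        return 0.0, 0
    return matches / columns, int(columns)


def map_to_anchor(anchor: np.ndarray, read: np.ndarray) -> np.ndarray:
    """For each anchor column, the aligned read index (-1 uncovered, -2 gap).

    The anchor plays the role of sequence ``b`` so the returned array has
    one entry per anchor column.
    """
    return _align_map(read, anchor)


@njit(cache=True)
def best_overlap(f, r):  # pragma: no cover
    """Best ungapped overlap between forward read f and reverse-complemented
    reverse read r.

    The offset s places r[0] at coordinate s of f (s may be negative).
    Returns (s, overlap_len, matches) maximizing matches; ties prefer the
    longer overlap, then the smaller s.
    """
    nf, nr = f.shape[0], r.shape[0]
    best_s = 0
    best_ov = -1
    best_matches = -1
    for s in range(-nr + 1, nf):
        lo = s if s > 0 else 0
        hi = s + nr if s + nr < nf else nf
        ov = hi - lo
        if ov <= 0:
            continue
        m = 0
        for k in range(lo, hi):
            cf = f[k]
            cr = r[k - s]
            if cf == cr and cf < 4:
                m += 1
        if m > best_matches or (m == best_matches and ov > best_ov):
            best_matches = m
            best_ov = ov
            best_s = s
    return best_s, best_ov, best_matches
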