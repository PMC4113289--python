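"""Global pairwise DNA alignment with free terminal gaps.

This is the identity engine behind 97% OTU clustering, read->OTU mapping and
both chimera filters. Scoring is fixed: match +1, mismatch -1, gap open -2,
gap extension -1; terminal gaps cost half an extension point per base.
Charging terminal gaps a little (rather than nothing) keeps containment
alignments intact while forcing unrelated sequences into an end-to-end
alignment — with fully free ends the optimum for unrelated pairs collapses
to a one-column overlap whose "identity" is meaningless. Identity is the
fraction of matching columns over all alignment columns excluding
terminal-gap columns, so a sequence aligned inside a longer one scores 1.0.
All scores are handled internally in doubled (half-point) integer units.

The dynamic program is a three-state Gotoh recursion, jitted with numba; the
traceback is done in Python from the pointer matrices. Alignments are
memoised because amplicon data is massively replicated.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

# doubled units: match +1 -> +2 etc.; terminal gaps cost -1 (half a point)
MATCH = 2
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -2
TERM_GAP = -1

_NEG = -(10**8)

# states
_M, _X, _Y = 0, 1, 2  # match/mismatch, gap-in-b (consumes a), gap-in-a (consumes b)


@njit(cache=True)
def _gotoh_fill(a: np.ndarray, b: np.ndarray):
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0
    for i in range(1, n + 1):  # cheap leading terminal gap in b
        X[i, 0] = TERM_GAP * i
        pX[i, 0] = _X
    for j in range(1, m + 1):  # cheap leading terminal gap in a
        Y[0, j] = TERM_GAP * j
        pY[0, j] = _Y

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            # M from diagonal
            best = M[i - 1, j - 1]
            ptr = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _Y
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: gap in b, consume a[i-1]
            best = M[i - 1, j] + GAP_OPEN
            ptr = _M
            if X[i - 1, j] + GAP_EXTEND > best:
                best = X[i - 1, j] + GAP_EXTEND
                ptr = _X
            if Y[i - 1, j] + GAP_OPEN > best:
                best = Y[i - 1, j] + GAP_OPEN
                ptr = _Y
            X[i, j] = best
            pX[i, j] = ptr
            # Y: gap in a, consume b[j-1]
            best = M[i, j - 1] + GAP_OPEN
            ptr = _M
            if X[i, j - 1] + GAP_OPEN > best:
                best = X[i, j - 1] + GAP_OPEN
                ptr = _X
            if Y[i, j - 1] + GAP_EXTEND > best:
                best = Y[i, j - 1] + GAP_EXTEND
                ptr = _Y
            Y[i, j] = best
            pY[i, j] = ptr

    # trailing terminal gaps charged at TERM_GAP per remaining base
    bi, bj, bstate, bscore = 0, 0, _M, _NEG
    for i in range(n + 1):
        for st in range(3):
            v = M[i, m] if st == _M else (X[i, m] if st == _X else Y[i, m])
            v += TERM_GAP * (n - i)
            if v > bscore:
                bscore, bi, bj, bstate = v, i, m, st
    for j in range(m + 1):
        for st in range(3):
            v = M[n, j] if st == _M else (X[n, j] if st == _X else Y[n, j])
            v += TERM_GAP * (m - j)
            if v > bscore:
                bscore, bi, bj, bstate = v, n, j, st
    return M, X, Y, pM, pX, pY, bi, bj, bstate, bscore


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@lru_cache(maxsize=200_000)
def align_global(a: str, b: str) -> tuple[str, str, int]:
    """Align two sequences globally (free end gaps).

    Returns ``(aligned_a, aligned_b, score)`` with ``-`` for gaps; terminal
    gaps appear as the unaligned overhangs padded against ``-``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    ea, eb = _encode(a), _encode(b)
    n, m = len(a), len(b)
    _Mm, _Xm, _Ym, pM, pX, pY, i, j, state, score = _gotoh_fill(ea, eb)

    end_i, end_j = i, j
    cols_a: list[str] = []
    cols_b: list[str] = []
    au, bu = a.upper(), b.upper()
    while not (i == 0 and j == 0):
        if state == _M:
            cols_a.append(au[i - 1])
            cols_b.append(bu[j - 1])
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == _X:
            if j == 0:  # remaining a[:i] is a leading terminal gap
                break
            cols_a.append(au[i - 1])
            cols_b.append("-")
            state = pX[i, j]
            i -= 1
        else:
            if i == 0:
                break
            cols_a.append("-")
            cols_b.append(bu[j - 1])
            state = pY[i, j]
            j -= 1
    core_a = "".join(reversed(cols_a))
    core_b = "".join(reversed(cols_b))
    # at most one of i/j (and one of the trailing overhangs) is nonzero
    aln_a = au[:i] + "-" * j + core_a + au[end_i:] + "-" * (m - end_j)
    aln_b = "-" * i + bu[:j] + core_b + "-" * (n - end_i) + bu[end_j:]
    assert len(aln_a) == len(aln_b)
    return aln_a, aln_b, int(score)


def identity_from_alignment(aln_a: str, aln_b: str) -> float:
    """Matches / columns, excluding terminal-gap columns at either end."""
    lo, hi = 0, len(aln_a)
    while lo < hi and (aln_a[lo] == "-" or aln_b[lo] == "-"):
        lo += 1
    while hi > lo and (aln_a[hi - 1] == "-" or aln_b[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for k in range(lo, hi) if aln_a[k] == aln_b[k] != "-")
    return matches / (hi - lo)


@lru_cache(maxsize=200_000)
def global_identity(a: str, b: str) -> float:
    """Pairwise identity under the package's fixed global-alignment scoring."""
    aln_a, aln_b, _ = align_global(a.upper(), b.upper())
    return identity_from_alignment(aln_a, aln_b)


@lru_cache(maxsize=200_000)
def match_profile(query: str, parent: str) -> np.ndarray:
    """Per-query-base match indicator against ``parent``.

    ``profile[i]`` is 1 when query base ``i`` aligns to an identical parent
    base in the global alignment, else 0. This projection onto query
    coordinates is the frame in which chimeric two-parent models are scored.
    """
    aln_q, aln_p, _ = align_global(query.upper(), parent.upper())
    prof = np.zeros(len(query), dtype=np.int8)
    qi = 0
    for cq, cp in zip(aln_q, aln_p):
        if cq != "-":
            if cq == cp:
                prof[qi] = 1
            qi += 1
    return prof
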