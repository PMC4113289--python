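"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive plain Python: a textbook three-state
affine-gap DP with free end gaps, an exhaustive overlap scorer for read
merging, and an exhaustive-crossover bimera scorer. Shared conventions that
the identity/bimera definitions themselves fix (match/mismatch/gap scores,
terminal-gap-free column counting, leftmost best crossover, longest best
overlap) are followed here too; the code paths share nothing with the
package.
"""

from __future__ import annotations

from typing import Optional

# doubled (half-point) units; terminal gaps cost half an extension per base
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND, TERM_GAP = 2, -2, -4, -2, -1
NEG = float("-inf")


def gotoh_align(a: str, b: str) -> tuple[str, str, int]:
    """Textbook affine-gap global alignment with cheap terminal gaps."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    pM = [[0] * (m + 1) for _ in range(n + 1)]
    pX = [[0] * (m + 1) for _ in range(n + 1)]
    pY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = TERM_GAP * i
    for j in range(1, m + 1):
        Y[0][j] = TERM_GAP * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            opts = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            k = max(range(3), key=lambda t: opts[t])
            M[i][j] = opts[k] + s
            pM[i][j] = k
            opts = (
                M[i - 1][j] + GAP_OPEN,
                X[i - 1][j] + GAP_EXTEND,
                Y[i - 1][j] + GAP_OPEN,
            )
            k = max(range(3), key=lambda t: opts[t])
            X[i][j] = opts[k]
            pX[i][j] = k
            opts = (
                M[i][j - 1] + GAP_OPEN,
                X[i][j - 1] + GAP_OPEN,
                Y[i][j - 1] + GAP_EXTEND,
            )
            k = max(range(3), key=lambda t: opts[t])
            Y[i][j] = opts[k]
            pY[i][j] = k

    best = (NEG, 0, 0, 0)
    for i in range(n + 1):
        for st, mat in enumerate((M, X, Y)):
            v = mat[i][m] + TERM_GAP * (n - i)
            if v > best[0]:
                best = (v, i, m, st)
    for j in range(m + 1):
        for st, mat in enumerate((M, X, Y)):
            v = mat[n][j] + TERM_GAP * (m - j)
            if v > best[0]:
                best = (v, n, j, st)
    score, i, j, state = best
    end_i, end_j = i, j
    ca: list[str] = []
    cb: list[str] = []
    while not (i == 0 and j == 0):
        if state == 0:
            ca.append(a[i - 1])
            cb.append(b[j - 1])
            state = pM[i][j]
            i -= 1
            j -= 1
        elif state == 1:
            if j == 0:
                break
            ca.append(a[i - 1])
            cb.append("-")
            state = pX[i][j]
            i -= 1
        else:
            if i == 0:
                break
            ca.append("-")
            cb.append(b[j - 1])
            state = pY[i][j]
            j -= 1
    aln_a = a[:i] + "-" * j + "".join(reversed(ca)) + a[end_i:] + "-" * (m - end_j)
    aln_b = "-" * i + b[:j] + "".join(reversed(cb)) + "-" * (n - end_i) + b[end_j:]
    return aln_a, aln_b, int(score)


def identity_oracle(a: str, b: str) -> float:
    """Matches / columns with terminal-gap columns trimmed from both ends."""
    aln_a, aln_b, _ = gotoh_align(a, b)
    lo, hi = 0, len(aln_a)
    while lo < hi and (aln_a[lo] == "-" or aln_b[lo] == "-"):
        lo += 1
    while hi > lo and (aln_a[hi - 1] == "-" or aln_b[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    return sum(1 for k in range(lo, hi) if aln_a[k] == aln_b[k]) / (hi - lo)


def score_oracle(a: str, b: str) -> int:
    return gotoh_align(a, b)[2]


# ---------------------------------------------------------------------------
# read merging


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def merge_oracle(
    s1: str, q1: list[int], s2: str, q2: list[int],
    min_overlap: int = 5, max_mismatch_frac: float = 0.25, reject_n: bool = True,
) -> tuple[Optional[tuple[str, list[int], int, int]], Optional[str]]:
    """Score every overlap length, pick best score (ties: longest), build
    the consensus naively."""
    t = revcomp(s2)
    tq = list(reversed(q2))
    n1, n2 = len(s1), len(t)
    best_l, best_score = None, None
    for L in range(min_overlap, min(n1, n2) + 1):
        score = 0
        for k in range(L):
            score += 1 if s1[n1 - L + k] == t[k] else -1
        if best_score is None or score > best_score or (
            score == best_score and L > best_l
        ):
            best_score, best_l = score, L
    if best_l is None:
        return None, "no_overlap"
    L = best_l
    mism = sum(1 for k in range(L) if s1[n1 - L + k] != t[k])
    if mism / L > max_mismatch_frac:
        return None, "too_many_mismatches"
    seq, quals, n_corr = list(s1[: n1 - L]), q1[: n1 - L], 0
    for k in range(L):
        b1, b2, p1, p2 = s1[n1 - L + k], t[k], q1[n1 - L + k], tq[k]
        if b1 == b2:
            seq.append(b1)
            quals.append(min(p1 + p2, 41))
        else:
            n_corr += 1
            if p1 > p2:
                seq.append(b1)
                quals.append(p1 - p2)
            elif p2 > p1:
                seq.append(b2)
                quals.append(p2 - p1)
            else:
                seq.append(b1)
                quals.append(2)
    merged = "".join(seq) + t[L:]
    quals = quals + tq[L:]
    if reject_n and "N" in merged:
        return None, "contains_N"
    return (merged, quals, L, n_corr), None


# ---------------------------------------------------------------------------
# bimera model


def profile_oracle(query: str, parent: str) -> list[int]:
    """Per-query-base match indicator from the oracle alignment."""
    aln_q, aln_p, _ = gotoh_align(query, parent)
    prof = []
    for cq, cp in zip(aln_q, aln_p):
        if cq != "-":
            prof.append(1 if cq == cp else 0)
    assert len(prof) == len(query)
    return prof


def bimera_oracle(
    query: str, parent_a: str, parent_b: str,
    threshold: float = 0.97, model_gain: float = 0.02, min_diffs: int = 3,
) -> tuple[bool, float, float, int]:
    """Exhaustive single-crossover scan in query coordinates.

    Returns (verdict, id_model, id_best_single, crossover). The best model
    is the leftmost best crossover of the better direction (A-left preferred
    on ties), matching the stated convention.
    """
    ma = profile_oracle(query, parent_a)
    mb = profile_oracle(query, parent_b)
    n = len(query)
    best = None  # (matches, -direction, -c): A-left preferred, then leftmost c
    for direction, (ml, mr) in enumerate(((ma, mb), (mb, ma))):
        for c in range(n + 1):
            matches = sum(ml[:c]) + sum(mr[c:])
            key = (matches, -direction, -c)
            if best is None or key > best:
                best = key
    matches, neg_dir, neg_c = best
    direction, c = -neg_dir, -neg_c
    ml, mr = (ma, mb) if direction == 0 else (mb, ma)
    id_model = matches / n
    id_single = max(sum(ma), sum(mb)) / n
    left_diffs = sum(1 for i in range(c) if ml[i] and not mr[i])
    right_diffs = sum(1 for i in range(c, n) if mr[i] and not ml[i])
    verdict = (
        id_model >= threshold
        and id_model - id_single >= model_gain
        and left_diffs >= min_diffs
        and right_diffs >= min_diffs
    )
    return verdict, id_model, id_single, c
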