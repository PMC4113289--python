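"""Paired quality/length filtering and overlap-consensus read merging.

Filtering keeps a pair only when BOTH mates pass the mean-quality and
length thresholds — dropping one mate always drops the other, so the files
stay synchronized for the merger.

Merging scores every candidate overlap length L (from the full mate length
down to ``min_overlap``) between the 3' end of R1 and the 5' end of the
reverse-complemented R2 as matches - mismatches; the best-scoring L wins
(ties: longer overlap). In the overlap, agreeing bases get quality
min(q1+q2, 41); disagreements take the higher-quality basecall with quality
|q1 - q2| (tie: the R1 base at quality 2). A merge is rejected when no
candidate overlap exists, when the best overlap's mismatch fraction exceeds
the cap, or when the merged sequence still contains an N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .seqio import ReadPair, SeqRecord, StageReport, mean_phred, revcomp

QUAL_CAP = 41  # phred+33 'J', the MiSeq-era maximum


@dataclass
class QualityFilterParams:
    mean_q_min: float = 26.0
    len_min: int = 150

    def __post_init__(self) -> None:
        if self.mean_q_min < 0 or self.len_min < 1:
            raise ValueError("invalid quality-filter parameters")


@dataclass
class MergeParams:
    min_overlap: int = 5
    reject_N: bool = True
    max_overlap_mismatch_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class MergedRead:
    """A merged pair: consensus record plus how the overlap was resolved."""

    record: SeqRecord
    overlap_len: int
    n_corrected: int


def quality_filter_pairs(
    pairs: Iterable[ReadPair], params: QualityFilterParams
) -> tuple[list[ReadPair], StageReport]:
    """Keep pairs where both mates satisfy mean quality and length minima."""
    kept: list[ReadPair] = []
    reasons = {"too_short": 0, "low_quality": 0}
    n_in = 0
    for pair in pairs:
        n_in += 1
        if len(pair.r1) < params.len_min or len(pair.r2) < params.len_min:
            reasons["too_short"] += 1
        elif (
            mean_phred(pair.r1.quals) < params.mean_q_min
            or mean_phred(pair.r2.quals) < params.mean_q_min
        ):
            reasons["low_quality"] += 1
        else:
            kept.append(pair)
    report = StageReport(
        "quality_filter", n_in, len(kept), {k: v for k, v in reasons.items() if v}
    )
    return kept, report


def _best_overlap(s1: str, s2rc: str, min_overlap: int) -> Optional[tuple[int, int]]:
    """Highest-scoring overlap length and its match count (ties: longest L).

    Scans L descending with an admissible bound: a length-L overlap scores at
    most L, so once L drops below the best score seen the scan can stop.
    """
    n1, n2 = len(s1), len(s2rc)
    max_l = min(n1, n2)
    if max_l < min_overlap:
        return None
    a = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(s2rc.encode("ascii"), dtype=np.uint8)
    best_score = -(10**9)
    best: Optional[tuple[int, int]] = None
    for L in range(max_l, min_overlap - 1, -1):
        if L < best_score:
            break
        matches = int(np.count_nonzero(a[n1 - L :] == b[:L]))
        score = 2 * matches - L
        if score > best_score:
            best_score, best = score, (L, matches)
    return best


def merge_pair(
    pair: ReadPair, params: MergeParams
) -> tuple[Optional[MergedRead], Optional[str]]:
    """Merge one pair; returns ``(merged, None)`` or ``(None, reason)``."""
    s1, q1 = pair.r1.bases, pair.r1.quals
    s2rc = revcomp(pair.r2.bases)
    q2rc = list(reversed(pair.r2.quals))

    hit = _best_overlap(s1, s2rc, params.min_overlap)
    if hit is None:
        return None, "no_overlap"
    L, matches = hit
    if (L - matches) / L > params.max_overlap_mismatch_frac:
        return None, "too_many_mismatches"

    n1 = len(s1)
    head, head_q = s1[: n1 - L], q1[: n1 - L]
    tail, tail_q = s2rc[L:], q2rc[L:]
    cons: list[str] = []
    cons_q: list[int] = []
    n_corrected = 0
    for k in range(L):
        b1, b2 = s1[n1 - L + k], s2rc[k]
        p1, p2 = q1[n1 - L + k], q2rc[k]
        if b1 == b2:
            cons.append(b1)
            cons_q.append(min(p1 + p2, QUAL_CAP))
        else:
            n_corrected += 1
            if p1 > p2:
                cons.append(b1)
                cons_q.append(p1 - p2)
            elif p2 > p1:
                cons.append(b2)
                cons_q.append(p2 - p1)
            else:
                cons.append(b1)
                cons_q.append(2)
    merged = head + "".join(cons) + tail
    if params.reject_N and "N" in merged:
        return None, "contains_N"
    record = SeqRecord(pair.r1.id, merged, head_q + cons_q + tail_q, desc=pair.r1.desc)
    return MergedRead(record, overlap_len=L, n_corrected=n_corrected), None


def merge_stream(
    pairs: Iterable[ReadPair], params: MergeParams
) -> tuple[list[MergedRead], StageReport]:
    """Merge pairs in order, accounting for every rejection."""
    merged: list[MergedRead] = []
    reasons: dict[str, int] = {}
    n_in = 0
    for pair in pairs:
        n_in += 1
        result, reason = merge_pair(pair, params)
        if result is not None:
            merged.append(result)
        else:
            reasons[reason] = reasons.get(reason, 0) + 1
    return merged, StageReport("merge_pairs", n_in, len(merged), reasons)


def length_distribution(records: Iterable[SeqRecord]) -> dict[int, int]:
    """Two-column length -> count summary (read-length distribution output)."""
    dist: dict[int, int] = {}
    for rec in records:
        dist[len(rec)] = dist.get(len(rec), 0) + 1
    return dict(sorted(dist.items()))
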