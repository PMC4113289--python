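"""Dereplication, abundance sorting and greedy 97% centroid OTU clustering
with de-novo bimera rejection.

The clusterer processes unique sequences in decreasing abundance. Each
unique joins the first centroid (in creation order) it matches at the
identity threshold; otherwise it is tested as a two-parent (bimeric) PCR
chimera of more abundant centroids, and only if that test fails does it
found a new OTU. Processing high-abundance sequences first rests on the
usual amplicon argument: genuine templates outnumber their own chimeras and
error variants, so centroids are in place before their artifacts arrive.

The bimera rule is explicit and auditable. In the query coordinate frame
(per-base match profiles against each parent from global alignments), the
best single-crossover two-parent model must (1) reach the clustering
identity threshold, (2) beat the best single parent by ``model_gain``, and
(3) draw at least ``min_diffs`` diagnostic matches from each side — bases
where one parent matches the query and the other does not. De-novo parents
must be at least ``abundance_skew`` times as abundant as the query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._align import global_identity, match_profile
from .seqio import SeqRecord, StageReport

SIZE_RE = re.compile(r"size=(\d+)")


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its replicate count."""

    bases: str
    size: int
    source_headers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("UniqueSeq size must be >= 1")


@dataclass
class ClusterParams:
    min_size: int = 2
    identity_threshold: float = 0.97
    denovo_chimera: bool = True
    model_gain: float = 0.02
    min_diffs: int = 3
    abundance_skew: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity threshold must lie in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class Centroid:
    """An OTU representative with its absorbed members."""

    representative: str
    size: int
    members: list[UniqueSeq]
    label: Optional[str] = None


@dataclass
class BimeraResult:
    is_bimera: bool
    id_model: float
    id_best_single: float
    crossover: int
    left_is_a: bool


def dereplicate(records: Iterable[SeqRecord]) -> list[UniqueSeq]:
    """Collapse identical full-length sequences (case-insensitive).

    Output order is first-appearance order; the summed sizes equal the input
    read count.
    """
    table: dict[str, UniqueSeq] = {}
    for rec in records:
        key = rec.bases.upper()
        u = table.get(key)
        if u is None:
            table[key] = UniqueSeq(key, 1, [rec.id])
        else:
            u.size += 1
            u.source_headers.append(rec.id)
    return list(table.values())


def sort_by_size(uniques: Sequence[UniqueSeq], min_size: int = 2) -> list[UniqueSeq]:
    """Descending abundance (ties: lexicographic by sequence); drop rares."""
    kept = [u for u in uniques if u.size >= min_size]
    return sorted(kept, key=lambda u: (-u.size, u.bases))


def uniques_to_records(uniques: Sequence[UniqueSeq], prefix: str = "Uniq") -> list[SeqRecord]:
    """FASTA records using the ``;size=N;`` header convention."""
    return [
        SeqRecord(f"{prefix}{i + 1};size={u.size};", u.bases)
        for i, u in enumerate(uniques)
    ]


def is_bimera(
    query: str,
    parent_a: str,
    parent_b: str,
    threshold: float = 0.97,
    model_gain: float = 0.02,
    min_diffs: int = 3,
) -> BimeraResult:
    """Test whether ``query`` fits a single-crossover model of two parents.

    All identities are per-query-base (match profiles projected from the
    pairwise global alignments), so the two-parent model and the single
    parents are compared in one frame.
    """
    ma = match_profile(query, parent_a).astype(np.int64)
    mb = match_profile(query, parent_b).astype(np.int64)
    n = len(query)
    pa = np.concatenate(([0], np.cumsum(ma)))
    pb = np.concatenate(([0], np.cumsum(mb)))
    sa, sb = int(pa[-1]), int(pb[-1])

    # direction 1: parent A on the left; direction 2: parent B on the left
    model_ab = pa[: n + 1] + (sb - pb[: n + 1])
    model_ba = pb[: n + 1] + (sa - pa[: n + 1])
    c_ab = int(np.argmax(model_ab))  # leftmost best crossover
    c_ba = int(np.argmax(model_ba))
    if model_ab[c_ab] >= model_ba[c_ba]:
        left_is_a, c, best_matches = True, c_ab, int(model_ab[c_ab])
        m_left, m_right = ma, mb
    else:
        left_is_a, c, best_matches = False, c_ba, int(model_ba[c_ba])
        m_left, m_right = mb, ma

    id_model = best_matches / n
    id_best_single = max(sa, sb) / n
    left_diffs = int(np.sum(m_left[:c] & ~m_right[:c].astype(bool)))
    right_diffs = int(np.sum(m_right[c:] & ~m_left[c:].astype(bool)))
    verdict = (
        id_model >= threshold
        and id_model - id_best_single >= model_gain
        and left_diffs >= min_diffs
        and right_diffs >= min_diffs
    )
    return BimeraResult(verdict, id_model, id_best_single, c, left_is_a)


def greedy_cluster(
    sorted_uniques: Sequence[UniqueSeq], params: ClusterParams
) -> tuple[list[Centroid], list[tuple[UniqueSeq, BimeraResult, tuple[int, int]]], StageReport]:
    """Greedy centroid clustering of abundance-sorted uniques.

    Returns centroids (creation order), de-novo chimeras with their verdicts
    and parent centroid indices, and the stage accounting over uniques.
    """
    sizes = [u.size for u in sorted_uniques]
    if sizes != sorted(sizes, reverse=True):
        raise ValueError("greedy_cluster requires input sorted by descending size")

    centroids: list[Centroid] = []
    chimeras: list[tuple[UniqueSeq, BimeraResult, tuple[int, int]]] = []
    for u in sorted_uniques:
        joined = False
        for cent in centroids:
            if global_identity(u.bases, cent.representative) >= params.identity_threshold:
                cent.members.append(u)
                cent.size += u.size
                joined = True
                break
        if joined:
            continue
        flagged = None
        if params.denovo_chimera:
            eligible = [
                i for i, cent in enumerate(centroids)
                if cent.size >= params.abundance_skew * u.size
            ]
            for x in range(len(eligible)):
                for y in range(x + 1, len(eligible)):
                    i, j = eligible[x], eligible[y]
                    res = is_bimera(
                        u.bases,
                        centroids[i].representative,
                        centroids[j].representative,
                        params.identity_threshold,
                        params.model_gain,
                        params.min_diffs,
                    )
                    if res.is_bimera:
                        flagged = (res, (i, j))
                        break
                if flagged:
                    break
        if flagged:
            chimeras.append((u, flagged[0], flagged[1]))
        else:
            centroids.append(Centroid(u.bases, u.size, [u]))

    report = StageReport(
        "cluster_otus",
        len(sorted_uniques),
        len(sorted_uniques) - len(chimeras),
        {"denovo_chimera": len(chimeras)} if chimeras else {},
    )
    return centroids, chimeras, report


def centroids_to_records(centroids: Sequence[Centroid], prefix: str = "Centroid") -> list[SeqRecord]:
    return [
        SeqRecord(
            c.label if c.label else f"{prefix}{i + 1};size={c.size};",
            c.representative,
        )
        for i, c in enumerate(centroids)
    ]


def audit_member_identities(centroids: Sequence[Centroid], threshold: float) -> bool:
    """Post-hoc check: every member matches its representative at threshold."""
    return all(
        global_identity(m.bases, c.representative) >= threshold
        for c in centroids
        for m in c.members
    )


def parse_size(header: str) -> Optional[int]:
    m = SIZE_RE.search(header)
    return int(m.group(1)) if m else None
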