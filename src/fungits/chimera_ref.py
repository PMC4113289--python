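"""Reference-based chimera filtering of OTU centroids.

Each centroid is tested as a two-parent chimera whose parents come from a
trusted reference set instead of the de-novo centroid pool. Candidate
parents are found by a chunked 8-mer search: the query is split into
contiguous chunks, each chunk votes for the references sharing the most
8-mers, and the union of the per-chunk top candidates is evaluated with the
same explicit bimera rule used de novo. The chunking matters because a
chimera's halves match *different* references — a whole-query ranking can
miss the minority parent.

The search is plus-strand only: queries must already run 5'->3', and
reverse-complemented chimeras are by design not detected. Reference
sequences carry no abundance, so the de-novo abundance-skew requirement is
waived here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from .clustering import BimeraResult, is_bimera
from .seqio import SeqRecord, StageReport, read_fasta

KMER = 8


@dataclass
class ReferenceDB:
    """In-memory reference set with an 8-mer -> sequence-id index."""

    ids: list[str]
    seqs: list[str]
    kmer_index: dict[str, list[int]]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class UchimeRefParams:
    candidates_per_chunk: int = 4
    n_chunks: int = 4
    threshold: float = 0.97
    model_gain: float = 0.02
    min_diffs: int = 3


@dataclass
class ChimeraVerdict:
    query: str
    parent_a: str
    parent_b: str
    crossover: int
    id_model: float
    id_best_single: float
    verdict: str  # "chimeric" | "clean"

    def __post_init__(self) -> None:
        if self.verdict == "chimeric" and self.id_model <= self.id_best_single:
            raise ValueError("chimeric verdict requires id_model > id_best_single")


def _kmers(seq: str) -> set[str]:
    return {
        seq[i : i + KMER]
        for i in range(len(seq) - KMER + 1)
        if "N" not in seq[i : i + KMER]
    }


def build_refdb(source: Union[str, Path, Iterable[SeqRecord]]) -> ReferenceDB:
    """Index a FASTA file (or records) of trusted plus-strand sequences."""
    records = (
        list(read_fasta(source)) if isinstance(source, (str, Path)) else list(source)
    )
    if not records:
        raise ValueError("empty reference set")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in reference set")
    seqs = [r.bases.upper() for r in records]
    index: dict[str, list[int]] = {}
    for i, seq in enumerate(seqs):
        for kmer in _kmers(seq):
            index.setdefault(kmer, []).append(i)
    return ReferenceDB(ids, seqs, index)


def _chunk_candidates(query: str, db: ReferenceDB, params: UchimeRefParams) -> list[int]:
    """Union of per-chunk top references by shared-8-mer count."""
    n = len(query)
    chunk_len = max(n // params.n_chunks, KMER)
    candidates: list[int] = []
    for c in range(params.n_chunks):
        lo = c * chunk_len
        hi = n if c == params.n_chunks - 1 else min((c + 1) * chunk_len, n)
        if hi - lo < KMER:
            continue
        counts: dict[int, int] = {}
        for kmer in _kmers(query[lo:hi]):
            for rid in db.kmer_index.get(kmer, ()):
                counts[rid] = counts.get(rid, 0) + 1
        top = sorted(counts, key=lambda rid: (-counts[rid], rid))
        for rid in top[: params.candidates_per_chunk]:
            if rid not in candidates:
                candidates.append(rid)
    return sorted(candidates)


def uchime_ref(
    centroids: Sequence[SeqRecord],
    db: ReferenceDB,
    params: UchimeRefParams = UchimeRefParams(),
) -> tuple[list[SeqRecord], list[SeqRecord], list[ChimeraVerdict], StageReport]:
    """Partition centroids into clean and chimeric against the references."""
    if len(db) == 0:
        raise ValueError("empty reference database")
    clean: list[SeqRecord] = []
    chimeric: list[SeqRecord] = []
    verdicts: list[ChimeraVerdict] = []
    for rec in centroids:
        query = rec.bases.upper()
        cands = _chunk_candidates(query, db, params)
        best: tuple[BimeraResult, int, int] | None = None
        for x in range(len(cands)):
            for y in range(x + 1, len(cands)):
                i, j = cands[x], cands[y]
                res = is_bimera(
                    query, db.seqs[i], db.seqs[j],
                    params.threshold, params.model_gain, params.min_diffs,
                )
                if res.is_bimera and (best is None or res.id_model > best[0].id_model):
                    best = (res, i, j)
        if best is None:
            clean.append(rec)
            verdicts.append(
                ChimeraVerdict(rec.id, "", "", -1, 0.0, 0.0, "clean")
            )
        else:
            res, i, j = best
            chimeric.append(rec)
            pa, pb = (i, j) if res.left_is_a else (j, i)
            verdicts.append(
                ChimeraVerdict(
                    rec.id, db.ids[pa], db.ids[pb], res.crossover,
                    res.id_model, res.id_best_single, "chimeric",
                )
            )
    report = StageReport(
        "uchime_ref", len(centroids), len(clean),
        {"ref_chimera": len(chimeric)} if chimeric else {},
    )
    return clean, chimeric, verdicts, report
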