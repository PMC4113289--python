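"""OTU relabeling, read->OTU mapping, and the OTU x sample abundance table.

The original (pre-dereplication) ITS2 reads — including singletons that
never entered clustering — are mapped back against the fungal OTU
representatives at the clustering identity, so table totals can exceed the
summed centroid sizes. Mapping is plus-strand only and deterministic: the
best-identity OTU wins, ties break to the lower OTU index.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._align import global_identity
from .clustering import parse_size
from .seqio import SeqRecord, StageReport

SAMPLE_RE = re.compile(r"^sample=([^;]+);")


def relabel_otus(
    records: Sequence[SeqRecord], prefix: str = "OTU_"
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Relabel OTUs ``OTU_1..OTU_n`` by descending ``;size=N;`` annotation.

    Ties break lexicographically by sequence. When any record lacks a size
    annotation the original order of appearance is used instead (warned).
    """
    if not records:
        raise ValueError("no OTUs to relabel")
    sizes = [parse_size(r.header) for r in records]
    if any(s is None for s in sizes):
        warnings.warn("missing size annotation; keeping order of appearance")
        order = list(range(len(records)))
    else:
        order = sorted(range(len(records)), key=lambda i: (-sizes[i], records[i].bases))
    relabeled: list[SeqRecord] = []
    mapping: dict[str, str] = {}
    for new_idx, old_idx in enumerate(order):
        old = records[old_idx]
        label = f"{prefix}{new_idx + 1}"
        mapping[old.id] = label
        relabeled.append(SeqRecord(label, old.bases))
    return relabeled, mapping


@dataclass
class MappedRead:
    read_id: str
    sample: str
    otu: Optional[str]  # None = unmapped
    identity: float


def map_reads(
    reads: Iterable[SeqRecord],
    otus: Sequence[SeqRecord],
    id_threshold: float = 0.97,
) -> tuple[list[MappedRead], StageReport]:
    """Assign each read to its best-identity OTU at the threshold.

    Read headers must carry the ``sample=NAME;`` prefix written at pooling.
    Identities are memoised per distinct read sequence — amplicon reads are
    massively replicated.
    """
    cache: dict[str, tuple[Optional[int], float]] = {}
    mapped: list[MappedRead] = []
    reasons = {"below_threshold": 0, "no_otus": 0}
    n_in = 0
    n_kept = 0
    for rec in reads:
        n_in += 1
        m = SAMPLE_RE.match(rec.id)
        if not m:
            raise ValueError(f"read {rec.id!r} lacks the sample=NAME; annotation")
        sample = m.group(1)
        key = rec.bases.upper()
        if key not in cache:
            if not otus:
                cache[key] = (None, 0.0)
            else:
                idents = [global_identity(key, o.bases) for o in otus]
                best_i = max(range(len(otus)), key=lambda i: (idents[i], -i))
                if idents[best_i] >= id_threshold:
                    cache[key] = (best_i, idents[best_i])
                else:
                    cache[key] = (None, idents[best_i])
        best_i, ident = cache[key]
        if best_i is None:
            reasons["no_otus" if not otus else "below_threshold"] += 1
            mapped.append(MappedRead(rec.id, sample, None, ident))
        else:
            n_kept += 1
            mapped.append(MappedRead(rec.id, sample, otus[best_i].id, ident))
    report = StageReport(
        "map_reads", n_in, n_kept, {k: v for k, v in reasons.items() if v}
    )
    return mapped, report


def build_table(
    readmap: Sequence[MappedRead],
    otu_labels: Sequence[str],
    sample_names: Sequence[str],
) -> pd.DataFrame:
    """Counts[otu, sample] over mapped reads; fixed row/column order."""
    table = pd.DataFrame(0, index=list(otu_labels), columns=list(sample_names), dtype=int)
    for mr in readmap:
        if mr.otu is not None:
            table.loc[mr.otu, mr.sample] += 1
    return table


def audit_sums(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Row (per-OTU) and column (per-sample) read sums for eyeballing."""
    return table.sum(axis=1), table.sum(axis=0)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited table with the conventional ``#OTU ID`` first column."""
    out = table.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")
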