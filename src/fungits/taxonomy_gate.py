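"""Lowest-common-ancestor taxonomy gating of OTUs from tabular homology hits.

The homology search itself (e.g. blastn against a nucleotide database) is
external; this module consumes its tabular output — one row per hit with a
root->leaf lineage path — applies the LCA parameterization used for
Illumina paired-end amplicons (minimum bitscore 170, hits within 5% of the
best score, minimum support 1), and keeps only OTUs whose assignment passes
through the Fungi node.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .seqio import SeqRecord

UNASSIGNED = "No hits/unassigned"


@dataclass
class TaxHit:
    query: str
    lineage: list[str]  # root -> leaf
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError(f"hit for {self.query}: empty lineage")
        if self.bitscore < 0:
            raise ValueError(f"hit for {self.query}: negative bitscore")


@dataclass
class LcaParams:
    min_score: float = 170.0
    top_percent: float = 5.0
    min_support: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.top_percent <= 100.0:
            raise ValueError("top_percent must lie in [0, 100]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def read_hits(path: str | Path) -> dict[str, list[TaxHit]]:
    """Read a TSV of hits: columns qseqid, lineage (';'-joined), bitscore, evalue."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["qseqid", "lineage", "bitscore", "evalue"],
        dtype={"qseqid": str, "lineage": str},
    )
    if len(df) and df.iloc[0]["qseqid"] == "qseqid":  # tolerate a header row
        df = df.iloc[1:]
    hits: dict[str, list[TaxHit]] = {}
    for row in df.itertuples(index=False):
        hit = TaxHit(
            str(row.qseqid),
            [n.strip() for n in str(row.lineage).split(";") if n.strip()],
            float(row.bitscore),
            float(row.evalue),
        )
        hits.setdefault(hit.query, []).append(hit)
    return hits


def _common_prefix(paths: Sequence[list[str]]) -> list[str]:
    prefix = list(paths[0])
    for p in paths[1:]:
        k = 0
        while k < len(prefix) and k < len(p) and prefix[k] == p[k]:
            k += 1
        prefix = prefix[:k]
    return prefix


def lca_assign(
    hits_per_query: dict[str, list[TaxHit]], params: LcaParams = LcaParams()
) -> dict[str, Optional[list[str]]]:
    """Assign each query to the LCA of its score-filtered hits.

    Hits below ``min_score`` are dropped; of the rest only hits within
    ``top_percent`` of the best bitscore vote. The assignment is the longest
    common prefix of the voting lineages (``None`` when no hit survives).
    Nodes supported by fewer than ``min_support`` queries push their queries
    one level up until support suffices.
    """
    assignments: dict[str, Optional[list[str]]] = {}
    for query, hits in hits_per_query.items():
        strong = [h for h in hits if h.bitscore >= params.min_score]
        if not strong:
            assignments[query] = None
            continue
        best = max(h.bitscore for h in strong)
        voting = [h for h in strong if h.bitscore >= (1 - params.top_percent / 100) * best]
        prefix = _common_prefix([h.lineage for h in voting])
        assignments[query] = prefix if prefix else None

    if params.min_support > 1:
        changed = True
        while changed:
            changed = False
            support: dict[tuple[str, ...], int] = {}
            for lin in assignments.values():
                if lin:
                    for k in range(1, len(lin) + 1):
                        node = tuple(lin[:k])
                        support[node] = support.get(node, 0) + 1
            for query, lin in assignments.items():
                if lin and support[tuple(lin)] < params.min_support:
                    assignments[query] = lin[:-1] if len(lin) > 1 else None
                    changed = True
    return assignments


def filter_fungal(
    otus: Iterable[SeqRecord],
    assignments: dict[str, Optional[list[str]]],
) -> tuple[list[SeqRecord], list[SeqRecord], pd.Series]:
    """Keep OTUs whose lineage contains the Fungi node; tally the rest.

    The tally groups excluded OTUs by the lineage node below the root (e.g.
    Viridiplantae from ``Eukaryota;Viridiplantae;...``); OTUs without an
    assignment fall under ``No hits/unassigned``.
    """
    fungal: list[SeqRecord] = []
    excluded: list[SeqRecord] = []
    tally: dict[str, int] = {}
    for rec in otus:
        lineage = assignments.get(rec.id)
        if lineage and "Fungi" in lineage:
            fungal.append(rec)
            tally["Fungi"] = tally.get("Fungi", 0) + 1
        else:
            excluded.append(rec)
            if not lineage:
                group = UNASSIGNED
            elif len(lineage) >= 2:
                group = lineage[1]
            else:
                group = lineage[0]
            tally[group] = tally.get(group, 0) + 1
    return fungal, excluded, pd.Series(tally, dtype=int).sort_index()
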