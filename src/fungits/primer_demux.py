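"""Primer-artifact removal, 5'->3' reorientation, dual-tag demultiplexing,
sample pooling and primer/label trimming.

The dual-label design puts the same 8-bp tag on both ends of every
amplicon; a read is assigned to a sample only when tag+primer match
perfectly at the 5' end AND the reverse complement of tag+primer matches at
the 3' end. Requiring both ends is what defuses tag switching: a read whose
two tags disagree matches no sample and is dropped. Patterns are anchored
(prefix/suffix) by default — stricter than grep-anywhere semantics and
immune to internal hits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional


from .its_extract import mismatch_counts
from .seqio import SeqRecord, StageReport, revcomp

_ACGT = set("ACGT")


@dataclass
class PrimerSet:
    """Forward/reverse PCR primers.

    Exact-match operations (multi-primer screening, demultiplex patterns)
    require plain ACGT; the mismatch-tolerant orientation search also accepts
    IUPAC ambiguity codes.
    """

    fwd: str
    rev: str
    search_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.fwd or not self.rev:
            raise ValueError("both primers must be nonempty")
        self.fwd = self.fwd.upper()
        self.rev = self.rev.upper()

    def require_exact(self) -> None:
        for name, p in (("forward", self.fwd), ("reverse", self.rev)):
            if not set(p) <= _ACGT:
                raise ValueError(
                    f"{name} primer contains ambiguity codes; exact-match "
                    f"operations need plain ACGT: {p}"
                )


@dataclass
class SampleSheet:
    """sample -> tag table with derived anchored demultiplex patterns."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        tags = [t.upper() for _, t in self.entries]
        self.entries = list(zip(names, tags))
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample name in sheet")
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate tag in sheet")
        if len({len(t) for t in tags}) > 1:
            raise ValueError("tags must all have the same length")
        for t in tags:
            if not set(t) <= _ACGT:
                raise ValueError(f"tag {t!r} is not plain ACGT")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        entries: list[tuple[str, str]] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                if row[0].strip().lower() == "name":  # header line
                    continue
                entries.append((row[0].strip(), row[1].strip().upper()))
        if not entries:
            raise ValueError(f"empty sample sheet: {path}")
        return cls(entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def tag_len(self) -> int:
        return len(self.entries[0][1])

    def patterns(self, primers: PrimerSet) -> list[tuple[str, str, str]]:
        """Per sample: (name, 5' prefix tag+fwd, 3' suffix rc(tag+rev))."""
        primers.require_exact()
        return [
            (name, tag + primers.fwd, revcomp(tag + primers.rev))
            for name, tag in self.entries
        ]


@dataclass
class TrimParams:
    head: int = 26  # tag (8) + primer (18) in the default design
    tail: int = 26

    def __post_init__(self) -> None:
        if self.head < 0 or self.tail < 0:
            raise ValueError("trim lengths must be >= 0")


def count_occurrences(seq: str, sub: str) -> int:
    """Occurrences of ``sub`` in ``seq``, counting overlapping hits."""
    n, start = 0, 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def remove_multiprimer(
    reads: Iterable[SeqRecord], primers: PrimerSet
) -> tuple[list[SeqRecord], StageReport]:
    """Drop reads carrying more than one copy of either primer (any strand).

    A clean merged amplicon shows each primer exactly once; extra internal
    copies are PCR artifacts of roughly amplicon length that survive naive
    length checks and must go before demultiplexing.
    """
    primers.require_exact()
    f, rf = primers.fwd, revcomp(primers.fwd)
    r, rr = primers.rev, revcomp(primers.rev)
    kept: list[SeqRecord] = []
    n_in = 0
    n_multi = 0
    for rec in reads:
        n_in += 1
        seq = rec.bases
        if (
            count_occurrences(seq, f) + count_occurrences(seq, rf) <= 1
            and count_occurrences(seq, r) + count_occurrences(seq, rr) <= 1
        ):
            kept.append(rec)
        else:
            n_multi += 1
    report = StageReport(
        "remove_multiprimer", n_in, len(kept),
        {"multiprimer": n_multi} if n_multi else {},
    )
    return kept, report


def _contains(seq: str, pattern: str, max_mm: int) -> bool:
    if max_mm == 0 or pattern in seq:  # exact fast path
        return pattern in seq
    mm = mismatch_counts(seq, pattern)
    return bool(mm.size and int(mm.min()) <= max_mm)


def orient_reads(
    reads: Iterable[SeqRecord], primers: PrimerSet, mismatches: int = 1
) -> tuple[list[SeqRecord], StageReport]:
    """Flip reverse-strand reads so everything runs 5'->3'.

    Strand evidence is the forward primer found (within ``mismatches``
    substitutions) on the read or on its reverse complement; reads with no
    evidence, or with evidence on both strands, are discarded.
    """
    kept: list[SeqRecord] = []
    reasons = {"no_primer": 0, "ambiguous": 0}
    n_in = 0
    for rec in reads:
        n_in += 1
        fwd_hit = _contains(rec.bases, primers.fwd, mismatches)
        rc = revcomp(rec.bases)
        rev_hit = _contains(rc, primers.fwd, mismatches)
        if fwd_hit and not rev_hit:
            kept.append(rec)
        elif rev_hit and not fwd_hit:
            quals = None if rec.quals is None else list(reversed(rec.quals))
            kept.append(SeqRecord(rec.id, rc, quals, desc=rec.desc))
        elif fwd_hit and rev_hit:
            reasons["ambiguous"] += 1
        else:
            reasons["no_primer"] += 1
    report = StageReport(
        "orient_reads", n_in, len(kept), {k: v for k, v in reasons.items() if v}
    )
    return kept, report


def demultiplex(
    reads: Iterable[SeqRecord],
    sheet: SampleSheet,
    primers: PrimerSet,
    anchored: bool = True,
) -> tuple[dict[str, list[SeqRecord]], list[SeqRecord], StageReport]:
    """Assign reads to samples by perfect tag+primer matches on BOTH ends.

    ``anchored=False`` restores grep-anywhere semantics (the pattern may sit
    anywhere in the read); the default demands prefix/suffix placement.
    """
    patterns = sheet.patterns(primers)
    by_prefix = {p5: (name, p3) for name, p5, p3 in patterns}
    p5_len = len(patterns[0][1])
    assigned: dict[str, list[SeqRecord]] = {name: [] for name, _, _ in patterns}
    unassigned: list[SeqRecord] = []
    n_in = 0
    for rec in reads:
        n_in += 1
        target: Optional[str] = None
        if anchored:
            hit = by_prefix.get(rec.bases[:p5_len])
            if hit is not None and rec.bases.endswith(hit[1]):
                target = hit[0]
        else:
            for name, p5, p3 in patterns:
                if p5 in rec.bases and p3 in rec.bases:
                    target = name
                    break
        if target is None:
            unassigned.append(rec)
        else:
            assigned[target].append(rec)
    n_kept = n_in - len(unassigned)
    report = StageReport(
        "demultiplex", n_in, n_kept,
        {"unassigned": len(unassigned)} if unassigned else {},
    )
    return assigned, unassigned, report


def pool_and_trim(
    sample_map: dict[str, list[SeqRecord]],
    trim: TrimParams,
    sample_order: Optional[list[str]] = None,
) -> list[SeqRecord]:
    """Pool samples (sheet order), tag headers ``sample=NAME;<id>``, trim ends."""
    order = sample_order if sample_order is not None else list(sample_map)
    pooled: list[SeqRecord] = []
    for name in order:
        for rec in sample_map.get(name, []):
            if len(rec) <= trim.head + trim.tail:
                raise ValueError(
                    f"read {rec.id} (len {len(rec)}) too short to trim "
                    f"{trim.head}+{trim.tail}"
                )
            end = len(rec) - trim.tail
            pooled.append(
                SeqRecord(f"sample={name};{rec.id}", rec.bases[trim.head : end])
            )
    return pooled
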