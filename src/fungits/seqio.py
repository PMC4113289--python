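"""Sequence records and bit-exact FASTA/FASTQ I/O shared by every pipeline stage.

Quality scores are fixed to the phred+33 convention of MiSeq-era FASTQ.
Other offsets are rejected rather than auto-detected: silent auto-detection
of a wrong offset corrupts every downstream quality decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
_DNA = set("ACGTN")
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PathLike = Union[str, Path]


class FastqFormatError(ValueError):
    """Malformed FASTQ record or non-phred+33 quality character."""


@dataclass
class SeqRecord:
    """A DNA sequence with optional per-base phred qualities.

    ``id`` is the first whitespace-delimited token of the header; ``desc``
    holds the remainder (empty string when absent).
    """

    id: str
    bases: str
    quals: Optional[list[int]] = None
    desc: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.bases:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise FastqFormatError(
                f"record {self.id}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def header(self) -> str:
        return f"{self.id} {self.desc}" if self.desc else self.id


@dataclass
class ReadPair:
    """Synchronized forward/reverse mates; both must carry qualities."""

    r1: SeqRecord
    r2: SeqRecord

    def __post_init__(self) -> None:
        if self.r1.quals is None or self.r2.quals is None:
            raise ValueError("both mates of a ReadPair need quality scores")
        if _stem(self.r1.id) != _stem(self.r2.id):
            warnings.warn(
                f"mate ids differ beyond /1 //2 suffix: "
                f"{self.r1.id!r} vs {self.r2.id!r}",
                stacklevel=2,
            )


def _stem(read_id: str) -> str:
    for suffix in ("/1", "/2", ".1", ".2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


@dataclass
class StageReport:
    """Per-stage read/cluster accounting: what came in, what survived, why not.

    The conservation invariant ``n_in == n_kept + n_discarded`` (with reason
    counts summing to ``n_discarded``) is enforced on construction, so any
    stage that loses track of a read fails immediately.
    """

    stage: str
    n_in: int
    n_kept: int
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + self.n_discarded:
            raise ValueError(
                f"stage {self.stage}: n_in={self.n_in} != "
                f"n_kept={self.n_kept} + discarded={self.n_discarded}"
            )
        if any(v < 0 for v in self.reasons.values()) or self.n_kept < 0:
            raise ValueError(f"stage {self.stage}: negative count")

    @property
    def n_discarded(self) -> int:
        return sum(self.reasons.values())

    def as_row(self) -> dict[str, object]:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
            "reasons": ";".join(f"{k}={v}" for k, v in sorted(self.reasons.items()))
            or "-",
        }


# ---------------------------------------------------------------------------
# reading


def _decode_quals(qual_str: str, where: str) -> list[int]:
    quals = [ord(c) - PHRED_OFFSET for c in qual_str]
    if any(q < 0 for q in quals):
        raise FastqFormatError(f"{where}: quality character below phred+33 range")
    return quals


def read_fastq(path: PathLike) -> Iterator[SeqRecord]:
    """Stream records of a 4-line-per-record, phred+33 FASTQ file."""
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise FastqFormatError(
                        f"{path}: record {title.split()[0]}: base/quality length mismatch"
                    )
                tokens = title.split(maxsplit=1)
                yield SeqRecord(
                    id=tokens[0],
                    desc=tokens[1] if len(tokens) > 1 else "",
                    bases=seq.upper(),
                    quals=_decode_quals(qual, f"{path}: {tokens[0]}"),
                )
        except ValueError as exc:  # Biopython signals malformed records this way
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(f"{path}: {exc}") from exc


def read_fasta(path: PathLike) -> Iterator[SeqRecord]:
    """Stream FASTA records; multi-line sequences are accepted."""
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            tokens = title.split(maxsplit=1)
            yield SeqRecord(
                id=tokens[0],
                desc=tokens[1] if len(tokens) > 1 else "",
                bases=seq.upper(),
            )


def read_fastq_pairs(path_r1: PathLike, path_r2: PathLike) -> Iterator[ReadPair]:
    """Pair the i-th record of each file; error when the files desynchronize.

    Pairing is positional (the merger's contract); differing id stems only
    warn, they do not abort.
    """
    it1, it2 = read_fastq(path_r1), read_fastq(path_r2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            longer = path_r2 if r1 is None else path_r1
            raise FastqFormatError(
                f"paired FASTQ files desynchronized after {n} pairs: "
                f"{longer} has extra records"
            )
        n += 1
        yield ReadPair(r1, r2)


# ---------------------------------------------------------------------------
# writing


def _phred_string(quals: Sequence[int]) -> str:
    return "".join(chr(min(q, 93) + PHRED_OFFSET) for q in quals)


def write_fastq(records: Iterable[SeqRecord], path: PathLike) -> int:
    """Write canonical 4-line FASTQ; round-trips byte-for-byte."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"record {rec.id}: FASTQ output requires qualities")
            out.write(f"@{rec.header}\n{rec.bases}\n+\n{_phred_string(rec.quals)}\n")
            n += 1
    return n


def write_fasta(records: Iterable[SeqRecord], path: PathLike) -> int:
    """Write single-line-sequence FASTA (qualities, if any, are dropped)."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.header}\n{rec.bases}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# small sequence utilities


def revcomp(bases: str) -> str:
    """Reverse complement over the A,C,G,T,N alphabet (involution; N -> N)."""
    if not set(bases.upper()) <= _DNA:
        bad = sorted(set(bases.upper()) - _DNA)
        raise ValueError(f"non-IUPAC character(s) in sequence: {bad}")
    return bases.translate(_RC)[::-1]


def mean_phred(quals: Sequence[int]) -> float:
    """Arithmetic mean of integer phred scores."""
    if len(quals) == 0:
        raise ValueError("mean_phred of empty quality list")
    return sum(quals) / len(quals)
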