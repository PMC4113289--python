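"""Extraction of the hypervariable ITS2 from conserved flanking anchors.

ITS2 amplicons carry conserved 5.8S / LSU stretches around the variable
spacer. Left in place, those stretches inflate pairwise similarity and bias
both clustering and database searches, so they are located here via IUPAC
anchor motifs and cut away; reads that do not fit the structural model
(anchor missing, or spacer implausibly short) are diverted to a discard
stream. Anchor motifs are configuration data (``data/anchors.yaml``), not
code — swap them to target other marker designs.

Coordinates are 0-based half-open: the extracted spacer runs from the first
base after the 5' motif match to the base before the 3' motif match.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import yaml

from .seqio import SeqRecord, StageReport

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15}


def _pattern_bits(motif: str) -> np.ndarray:
    try:
        return np.array(
            [sum(_BITS[b] for b in IUPAC[c]) for c in motif.upper()],
            dtype=np.uint8,
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc} in motif {motif!r}") from exc


def _seq_bits(seq: str) -> np.ndarray:
    bits = np.zeros(len(seq), dtype=np.uint8)
    for base, bit in _BITS.items():
        bits[np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)] |= bit
    return bits


def mismatch_counts(seq: str, motif: str) -> np.ndarray:
    """Mismatches of ``motif`` at every start position of ``seq`` (IUPAC-aware)."""
    sb = _seq_bits(seq.upper())
    pb = _pattern_bits(motif)
    if len(sb) < len(pb):
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(sb, len(pb))
    return np.count_nonzero((windows & pb) == 0, axis=1)


@dataclass
class AnchorModel:
    """Structural model: motif lists flanking the ITS2 plus search limits."""

    motifs_5p: list[str]
    motifs_3p: list[str]
    max_mismatches: int = 1
    search_window_5p: int = 80
    search_window_3p: int = 80
    min_its2_len: int = 30

    def __post_init__(self) -> None:
        for m in self.motifs_5p + self.motifs_3p:
            if len(m) < 8:
                raise ValueError(f"anchor motif too short (<8 bp): {m!r}")
            _pattern_bits(m)
        if self.search_window_5p < max(len(m) for m in self.motifs_5p):
            raise ValueError("5' search window shorter than motif")
        if self.search_window_3p < max(len(m) for m in self.motifs_3p):
            raise ValueError("3' search window shorter than motif")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnchorModel":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_model() -> AnchorModel:
    """The packaged anchor model (also used by the read simulator)."""
    text = resources.files("fungits").joinpath("data/anchors.yaml").read_text()
    return AnchorModel(**yaml.safe_load(text))


def find_anchor(
    seq: str,
    motifs: Iterable[str],
    max_mm: int,
    window: int,
    end: Literal["5p", "3p"],
) -> Optional[tuple[int, int]]:
    """Best anchor hit within ``window`` bases of the given read end.

    Best = fewest mismatches, then outermost (closest to the read end), then
    motif list order. Returns ``(start, motif_length)`` or ``None``.
    """
    best_key: Optional[tuple[int, int]] = None  # (mismatches, outermost rank)
    best_hit: Optional[tuple[int, int]] = None  # (start, motif_len)
    n = len(seq)
    for motif in motifs:
        mm = mismatch_counts(seq, motif)
        if mm.size == 0:
            continue
        if end == "5p":
            hi = min(window - len(motif), mm.size - 1)
            positions = range(0, hi + 1)  # rank 0 = leftmost
        else:
            lo = max(0, n - window)
            positions = range(mm.size - 1, lo - 1, -1)  # rank 0 = rightmost
        for rank, p in enumerate(positions):
            if mm[p] <= max_mm:
                key = (int(mm[p]), rank)
                if best_key is None or key < best_key:
                    best_key, best_hit = key, (p, len(motif))
                if mm[p] == 0:
                    break  # later positions for this motif are more inward
    return best_hit


def extract_its2(
    reads: Iterable[SeqRecord], model: AnchorModel
) -> tuple[list[SeqRecord], list[SeqRecord], StageReport]:
    """Cut the ITS2 between the anchors; divert non-conforming reads."""
    kept: list[SeqRecord] = []
    discarded: list[SeqRecord] = []
    reasons = {"no_5p_anchor": 0, "no_3p_anchor": 0, "too_short": 0}
    n_in = 0
    for rec in reads:
        n_in += 1
        hit5 = find_anchor(
            rec.bases, model.motifs_5p, model.max_mismatches,
            model.search_window_5p, "5p",
        )
        if hit5 is None:
            reasons["no_5p_anchor"] += 1
            discarded.append(rec)
            continue
        hit3 = find_anchor(
            rec.bases, model.motifs_3p, model.max_mismatches,
            model.search_window_3p, "3p",
        )
        if hit3 is None:
            reasons["no_3p_anchor"] += 1
            discarded.append(rec)
            continue
        e5 = hit5[0] + hit5[1]
        s3 = hit3[0]
        if s3 - e5 < model.min_its2_len:
            reasons["too_short"] += 1
            discarded.append(rec)
            continue
        kept.append(SeqRecord(rec.id, rec.bases[e5:s3], desc=rec.desc))
    report = StageReport(
        "extract_its2", n_in, len(kept), {k: v for k, v in reasons.items() if v}
    )
    return kept, discarded, report
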