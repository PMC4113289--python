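"""Ground-truthed simulation of dual-tagged paired-end ITS2 amplicon runs.

Amplicons follow the dual-label design used for MiSeq fungal metabarcoding:
the same 8-bp sample tag sits at both ends, inside it the PCR primers, then
conserved rRNA flanks (5.8S tail / LSU head) around a hypervariable ITS2
core::

    tag + primer_fwd + anchor_5p + ITS2 + anchor_3p + rc(primer_rev) + rc(tag)

Reads are emitted as 2x250 pairs with ~50/50 random strand orientation,
uniform per-base substitution error (constant phred quality consistent with
the error rate), plus three injectable artifact classes: single-crossover
bimeric chimeras (within-sample parents, breakpoint in the middle 60% of the
ITS2), multi-primer artifacts (an extra internal primer copy at constant
length), and tag corruption / tag switching for demultiplexing stress tests.
Every read is recorded in a per-read ground-truth table together with the
OTU x sample table an ideal pipeline run should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .its_extract import default_model
from ._align import global_identity
from .seqio import SeqRecord, revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: fixed pool of mutually distinct 8-bp sample tags (dual-label design)
DEFAULT_TAGS = [
    "ACACACGT", "CGTGTACA", "GTCAGCAT", "TACGATCG", "ATGCTGCA",
    "CAGTAGTC", "GACTCATG", "TGTACGAC", "AGCATCTG", "CTGACTGA",
]

_DEF_MODEL = default_model()
DEFAULT_ANCHOR_5P = _DEF_MODEL.motifs_5p[0]
DEFAULT_ANCHOR_3P = _DEF_MODEL.motifs_3p[0]
DEFAULT_PRIMER_FWD = "GTGAATCATCGAATCTTT"  # 18 bp, tag+primer = 26 bp
DEFAULT_PRIMER_REV = "TCCTCCGCTTATTGATAT"  # 18 bp


def default_samples(n: int) -> list[tuple[str, str]]:
    if n > len(DEFAULT_TAGS):
        raise ValueError(f"only {len(DEFAULT_TAGS)} built-in tags available")
    return [(f"S{i + 1:02d}", DEFAULT_TAGS[i]) for i in range(n)]


@dataclass
class SimConfig:
    """Study-design parameters of a simulated sequencing run."""

    n_species: int = 10
    its2_len: tuple[int, int] = (180, 260)
    species_min_divergence: float = 0.10
    anchor_5p: str = DEFAULT_ANCHOR_5P
    anchor_3p: str = DEFAULT_ANCHOR_3P
    primer_fwd: str = DEFAULT_PRIMER_FWD
    primer_rev: str = DEFAULT_PRIMER_REV
    samples: list[tuple[str, str]] = field(default_factory=lambda: default_samples(5))
    reads_per_sample: int = 2000
    read_len: int = 250
    per_base_error: float = 0.001
    chimera_rate: float = 0.02
    multiprimer_rate: float = 0.01
    revorient_prob: float = 0.5
    tag_error_rate: float = 0.0
    tag_switch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        tags = [t for _, t in self.samples]
        if len(set(tags)) != len(tags):
            raise ValueError("sample tags must be unique")
        if len({len(t) for t in tags}) > 1:
            raise ValueError("sample tags must share one length")
        for name, rate in [
            ("per_base_error", self.per_base_error),
            ("chimera_rate", self.chimera_rate),
            ("multiprimer_rate", self.multiprimer_rate),
            ("revorient_prob", self.revorient_prob),
            ("tag_error_rate", self.tag_error_rate),
            ("tag_switch_rate", self.tag_switch_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {rate}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.its2_len[0] > self.its2_len[1] or self.its2_len[0] < 1:
            raise ValueError(f"invalid its2_len range {self.its2_len}")

    @property
    def tag_len(self) -> int:
        return len(self.samples[0][1])

    @property
    def head_trim(self) -> int:
        return self.tag_len + len(self.primer_fwd)

    @property
    def tail_trim(self) -> int:
        return self.tag_len + len(self.primer_rev)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "samples" in raw:
            raw["samples"] = [tuple(s) for s in raw["samples"]]
        if "its2_len" in raw:
            raw["its2_len"] = tuple(raw["its2_len"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What was put into the reads, per read and in aggregate."""

    reads: pd.DataFrame  # read_id, sample, kind, species, orientation, tag_status, breakpoint
    species: dict[str, str]  # species id -> true ITS2 core
    expected_table: pd.DataFrame  # species x sample counts of cleanly recoverable reads


@dataclass
class SimResult:
    config: SimConfig
    r1: list[SeqRecord]
    r2: list[SeqRecord]
    truth: GroundTruth


def _random_core(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def make_species(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list[str]:
    """Draw ITS2 cores whose pairwise identities stay below 1 - min_divergence.

    The check uses the same global identity function as OTU clustering, so a
    simulated community is divergent in exactly the sense the clusterer sees.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    max_ident = 1.0 - cfg.species_min_divergence
    cores: list[str] = []
    lo, hi = cfg.its2_len
    for _ in range(cfg.n_species):
        for _attempt in range(60):
            cand = _random_core(rng, int(rng.integers(lo, hi + 1)))
            if all(global_identity(cand, c) <= max_ident for c in cores):
                cores.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw {cfg.n_species} species at "
                f">={cfg.species_min_divergence:.0%} divergence"
            )
    return cores


def make_amplicon(core: str, tag: str, cfg: SimConfig, tag3: Optional[str] = None) -> str:
    """Full dual-tagged amplicon around an ITS2 core (same tag both ends)."""
    tag3 = tag if tag3 is None else tag3
    return (
        tag + cfg.primer_fwd + cfg.anchor_5p + core + cfg.anchor_3p
        + revcomp(cfg.primer_rev) + revcomp(tag3)
    )


def _mutate(seq: str, rng: np.random.Generator, e: float) -> str:
    if e <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < e)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _corrupt_tag(tag: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(tag)))
    alt = rng.choice(_BASES[_BASES != ord(tag[pos])])
    return tag[:pos] + chr(alt) + tag[pos + 1 :]


def phred_for_error_rate(e: float) -> int:
    """Constant quality consistent with a uniform substitution rate."""
    if e <= 0.0:
        return 40
    return int(min(40, max(2, round(-10.0 * math.log10(e)))))


def simulate_reads(cfg: SimConfig) -> SimResult:
    """Emit R1/R2 read pairs for every sample, plus the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    cores = make_species(cfg, rng)
    species_ids = [f"sp{k + 1:02d}" for k in range(cfg.n_species)]
    q = phred_for_error_rate(cfg.per_base_error)

    min_amplicon = (
        cfg.tag_len * 2 + len(cfg.primer_fwd) + len(cfg.primer_rev)
        + len(cfg.anchor_5p) + len(cfg.anchor_3p) + cfg.its2_len[0]
    )
    if cfg.read_len > min_amplicon:
        raise ValueError(
            f"read_len {cfg.read_len} exceeds the shortest amplicon ({min_amplicon})"
        )

    r1_out: list[SeqRecord] = []
    r2_out: list[SeqRecord] = []
    rows: list[dict] = []
    counts: dict[tuple[str, str], int] = {}

    for sample, tag in cfg.samples:
        for i in range(cfg.reads_per_sample):
            read_id = f"{sample}.{i}"
            u = rng.random()
            breakpoint_frac = float("nan")
            if u < cfg.chimera_rate and cfg.n_species >= 2:
                kind = "chimera"
                a, b = rng.choice(cfg.n_species, size=2, replace=False)
                f = 0.2 + 0.6 * rng.random()
                core = cores[a][: round(f * len(cores[a]))] + cores[b][round(f * len(cores[b])) :]
                species = f"{species_ids[a]}+{species_ids[b]}"
                breakpoint_frac = f
            elif u < cfg.chimera_rate + cfg.multiprimer_rate:
                kind = "multiprimer"
                k = int(rng.integers(cfg.n_species))
                base = cores[k]
                p = cfg.primer_fwd
                pos = int(rng.integers(0, len(base) - len(p)))
                core = base[:pos] + p + base[pos + len(p) :]
                species = species_ids[k]
            else:
                kind = "intact"
                k = int(rng.integers(cfg.n_species))
                core = cores[k]
                species = species_ids[k]

            tag5, tag3, tag_status = tag, tag, "ok"
            v = rng.random()
            if v < cfg.tag_error_rate:
                tag_status = "corrupted"
                if rng.random() < 0.5:
                    tag5 = _corrupt_tag(tag, rng)
                else:
                    tag3 = _corrupt_tag(tag, rng)
            elif v < cfg.tag_error_rate + cfg.tag_switch_rate and len(cfg.samples) > 1:
                tag_status = "switched"
                others = [t for _, t in cfg.samples if t != tag]
                tag3 = others[int(rng.integers(len(others)))]

            amplicon = make_amplicon(core, tag5, cfg, tag3=tag3)
            fwd_read = amplicon[: cfg.read_len]
            rev_read = revcomp(amplicon)[: cfg.read_len]
            orientation = "reverse" if rng.random() < cfg.revorient_prob else "forward"
            first, second = (
                (rev_read, fwd_read) if orientation == "reverse" else (fwd_read, rev_read)
            )
            r1_out.append(
                SeqRecord(read_id, _mutate(first, rng, cfg.per_base_error),
                          [q] * cfg.read_len)
            )
            r2_out.append(
                SeqRecord(read_id, _mutate(second, rng, cfg.per_base_error),
                          [q] * cfg.read_len)
            )
            rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "kind": kind,
                    "species": species,
                    "orientation": orientation,
                    "tag_status": tag_status,
                    "breakpoint_frac": breakpoint_frac,
                }
            )
            if kind == "intact" and tag_status == "ok":
                counts[(species, sample)] = counts.get((species, sample), 0) + 1

    sample_names = [s for s, _ in cfg.samples]
    table = pd.DataFrame(0, index=species_ids, columns=sample_names, dtype=int)
    for (sp, sa), c in counts.items():
        table.loc[sp, sa] = c
    truth = GroundTruth(
        reads=pd.DataFrame(rows),
        species=dict(zip(species_ids, cores)),
        expected_table=table,
    )
    return SimResult(cfg, r1_out, r2_out, truth)


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write R1.fastq, R2.fastq, truth.tsv, labels.csv and species.fasta."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": out / "R1.fastq",
        "r2": out / "R2.fastq",
        "truth": out / "truth.tsv",
        "labels": out / "labels.csv",
        "species": out / "species.fasta",
    }
    write_fastq(result.r1, paths["r1"])
    write_fastq(result.r2, paths["r2"])
    result.truth.reads.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["labels"], "w") as fh:
        fh.write("name,tag\n")
        for name, tag in result.config.samples:
            fh.write(f"{name},{tag}\n")
    write_fasta(
        [SeqRecord(sp, core) for sp, core in result.truth.species.items()],
        paths["species"],
    )
    return paths
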