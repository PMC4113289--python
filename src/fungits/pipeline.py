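"""End-to-end orchestration: raw paired FASTQ to chimera-filtered,
taxonomically gated OTU x sample table, with per-stage pruning accounting.

Every stage writes its intermediate files so any two stages can be
inspected or re-run independently — the pipeline is deliberately not a
black box, and the pruning report (one row per stage: what came in, what
survived, why reads were lost) is the machine-readable analog of a
read-accounting table for the whole run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import chimera_ref, clustering, its_extract, otu_table, primer_demux, readprep
from .seqio import (
    SeqRecord,
    StageReport,
    read_fastq_pairs,
    write_fasta,
    write_fastq,
)

logger = logging.getLogger("fungits")


def chimera_accounting(
    n_clustered: int, n_denovo_chimeric: int, n_ref_chimeric: int
) -> dict[str, float]:
    """Chimera bookkeeping over clustered OTUs.

    Given the number of OTUs produced by clustering (including those the
    de-novo filter then flags) and the counts flagged by the de-novo and
    reference filters, returns the surviving counts and the overall
    percentage of chimeric OTUs.
    """
    if min(n_clustered, n_denovo_chimeric, n_ref_chimeric) < 0:
        raise ValueError("counts must be non-negative")
    after_denovo = n_clustered - n_denovo_chimeric
    surviving = after_denovo - n_ref_chimeric
    if surviving < 0:
        raise ValueError("chimera counts exceed clustered OTUs")
    pct = 100.0 * (n_denovo_chimeric + n_ref_chimeric) / n_clustered
    return {
        "n_clustered": n_clustered,
        "n_after_denovo": after_denovo,
        "n_surviving": surviving,
        "pct_chimeric": pct,
    }


@dataclass
class PipelineConfig:
    """All stage parameters and file paths for a full run."""

    r1: str
    r2: str
    labels: str
    primer_fwd: str
    primer_rev: str
    outdir: str
    ref_fasta: Optional[str] = None
    hits_tsv: Optional[str] = None
    anchors_yaml: Optional[str] = None
    mean_q: float = 26.0
    len_min: int = 150
    min_overlap: int = 5
    max_overlap_mismatch_frac: float = 0.25
    reject_N: bool = True
    orient_mismatches: int = 1
    anchored_demux: bool = True
    trim_head: Optional[int] = None  # default: tag + forward-primer length
    trim_tail: Optional[int] = None
    min_size: int = 2
    otu_id: float = 0.97
    map_id: float = 0.97
    lca_min_score: float = 170.0
    lca_top_percent: float = 5.0
    lca_min_support: int = 1

    def __post_init__(self) -> None:
        for name, v in (("otu_id", self.otu_id), ("map_id", self.map_id)):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.mean_q < 0 or self.len_min < 1 or self.min_overlap < 1:
            raise ValueError("invalid read-filter/merge parameters")
        if not 0.0 <= self.lca_top_percent <= 100.0:
            raise ValueError("lca_top_percent must lie in [0, 100]")
        if self.orient_mismatches < 0 or self.min_size < 1:
            raise ValueError("invalid orientation/clustering parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    table: Optional[pd.DataFrame]
    pruning: pd.DataFrame
    stage_reports: list[StageReport]
    paths: dict[str, Path]
    centroids: list[clustering.Centroid] = field(default_factory=list)
    otu_records: list[SeqRecord] = field(default_factory=list)


def _row(stage: str, unit: str, n_in: int, n_kept: int, reasons: dict[str, int]) -> dict:
    return {
        "stage": stage,
        "unit": unit,
        "n_in": n_in,
        "n_kept": n_kept,
        "n_lost": n_in - n_kept,
        "reasons": ";".join(f"{k}={v}" for k, v in sorted(reasons.items())) or "-",
    }


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order; halt with a stage-tagged error on failure."""
    for path_attr in ("r1", "r2", "labels", "ref_fasta", "hits_tsv", "anchors_yaml"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{path_attr}: no such file {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rows: list[dict] = []
    stage_reports: list[StageReport] = []

    primers = primer_demux.PrimerSet(config.primer_fwd, config.primer_rev)
    sheet = primer_demux.SampleSheet.from_csv(config.labels)

    def log_stage(report: StageReport) -> None:
        stage_reports.append(report)
        logger.info(
            "stage=%s in=%d kept=%d lost=%d reasons=%s",
            report.stage, report.n_in, report.n_kept,
            report.n_discarded, report.reasons,
        )

    # 1. paired quality/length filtering
    pairs = list(read_fastq_pairs(config.r1, config.r2))
    kept_pairs, rep = readprep.quality_filter_pairs(
        pairs, readprep.QualityFilterParams(config.mean_q, config.len_min)
    )
    log_stage(rep)
    rows.append(_row("1_quality_filter", "read_pairs", rep.n_in, rep.n_kept, rep.reasons))
    paths["filtered_r1"] = out / "filtered_R1.fastq"
    paths["filtered_r2"] = out / "filtered_R2.fastq"
    write_fastq((p.r1 for p in kept_pairs), paths["filtered_r1"])
    write_fastq((p.r2 for p in kept_pairs), paths["filtered_r2"])

    # 2. paired-end assembly
    merged, rep = readprep.merge_stream(
        kept_pairs,
        readprep.MergeParams(
            config.min_overlap, config.reject_N, config.max_overlap_mismatch_frac
        ),
    )
    log_stage(rep)
    rows.append(_row("2_merge", "reads", rep.n_in, rep.n_kept, rep.reasons))
    merged_records = [m.record for m in merged]
    paths["merged"] = out / "merged.fastq"
    write_fastq(merged_records, paths["merged"])

    # 3. multi-primer artifact removal
    deprimed, rep = primer_demux.remove_multiprimer(merged_records, primers)
    log_stage(rep)
    rows.append(_row("3_remove_multiprimer", "reads", rep.n_in, rep.n_kept, rep.reasons))
    paths["deprimed"] = out / "deprimed.fastq"
    write_fastq(deprimed, paths["deprimed"])

    # 4. reorientation to 5'->3'
    oriented, rep = primer_demux.orient_reads(deprimed, primers, config.orient_mismatches)
    log_stage(rep)
    rows.append(_row("4_orient", "reads", rep.n_in, rep.n_kept, rep.reasons))
    paths["oriented"] = out / "oriented.fastq"
    write_fastq(oriented, paths["oriented"])

    # 5. dual-tag demultiplexing (fasta from here on)
    sample_map, unassigned, rep = primer_demux.demultiplex(
        oriented, sheet, primers, anchored=config.anchored_demux
    )
    log_stage(rep)
    rows.append(_row("5_demultiplex", "reads", rep.n_in, rep.n_kept, rep.reasons))
    for name in sheet.names:
        paths[f"sample_{name}"] = out / f"sample_{name}.fasta"
        write_fasta(sample_map[name], paths[f"sample_{name}"])
    paths["unassigned"] = out / "unassigned.fasta"
    write_fasta(unassigned, paths["unassigned"])

    # 6. pool, rename headers, trim tags+primers
    head = config.trim_head if config.trim_head is not None else sheet.tag_len + len(primers.fwd)
    tail = config.trim_tail if config.trim_tail is not None else sheet.tag_len + len(primers.rev)
    pooled = primer_demux.pool_and_trim(
        sample_map, primer_demux.TrimParams(head, tail), sheet.names
    )
    rows.append(_row("6_pool_trim", "reads", len(pooled), len(pooled), {}))
    paths["pooled"] = out / "pooled_trimmed.fasta"
    write_fasta(pooled, paths["pooled"])

    # 7. ITS2 extraction
    model = (
        its_extract.AnchorModel.from_yaml(config.anchors_yaml)
        if config.anchors_yaml
        else its_extract.default_model()
    )
    its2, non_its, rep = its_extract.extract_its2(pooled, model)
    log_stage(rep)
    rows.append(_row("7_extract_its2", "reads", rep.n_in, rep.n_kept, rep.reasons))
    paths["its2"] = out / "its2.fasta"
    paths["non_its"] = out / "non_its.fasta"
    write_fasta(its2, paths["its2"])
    write_fasta(non_its, paths["non_its"])

    # 8. dereplicate, sort/minsize, cluster
    uniques = clustering.dereplicate(its2)
    rows.append(_row("8a_dereplicate", "reads->clusters", len(its2), len(uniques), {}))
    paths["derep"] = out / "derep.fasta"
    write_fasta(clustering.uniques_to_records(uniques), paths["derep"])

    sorted_uniques = clustering.sort_by_size(uniques, config.min_size)
    n_below = len(uniques) - len(sorted_uniques)
    rep = StageReport(
        "sort_by_size", len(uniques), len(sorted_uniques),
        {"below_minsize": n_below} if n_below else {},
    )
    log_stage(rep)
    rows.append(_row("8b_sort_minsize", "clusters", rep.n_in, rep.n_kept, rep.reasons))
    paths["sorted"] = out / "sorted.fasta"
    write_fasta(clustering.uniques_to_records(sorted_uniques), paths["sorted"])

    params = clustering.ClusterParams(
        min_size=config.min_size, identity_threshold=config.otu_id
    )
    centroids, denovo_chim, rep = clustering.greedy_cluster(sorted_uniques, params)
    log_stage(rep)
    n_absorbed = len(sorted_uniques) - len(centroids) - len(denovo_chim)
    rows.append(
        _row(
            "8c_cluster_otus", "clusters", len(sorted_uniques), len(centroids),
            {"absorbed": n_absorbed, "denovo_chimera": len(denovo_chim)},
        )
    )
    otu_records = clustering.centroids_to_records(centroids)
    paths["otus"] = out / "otus.fasta"
    write_fasta(otu_records, paths["otus"])
    paths["denovo_chimeras"] = out / "denovo_chimeras.fasta"
    write_fasta(
        [SeqRecord(f"chimera{i + 1};size={u.size};", u.bases)
         for i, (u, _res, _par) in enumerate(denovo_chim)],
        paths["denovo_chimeras"],
    )

    # 9. reference-based chimera filtering (plus strand only)
    if config.ref_fasta:
        db = chimera_ref.build_refdb(config.ref_fasta)
        clean, chimeric, verdicts, rep = chimera_ref.uchime_ref(otu_records, db)
        log_stage(rep)
        rows.append(_row("9_uchime_ref", "clusters", rep.n_in, rep.n_kept, rep.reasons))
        paths["otus_good"] = out / "otus_good.fasta"
        paths["otus_chim"] = out / "otus_chim.fasta"
        write_fasta(clean, paths["otus_good"])
        write_fasta(chimeric, paths["otus_chim"])
        paths["verdicts"] = out / "chimera_verdicts.tsv"
        pd.DataFrame([vars(v) for v in verdicts]).to_csv(
            paths["verdicts"], sep="\t", index=False
        )
        surviving = clean
    else:
        surviving = otu_records

    # 10. LCA fungal gating (optional: homology search is external)
    if config.hits_tsv:
        from . import taxonomy_gate

        hits = taxonomy_gate.read_hits(config.hits_tsv)
        assignments = taxonomy_gate.lca_assign(
            hits,
            taxonomy_gate.LcaParams(
                config.lca_min_score, config.lca_top_percent, config.lca_min_support
            ),
        )
        fungal, _excluded, tally = taxonomy_gate.filter_fungal(surviving, assignments)
        rows.append(
            _row(
                "10_lca_fungal_gate", "clusters", len(surviving), len(fungal),
                {"non_fungal_or_unassigned": len(surviving) - len(fungal)},
            )
        )
        paths["taxa_summary"] = out / "taxa_summary.tsv"
        tally.rename("n_otus").to_csv(paths["taxa_summary"], sep="\t")
        final_otus = fungal
    else:
        final_otus = surviving
    paths["fungal_otus"] = out / "fungal_otus.fasta"
    write_fasta(final_otus, paths["fungal_otus"])

    # 11. relabel, map all ITS2 reads, build the abundance table
    table: Optional[pd.DataFrame] = None
    if final_otus:
        numbered, _mapping = otu_table.relabel_otus(final_otus)
        paths["otus_numbered"] = out / "fungal_otus_numbered.fasta"
        write_fasta(numbered, paths["otus_numbered"])
        readmap, rep = otu_table.map_reads(its2, numbered, config.map_id)
        log_stage(rep)
        rows.append(_row("11_map_reads", "reads", rep.n_in, rep.n_kept, rep.reasons))
        table = otu_table.build_table(readmap, [r.id for r in numbered], sheet.names)
        paths["otu_table"] = out / "otu_table.tsv"
        otu_table.write_table(table, paths["otu_table"])

    pruning = pd.DataFrame(rows)
    paths["pruning_report"] = out / "pruning_report.tsv"
    pruning.to_csv(paths["pruning_report"], sep="\t", index=False)

    # re-assert conservation across every stage report of the run
    for r in stage_reports:
        assert r.n_in == r.n_kept + r.n_discarded

    return PipelineResult(
        table=table,
        pruning=pruning,
        stage_reports=stage_reports,
        paths=paths,
        centroids=centroids,
        otu_records=final_otus,
    )
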