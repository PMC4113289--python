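"""Multi-primer screening, reorientation, dual-tag demultiplexing, pooling."""

import random

import pytest

from fungits import (
    MergeParams,
    PrimerSet,
    SampleSheet,
    TrimParams,
    demultiplex,
    merge_stream,
    orient_reads,
    pool_and_trim,
    remove_multiprimer,
)
from fungits.seqio import SeqRecord, revcomp
from conftest import random_dna

FWD, REV = "GTGAATCATCGAATCTTT", "TCCTCCGCTTATTGATAT"
PRIMERS = PrimerSet(FWD, REV)


def amplicon_read(core="ACGT" * 30, tag="ACACACGT"):
    return SeqRecord("r", tag + FWD + core + revcomp(REV) + revcomp(tag), None)


# ---------------------------------------------------------------------------
# multi-primer artifacts


def test_clean_amplicon_kept():
    kept, rep = remove_multiprimer([amplicon_read()], PRIMERS)
    assert len(kept) == 1 and rep.reasons == {}


def test_extra_internal_forward_primer_discarded():
    rec = amplicon_read()
    seq = rec.bases[:60] + FWD + rec.bases[60:]
    kept, rep = remove_multiprimer([SeqRecord("r", seq)], PRIMERS)
    assert kept == [] and rep.reasons == {"multiprimer": 1}


def test_extra_primer_on_reverse_strand_also_counts():
    rec = amplicon_read()
    seq = rec.bases[:60] + revcomp(FWD) + rec.bases[60:]
    kept, _ = remove_multiprimer([SeqRecord("r", seq)], PRIMERS)
    assert kept == []


def test_read_without_primers_passes_multiprimer_screen():
    rec = SeqRecord("r", "ACGT" * 20)
    kept, _ = remove_multiprimer([rec], PRIMERS)
    assert kept == [rec]  # zero occurrences <= 1; rejected later at orientation


def test_ambiguous_primer_rejected_for_exact_ops():
    with pytest.raises(ValueError, match="ambiguity"):
        remove_multiprimer([amplicon_read()], PrimerSet("GTGARTCATCG", REV))


# ---------------------------------------------------------------------------
# reorientation


def test_orient_keeps_forward_flips_reverse_drops_rest():
    fwd_rec = amplicon_read()
    rev_rec = SeqRecord("r2", revcomp(fwd_rec.bases), None)
    junk = SeqRecord("r3", random_dna(random.Random(0), 120))
    kept, rep = orient_reads([fwd_rec, rev_rec, junk], PRIMERS, mismatches=1)
    assert [r.bases for r in kept] == [fwd_rec.bases, fwd_rec.bases]
    assert rep.reasons == {"no_primer": 1}


def test_orient_allows_one_substitution_in_primer():
    rec = amplicon_read()
    seq = rec.bases.replace(FWD, FWD[:-1] + ("A" if FWD[-1] != "A" else "C"), 1)
    kept, _ = orient_reads([SeqRecord("r", seq)], PRIMERS, mismatches=1)
    assert len(kept) == 1
    kept, rep = orient_reads([SeqRecord("r", seq)], PRIMERS, mismatches=0)
    assert kept == [] and rep.reasons == {"no_primer": 1}


def test_orient_is_idempotent(clean_sim, clean_pairs):
    merged, _ = merge_stream(clean_pairs, MergeParams())
    records = [m.record for m in merged]
    once, rep1 = orient_reads(records, PRIMERS, 1)
    twice, rep2 = orient_reads(once, PRIMERS, 1)
    assert [r.bases for r in once] == [r.bases for r in twice]
    assert rep1.n_kept == rep1.n_in  # error-free reads all orient
    assert rep2.n_discarded == 0


def test_orient_reverses_qualities_with_bases():
    rec = amplicon_read()
    quals = list(range(len(rec.bases)))
    rc = SeqRecord("r", revcomp(rec.bases), list(reversed(quals)))
    kept, _ = orient_reads([rc], PRIMERS, 1)
    assert kept[0].quals == quals


# ---------------------------------------------------------------------------
# demultiplexing


SHEET = SampleSheet([("S01", "ACACACGT"), ("S02", "CGTGTACA")])


def test_demultiplex_assigns_by_both_ends_exactly():
    r_ok = amplicon_read(tag="ACACACGT")
    corrupted = SeqRecord("c", "T" + r_ok.bases[1:])  # 1 sub in 5' tag
    switched = SeqRecord(
        "s",
        "ACACACGT" + FWD + "ACGT" * 30 + revcomp(REV) + revcomp("CGTGTACA"),
    )
    smap, unassigned, rep = demultiplex([r_ok, corrupted, switched], SHEET, PRIMERS)
    assert [r.id for r in smap["S01"]] == ["r"]
    assert smap["S02"] == []
    assert {r.id for r in unassigned} == {"c", "s"}
    assert rep.n_in == 3 and rep.n_kept == 1


def test_demultiplex_partition_is_exhaustive(clean_sim, clean_pairs):
    cfg = clean_sim.config
    merged, _ = merge_stream(clean_pairs, MergeParams())
    oriented, _ = orient_reads([m.record for m in merged],
                               PrimerSet(cfg.primer_fwd, cfg.primer_rev), 1)
    sheet = SampleSheet(cfg.samples)
    smap, unassigned, rep = demultiplex(
        oriented, sheet, PrimerSet(cfg.primer_fwd, cfg.primer_rev)
    )
    assert sum(len(v) for v in smap.values()) + len(unassigned) == rep.n_in
    tags = dict(cfg.samples)
    for name, recs in smap.items():
        assert all(r.bases.startswith(tags[name]) for r in recs)
    # error-free reads of an intact run all demultiplex to the truth sample
    truth = clean_sim.truth.reads.set_index("read_id")["sample"]
    for name, recs in smap.items():
        assert all(truth[r.id] == name for r in recs)
    assert not unassigned


def test_internal_pattern_hit_not_assigned_when_anchored():
    inner = amplicon_read(tag="ACACACGT").bases
    rec = SeqRecord("r", "TTTT" + inner + "GGGG")
    smap, unassigned, _ = demultiplex([rec], SHEET, PRIMERS, anchored=True)
    assert unassigned == [rec]
    smap, unassigned, _ = demultiplex([rec], SHEET, PRIMERS, anchored=False)
    assert smap["S01"] == [rec]


def test_duplicate_tag_in_sheet_rejected():
    with pytest.raises(ValueError, match="duplicate tag"):
        SampleSheet([("a", "ACACACGT"), ("b", "ACACACGT")])


def test_sample_sheet_csv_roundtrip(tmp_path):
    path = tmp_path / "labels.csv"
    path.write_text("name,tag\nS01,ACACACGT\nS02,CGTGTACA\n")
    sheet = SampleSheet.from_csv(path)
    assert sheet.entries == [("S01", "ACACACGT"), ("S02", "CGTGTACA")]
    assert sheet.tag_len == 8


# ---------------------------------------------------------------------------
# pooling and trimming


def test_pool_and_trim_recovers_insert_and_renames_header():
    core = "ACGT" * 30
    rec = amplicon_read(core=core, tag="ACACACGT")
    pooled = pool_and_trim({"S01": [rec]}, TrimParams(26, 26), ["S01"])
    assert pooled[0].id == "sample=S01;r"
    assert pooled[0].bases == core


def test_pool_and_trim_zero_is_identity_rename():
    rec = amplicon_read()
    pooled = pool_and_trim({"S01": [rec]}, TrimParams(0, 0), ["S01"])
    assert pooled[0].bases == rec.bases


def test_pool_and_trim_rejects_too_short_read():
    rec = SeqRecord("r", "A" * 52)
    with pytest.raises(ValueError, match="too short"):
        pool_and_trim({"S01": [rec]}, TrimParams(26, 26), ["S01"])


def test_pool_order_follows_sheet_order():
    r1, r2 = SeqRecord("a", "A" * 60), SeqRecord("b", "C" * 60)
    pooled = pool_and_trim({"X": [r1], "Y": [r2]}, TrimParams(1, 1), ["Y", "X"])
    assert [p.id for p in pooled] == ["sample=Y;b", "sample=X;a"]
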