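"""Quality filtering and overlap-consensus merging, checked against the
exhaustive overlap oracle and simulator ground truth."""

import random

from oracles import merge_oracle
from fungits import (
    MergeParams,
    QualityFilterParams,
    ReadPair,
    make_amplicon,
    merge_pair,
    merge_stream,
    quality_filter_pairs,
)
from fungits.seqio import SeqRecord, revcomp


def pair(s1, s2, q1=None, q2=None):
    q1 = [40] * len(s1) if q1 is None else q1
    q2 = [40] * len(s2) if q2 is None else q2
    return ReadPair(SeqRecord("p", s1, q1), SeqRecord("p", s2, q2))


# ---------------------------------------------------------------------------
# quality filtering


def test_quality_filter_keeps_good_pairs_and_reports_reasons():
    params = QualityFilterParams(26.0, 150)
    good = pair("A" * 200, "C" * 200)
    low = pair("A" * 200, "C" * 200, q2=[25] * 200)
    short = pair("A" * 149, "C" * 200)
    kept, rep = quality_filter_pairs([good, low, short], params)
    assert kept == [good]
    assert rep.n_in == 3 and rep.n_kept == 1
    assert rep.reasons == {"low_quality": 1, "too_short": 1}


def test_quality_filter_boundary_mean_exactly_at_threshold():
    params = QualityFilterParams(26.0, 10)
    exact = pair("A" * 10, "C" * 10, q1=[26] * 10)
    kept, _ = quality_filter_pairs([exact], params)
    assert kept == [exact]  # >= threshold is kept


def test_dropping_one_mate_drops_the_pair():
    params = QualityFilterParams(30.0, 5)
    p = pair("A" * 10, "C" * 10, q1=[40] * 10, q2=[20] * 10)
    kept, rep = quality_filter_pairs([p], params)
    assert kept == [] and rep.reasons == {"low_quality": 1}


# ---------------------------------------------------------------------------
# merging


def test_merge_known_four_base_overlap():
    p = pair("AAAACGTG", revcomp("CGTGTTTT"))
    merged, reason = merge_pair(p, MergeParams(min_overlap=4))
    assert reason is None
    assert merged.record.bases == "AAAACGTGTTTT"
    assert merged.overlap_len == 4 and merged.n_corrected == 0
    assert merged.record.quals[4:8] == [41] * 4  # agreement: min(q1+q2, 41)


def test_full_overlap_identical_mates():
    s = "ACGTACGTGGTA"
    merged, _ = merge_pair(pair(s, revcomp(s)), MergeParams())
    assert merged.record.bases == s and merged.overlap_len == len(s)


def test_disagreement_resolved_by_higher_quality_base():
    s1 = "ACGTACGTAC"
    s2rc = "ACGTACCTAC"  # mismatch at index 6: G vs C
    q1 = [40] * 10
    q2rc = [40] * 6 + [10] + [40] * 3
    p = pair(s1, revcomp(s2rc), q1=q1, q2=list(reversed(q2rc)))
    merged, _ = merge_pair(p, MergeParams())
    assert merged.record.bases == s1  # r1 base wins at q40 vs q10
    assert merged.record.quals[6] == 30 and merged.n_corrected == 1


def test_equal_quality_disagreement_takes_r1_base_at_q2():
    s1, s2rc = "AAAAAAAAGA", "AAAAAAAACA"
    p = pair(s1, revcomp(s2rc), q1=[30] * 10, q2=[30] * 10)
    merged, _ = merge_pair(p, MergeParams())
    assert merged.record.bases == s1 and merged.record.quals[8] == 2


def test_merge_rejects_n_in_consensus():
    s = "ACGTNCGTAC"
    _, reason = merge_pair(pair(s, revcomp(s)), MergeParams())
    assert reason == "contains_N"
    merged, reason = merge_pair(pair(s, revcomp(s)), MergeParams(reject_N=False))
    assert reason is None and "N" in merged.record.bases


def test_no_candidate_overlap_when_reads_too_short():
    _, reason = merge_pair(pair("ACG", "CGT"), MergeParams(min_overlap=5))
    assert reason == "no_overlap"


def test_merge_matches_exhaustive_oracle_on_random_pairs():
    rng = random.Random(42)
    params = MergeParams()
    for _ in range(200):
        amp = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 120)))
        rl = rng.randint(40, min(90, len(amp)))
        s1 = "".join(
            c if rng.random() > 0.02 else rng.choice("ACGT") for c in amp[:rl]
        )
        s2 = "".join(
            c if rng.random() > 0.02 else rng.choice("ACGT")
            for c in revcomp(amp)[:rl]
        )
        q1 = [rng.randint(2, 40) for _ in s1]
        q2 = [rng.randint(2, 40) for _ in s2]
        got, reason = merge_pair(
            ReadPair(SeqRecord("x", s1, q1), SeqRecord("x", s2, q2)), params
        )
        expect, oreason = merge_oracle(s1, q1, s2, q2)
        assert reason == oreason
        if got is not None:
            seq, quals, L, nc = expect
            assert got.record.bases == seq
            assert got.record.quals == quals
            assert (got.overlap_len, got.n_corrected) == (L, nc)


def test_error_free_sim_pairs_all_merge_to_their_amplicons(clean_sim, clean_pairs):
    merged, rep = merge_stream(clean_pairs, MergeParams())
    assert rep.n_kept == rep.n_in == len(clean_pairs)
    cfg = clean_sim.config
    tags = dict(cfg.samples)
    for m, row in zip(merged, clean_sim.truth.reads.itertuples()):
        amp = make_amplicon(clean_sim.truth.species[row.species], tags[row.sample], cfg)
        expected = amp if row.orientation == "forward" else revcomp(amp)
        assert m.record.bases == expected
        assert len(m.record.bases) == 2 * cfg.read_len - m.overlap_len


def test_random_unrelated_pairs_mostly_rejected():
    rng = random.Random(7)
    pairs = []
    for _ in range(400):
        s1 = "".join(rng.choice("ACGT") for _ in range(250))
        s2 = "".join(rng.choice("ACGT") for _ in range(250))
        pairs.append(pair(s1, s2, q1=[30] * 250, q2=[30] * 250))
    merged, rep = merge_stream(pairs, MergeParams())
    # spurious short near-perfect overlaps can pass; the vast majority cannot
    assert rep.n_kept / rep.n_in <= 0.05
    assert set(rep.reasons) <= {"no_overlap", "too_many_mismatches", "contains_N"}


def test_merge_stream_empty_input():
    merged, rep = merge_stream([], MergeParams())
    assert merged == [] and rep.n_in == 0
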