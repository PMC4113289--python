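"""Dereplication, identity, greedy OTU clustering and the bimera rule,
cross-checked against textbook DP and exhaustive-crossover oracles."""

import random

import pytest

from conftest import random_dna
from oracles import bimera_oracle, identity_oracle, score_oracle
from fungits import (
    ClusterParams,
    UniqueSeq,
    dereplicate,
    greedy_cluster,
    is_bimera,
    sort_by_size,
)
from fungits._align import align_global, global_identity
from fungits.clustering import (
    audit_member_identities,
    parse_size,
    uniques_to_records,
)
from fungits.seqio import SeqRecord


# ---------------------------------------------------------------------------
# dereplication and sorting


def test_dereplicate_counts_exact_duplicates():
    recs = [SeqRecord(f"r{i}", b) for i, b in enumerate(["ACGT", "ACGT", "ACGA"])]
    uniques = dereplicate(recs)
    assert {(u.bases, u.size) for u in uniques} == {("ACGT", 2), ("ACGA", 1)}
    assert sum(u.size for u in uniques) == 3


def test_dereplicate_all_distinct():
    recs = [SeqRecord(f"r{i}", "ACGT"[: i + 1] + "A" * i) for i in range(4)]
    uniques = dereplicate(recs)
    assert len(uniques) == 4 and all(u.size == 1 for u in uniques)


def test_dereplicate_is_case_insensitive():
    uniques = dereplicate([SeqRecord("a", "acgt"), SeqRecord("b", "ACGT")])
    assert len(uniques) == 1 and uniques[0].size == 2
    assert uniques[0].bases == "ACGT"  # output uppercase


def test_size_annotation_in_headers():
    recs = uniques_to_records([UniqueSeq("ACGT", 7)])
    assert "size=7" in recs[0].id
    assert parse_size(recs[0].header) == 7


def test_sort_by_size_minsize_and_ties():
    uniques = [UniqueSeq("TTTT", 1), UniqueSeq("CCCC", 5), UniqueSeq("AAAA", 3)]
    assert [u.size for u in sort_by_size(uniques, 2)] == [5, 3]
    assert len(sort_by_size(uniques, 1)) == 3
    tied = [UniqueSeq("GGGG", 2), UniqueSeq("AAAA", 2), UniqueSeq("CCCC", 2)]
    assert [u.bases for u in sort_by_size(tied, 1)] == ["AAAA", "CCCC", "GGGG"]


# ---------------------------------------------------------------------------
# global identity


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGTACGT", "ACGTACGT", 1.0),
        ("ACGT", "ACGA", 0.75),
        ("ACGT", "ACGTACGT", 1.0),  # terminal gaps free
    ],
)
def test_identity_examples(a, b, expected):
    assert global_identity(a, b) == expected


def test_identity_and_score_match_textbook_dp():
    rng = random.Random(9)
    for t in range(80):
        a = random_dna(rng, rng.randint(30, 70))
        if t % 2:
            b = "".join(c if rng.random() > 0.15 else rng.choice("ACGT") for c in a)
        else:
            b = random_dna(rng, rng.randint(30, 70))
        _, _, score = align_global(a, b)
        assert score == score_oracle(a, b)
        assert global_identity(a, b) == identity_oracle(a, b)


def test_identity_nearly_symmetric_in_the_clustering_regime():
    # exact symmetry is not guaranteed for unrelated pairs (co-optimal
    # alignments may differ); near the 97% threshold it must hold tightly
    rng = random.Random(10)
    a = random_dna(rng, 120)
    b = "".join(c if rng.random() > 0.03 else rng.choice("ACGT") for c in a)
    assert abs(global_identity(a, b) - global_identity(b, a)) <= 0.01
    assert global_identity("ACGT", "ACGTACGT") == global_identity("ACGTACGT", "ACGT")


# ---------------------------------------------------------------------------
# bimera rule


def divergent_parents(rng, n=160, div=0.3):
    a = random_dna(rng, n)
    b = "".join(
        c if rng.random() > div else rng.choice([x for x in "ACGT" if x != c])
        for c in a
    )
    return a, b


def test_query_equal_to_parent_is_not_bimeric():
    rng = random.Random(11)
    a, b = divergent_parents(rng)
    res = is_bimera(a, a, b)
    assert not res.is_bimera
    assert res.id_model - res.id_best_single < 0.02  # model no better than parent


def test_exact_crossover_construct_is_bimeric():
    rng = random.Random(12)
    a, b = divergent_parents(rng)
    q = a[:80] + b[80:]
    res = is_bimera(q, a, b)
    assert res.is_bimera and res.id_model == 1.0
    assert abs(res.crossover - 80) <= 5  # breakpoint within the tie plateau


def test_random_sequence_is_not_bimeric():
    rng = random.Random(13)
    a, b = divergent_parents(rng)
    q = random_dna(rng, 160)
    res = is_bimera(q, a, b)
    assert not res.is_bimera and res.id_model < 0.97


def test_bimera_agrees_with_exhaustive_crossover_oracle():
    rng = random.Random(14)
    for t in range(60):
        a, b = divergent_parents(rng, n=rng.randint(120, 180))
        if t % 3 == 0:
            cut = rng.randint(30, len(a) - 30)
            q = a[:cut] + b[cut:]
        elif t % 3 == 1:
            q = "".join(c if rng.random() > 0.01 else rng.choice("ACGT") for c in a)
        else:
            q = random_dna(rng, 150)
        res = is_bimera(q, a, b)
        over, om, osingle, oc = bimera_oracle(q, a, b)
        assert res.is_bimera == over
        assert res.id_model == om and res.id_best_single == osingle
        assert res.crossover == oc


# ---------------------------------------------------------------------------
# greedy clustering


def test_simulated_species_recovered_exactly(clean_sim):
    cfg = clean_sim.config
    reads = []
    tr = clean_sim.truth.reads
    for row in tr.itertuples():
        reads.append(SeqRecord(row.read_id, clean_sim.truth.species[row.species]))
    uniques = sort_by_size(dereplicate(reads), 2)
    centroids, chimeras, rep = greedy_cluster(uniques, ClusterParams())
    assert len(centroids) == cfg.n_species and not chimeras
    assert {c.representative for c in centroids} == set(
        clean_sim.truth.species.values()
    )
    assert audit_member_identities(centroids, 0.97)


def test_sequences_below_threshold_make_two_centroids():
    rng = random.Random(15)
    a = random_dna(rng, 100)
    positions = rng.sample(range(100), 4)
    b = "".join(
        rng.choice([x for x in "ACGT" if x != c]) if i in positions else c
        for i, c in enumerate(a)
    )
    assert global_identity(a, b) == 0.96
    uniques = [UniqueSeq(a, 5), UniqueSeq(b, 3)]
    centroids, _, _ = greedy_cluster(uniques, ClusterParams(identity_threshold=0.97))
    assert len(centroids) == 2
    centroids, _, _ = greedy_cluster(uniques, ClusterParams(identity_threshold=0.95))
    assert len(centroids) == 1 and centroids[0].size == 8


def test_injected_bimera_flagged_not_made_centroid():
    rng = random.Random(16)
    a, b = divergent_parents(rng, n=200)
    chim = a[:100] + b[100:]
    uniques = [UniqueSeq(a, 50), UniqueSeq(b, 40), UniqueSeq(chim, 2)]
    centroids, chimeras, rep = greedy_cluster(uniques, ClusterParams(min_size=1))
    assert len(centroids) == 2
    assert len(chimeras) == 1 and chimeras[0][0].bases == chim
    assert rep.reasons == {"denovo_chimera": 1}


def test_low_abundance_parents_do_not_trigger_bimera_rule():
    rng = random.Random(17)
    a, b = divergent_parents(rng, n=200)
    chim = a[:100] + b[100:]
    # parents not 2x the query abundance: the construct founds its own OTU
    uniques = [UniqueSeq(a, 3), UniqueSeq(b, 3), UniqueSeq(chim, 2)]
    centroids, chimeras, _ = greedy_cluster(uniques, ClusterParams(min_size=1))
    assert len(centroids) == 3 and not chimeras


def test_size_conservation_and_determinism():
    rng = random.Random(18)
    seqs = [random_dna(rng, 120) for _ in range(6)]
    uniques = [UniqueSeq(s, n) for s, n in zip(seqs, [9, 7, 5, 3, 2, 1])]
    run1 = greedy_cluster(sort_by_size(uniques, 1), ClusterParams(min_size=1))
    run2 = greedy_cluster(sort_by_size(uniques, 1), ClusterParams(min_size=1))
    total = sum(u.size for u in uniques)
    c_sizes = sum(c.size for c in run1[0])
    chim_sizes = sum(u.size for u, _, _ in run1[1])
    assert c_sizes + chim_sizes == total
    assert [c.representative for c in run1[0]] == [c.representative for c in run2[0]]


def test_unsorted_input_rejected():
    uniques = [UniqueSeq("AAAA", 1), UniqueSeq("CCCC", 5)]
    with pytest.raises(ValueError, match="sorted"):
        greedy_cluster(uniques, ClusterParams())
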