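"""p-distance computation against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoxdiv.distance import (DistanceMatrix, distance_matrix, p_distance,
                             within_group_mean)
from hoxdiv.errors import UndefinedResultError, ValidationError
from hoxdiv.seqio import (GroupAssignment, SequenceRecord, build_aligned_set)

from conftest import random_aligned_set, random_nt

UNRESOLVED_NT = set("RYSWKMBDHVN-?")


def oracle_p(a: str, b: str) -> float | None:
    """Site-by-site mismatch counter, written independently of the
    implementation: resolved = plain A/C/G/T on both sides."""
    diff = comp = 0
    for x, y in zip(a, b):
        if x in UNRESOLVED_NT or y in UNRESOLVED_NT:
            continue
        comp += 1
        diff += x != y
    return None if comp == 0 else diff / comp


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACGT", "ACGT", 0.0),
        ("AAAA", "AAAT", 0.25),
        ("AC-T", "ACGT", 0.0),        # gap excluded under pairwise deletion
        ("ANGT", "ACGT", 0.0),        # ambiguity is missing, not mismatch
        ("AAAA", "TTTT", 1.0),
    ],
)
def test_p_distance_examples(a, b, expected):
    assert p_distance(a, b) == pytest.approx(expected)


def test_p_distance_matches_bruteforce_oracle_on_random_pairs():
    rng = np.random.default_rng(11)
    alphabet = list("ACGTN-")
    for _ in range(200):
        L = 75
        a = "".join(rng.choice(alphabet, size=L))
        b = "".join(rng.choice(alphabet, size=L))
        expected = oracle_p(a, b)
        if expected is None:
            with pytest.raises(UndefinedResultError):
                p_distance(a, b)
        else:
            assert p_distance(a, b) == expected


def test_p_distance_errors():
    with pytest.raises(ValidationError):
        p_distance("ACG", "ACGT")
    with pytest.raises(UndefinedResultError):
        p_distance("--NN", "NN--")
    with pytest.raises(ValidationError):
        p_distance("ACGT", "ACGT", deletion_mode="bogus")


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_p_distance_symmetry_and_bounds(seed):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list("ACGTN-"), size=40))
    b = "".join(rng.choice(list("ACGTN-"), size=40))
    try:
        d = p_distance(a, b)
    except UndefinedResultError:
        return
    assert 0.0 <= d <= 1.0
    assert p_distance(b, a) == d
    assert p_distance(a, a) == 0.0


def test_matrix_equals_elementwise_calls_and_is_symmetric():
    rng = np.random.default_rng(3)
    aligned = random_aligned_set(rng, n=6, length=60)
    dm = distance_matrix(aligned)
    for i, a in enumerate(aligned.records):
        for j, b in enumerate(aligned.records):
            if i == j:
                assert dm.values[i, j] == 0.0
            else:
                assert dm.values[i, j] == p_distance(a.sequence, b.sequence)
    assert np.array_equal(dm.values, dm.values.T)


def test_matrix_permutation_invariance():
    rng = np.random.default_rng(4)
    aligned = random_aligned_set(rng, n=5, length=50)
    dm = distance_matrix(aligned)
    perm = [3, 1, 4, 0, 2]
    permuted = build_aligned_set([aligned.records[i] for i in perm])
    dm2 = distance_matrix(permuted)
    for a in aligned.ids:
        for b in aligned.ids:
            if a != b:
                assert dm2.get(a, b) == dm.get(a, b)


def test_all_gap_column_leaves_pairwise_distances_unchanged():
    rng = np.random.default_rng(5)
    aligned = random_aligned_set(rng, n=4, length=30)
    with_gap = build_aligned_set(
        [SequenceRecord(id=r.id, sequence=r.sequence[:10] + "-"
                        + r.sequence[10:])
         for r in aligned.records]
    )
    assert np.array_equal(distance_matrix(aligned).values,
                          distance_matrix(with_gap).values)


def test_complete_deletion_masks_sites_for_every_pair():
    recs = [
        SequenceRecord(id="a", sequence="ACGTA"),
        SequenceRecord(id="b", sequence="ACGTT"),
        SequenceRecord(id="c", sequence="ACGT-"),
    ]
    aligned = build_aligned_set(recs)
    # pairwise: a vs b compare all 5 sites -> 1/5
    assert distance_matrix(aligned).get("a", "b") == pytest.approx(0.2)
    # complete: site 5 (gap in c) masked for every pair -> 0/4
    assert distance_matrix(aligned, deletion_mode="complete").get(
        "a", "b") == 0.0


def test_undefined_cells_are_nan_flagged_not_zero():
    recs = [
        SequenceRecord(id="a", sequence="AC--"),
        SequenceRecord(id="b", sequence="--GT"),
        SequenceRecord(id="c", sequence="ACGT"),
    ]
    dm = distance_matrix(build_aligned_set(recs))
    assert math.isnan(dm.get("a", "b"))
    assert not dm.defined[0, 1] and dm.defined[0, 2]


def test_within_group_mean_enumerated_pairs():
    # three sequences with pairwise p-distances 0.1, 0.2, 0.3 -> mean 20%
    base = "A" * 10
    s1 = SequenceRecord(id="s1", sequence=base)
    s2 = SequenceRecord(id="s2", sequence="C" + base[1:])
    s3 = SequenceRecord(id="s3", sequence="ACC" + base[3:])
    aligned = build_aligned_set([s1, s2, s3])
    assert p_distance(s1.sequence, s2.sequence) == pytest.approx(0.1)
    assert p_distance(s1.sequence, s3.sequence) == pytest.approx(0.2)
    assert p_distance(s2.sequence, s3.sequence) == pytest.approx(0.3)
    groups = GroupAssignment({"s1": "G", "s2": "G", "s3": "G"},
                             {"G": "insect"})
    summary = within_group_mean(aligned, groups, "G")
    assert summary.mean_p_percent == pytest.approx(20.0)
    assert summary.n_taxa == 3 and summary.n_sites == 10


def test_within_group_mean_of_identical_pair_is_zero_and_size1_errors():
    recs = [SequenceRecord(id="a", sequence="ACGT"),
            SequenceRecord(id="b", sequence="ACGT"),
            SequenceRecord(id="solo", sequence="ACGT")]
    aligned = build_aligned_set(recs)
    groups = GroupAssignment(
        {"a": "pair", "b": "pair", "solo": "single"},
        {"pair": "insect", "single": "insect"},
    )
    assert within_group_mean(aligned, groups, "pair").mean_p_percent == 0.0
    with pytest.raises(ValidationError, match="undefined"):
        within_group_mean(aligned, groups, "single")


def test_matrix_writers(tmp_path):
    rng = np.random.default_rng(6)
    dm = distance_matrix(random_aligned_set(rng, n=4, length=40))
    phylip = tmp_path / "m.phy"
    tsv = tmp_path / "m.tsv"
    dm.to_phylip(phylip)
    dm.to_tsv(tsv)
    assert phylip.read_text().splitlines()[0] == "4"
    assert tsv.read_text().count("\n") == 5
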