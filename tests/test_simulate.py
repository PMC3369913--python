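"""Synthetic star-phylogeny generator: determinism, expectation targeting
and bundle round-trips."""

import json

import numpy as np
import pytest

from hoxdiv.distance import distance_matrix
from hoxdiv.errors import ValidationError
from hoxdiv.simulate import (GroupSpec, SimulationSpec,
                             generate_study_fixture,
                             pairwise_substitution_load, simulate_group,
                             study_shaped_spec)
from hoxdiv.seqio import read_fasta, read_group_table


def mean_pairwise_p(aligned) -> float:
    dm = distance_matrix(aligned)
    iu = np.triu_indices(dm.n, k=1)
    return float(dm.values[iu].mean())


def test_rate_zero_gives_identical_sequences():
    aligned = simulate_group("g", 6, 75, 396, 0.0, seed=3)
    assert len({r.sequence for r in aligned.records}) == 1
    assert mean_pairwise_p(aligned) == 0.0


def test_same_seed_reproduces_output_exactly():
    a = simulate_group("g", 5, 75, 396, 0.066, seed=7)
    b = simulate_group("g", 5, 75, 396, 0.066, seed=7)
    assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
    c = simulate_group("g", 5, 75, 396, 0.066, seed=8)
    assert [r.sequence for r in c.records] != [r.sequence for r in a.records]


@pytest.mark.parametrize("model", ["linear", "jukes-cantor"])
def test_mean_p_distance_targets_rate_times_age(model):
    """E[p-hat] = rate x age / 100 under both saturation models."""
    rate, age, L = 0.066, 396.0, 75
    target = rate * age / 100
    reps = [
        mean_pairwise_p(
            simulate_group("g", 12, L, age, rate, saturation_model=model,
                           seed=1000 + i)
        )
        for i in range(60)
    ]
    mean = np.mean(reps)
    mc_se = np.std(reps, ddof=1) / np.sqrt(len(reps))
    assert abs(mean - target) < 3 * mc_se + 1e-4


def test_expected_p_increases_with_age_at_fixed_rate():
    loads = [pairwise_substitution_load(0.04 * age / 100, "linear")
             for age in (100, 300, 500, 700)]
    assert all(b > a for a, b in zip(loads, loads[1:]))
    rng_means = [
        np.mean([
            mean_pairwise_p(simulate_group("g", 10, 300, age, 0.04,
                                           seed=50 + age + i))
            for i in range(10)
        ])
        for age in (100, 500)
    ]
    assert rng_means[1] > rng_means[0]


def test_jukes_cantor_saturation_error():
    with pytest.raises(ValidationError, match="saturated"):
        simulate_group("g", 3, 75, 1000.0, 0.08,
                       saturation_model="jukes-cantor")
    # the linear model caps instead of raising
    aligned = simulate_group("g", 3, 75, 1000.0, 0.08,
                             saturation_model="linear", seed=1)
    assert mean_pairwise_p(aligned) <= 1.0


def test_substitution_load_inversions():
    # at small p the jukes-cantor event load approaches p itself, while
    # the uniform-replacement load includes silent draws (1/4 of events)
    assert pairwise_substitution_load(0.01, "jukes-cantor") == \
        pytest.approx(0.01, rel=0.05)
    assert 0.75 * pairwise_substitution_load(0.01, "linear") == \
        pytest.approx(0.01, rel=0.05)
    # approaching saturation the jukes-cantor load diverges
    assert pairwise_substitution_load(0.70, "jukes-cantor") > 1.5


def test_spec_validation():
    g = GroupSpec("lab", "Insecta", "insect", 9, 396.0, 0.066)
    with pytest.raises(ValidationError):
        SimulationSpec(groups=())
    with pytest.raises(ValidationError):
        SimulationSpec(groups=(g, g))
    with pytest.raises(ValidationError):
        GroupSpec("lab", "Insecta", "insect", 1, 396.0, 0.066)
    with pytest.raises(ValidationError):
        SimulationSpec(groups=(g,), saturation_model="quadratic")


def test_fixture_bundle_roundtrip_and_bit_reproducibility(tmp_path):
    spec = SimulationSpec(
        groups=(
            GroupSpec("lab", "Insecta", "insect", 4, 396.0, 0.06),
            GroupSpec("lab", "Gastropoda", "non-insect", 3, 528.0, 0.04),
            GroupSpec("Dfd", "Insecta", "insect", 2, 396.0, 0.06),
        ),
        sites=75,
        seed=11,
    )
    b1 = generate_study_fixture(spec, tmp_path / "one")
    b2 = generate_study_fixture(spec, tmp_path / "two")
    for name in ("lab.fasta", "Dfd.fasta", "groups.tsv",
                 "calibrations.tsv"):
        assert (b1.root / name).read_text() == (b2.root / name).read_text()

    records = read_fasta(b1.fasta_by_gene["lab"])
    assert len(records) == 7 and all(len(r) == 75 for r in records)
    groups = read_group_table(b1.group_table)
    assert set(groups.groups) == {"Insecta", "Gastropoda"}
    assert groups.group_super["Insecta"] == "insect"
    manifest = json.loads(b1.manifest.read_text())
    assert manifest["seed"] == 11
    assert {g["gene"] for g in manifest["groups"]} == {"lab", "Dfd"}


def test_minimal_bundle_supports_distance_stage(tmp_path):
    spec = SimulationSpec(
        groups=(GroupSpec("lab", "Insecta", "insect", 2, 396.0, 0.05),),
        seed=5,
    )
    bundle = generate_study_fixture(spec, tmp_path)
    from hoxdiv.seqio import build_aligned_set

    aligned = build_aligned_set(read_fasta(bundle.fasta_by_gene["lab"]))
    dm = distance_matrix(aligned)
    assert dm.n == 2 and 0.0 <= dm.values[0, 1] <= 1.0


def test_study_shaped_spec_mirrors_reference_layout(reference_table):
    spec = study_shaped_spec(seed=1)
    assert len(spec.groups) == 60
    assert spec.sites == 75          # modal site count
    insect = [g for g in spec.groups if g.super_label == "insect"]
    assert len(insect) == 8
    assert all(g.age_my == 396.0 for g in insect)
    assert all(g.rate_percent_per_my == 0.06 for g in insect)
    by_key = {(g.gene, g.group): g for g in spec.groups}
    for _, row in reference_table.iterrows():
        assert by_key[(row.gene, row.group)].n_taxa == row.n_taxa
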