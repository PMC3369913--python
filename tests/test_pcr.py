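"""Degenerate-primer arithmetic and in-silico amplification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoxdiv.errors import ValidationError
from hoxdiv.pcr import (IUPAC_SETS, DegeneratePrimer, degeneracy,
                        embed_amplicon, expansions, find_binding_sites,
                        iupac_match, load_packaged_primers,
                        melting_temperature_range, predict_amplicons,
                        primer_pairs, reverse_complement)

iupac_strings = st.text(alphabet=sorted(IUPAC_SETS), min_size=1,
                        max_size=12)


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ACGT", 1),
        ("ACN", 4),
        ("CAAGCGGCAGCGGACNCSNTAYAC", 64),   # N*S*N*Y = 4*2*4*2
        ("NN", 16),
        ("BDHV", 81),
    ],
)
def test_degeneracy_products(seq, expected):
    assert degeneracy(seq) == expected


def test_degeneracy_rejects_illegal_characters():
    with pytest.raises(ValidationError):
        degeneracy("ACGI")


@settings(derandomize=True, max_examples=50)
@given(iupac_strings, iupac_strings)
def test_degeneracy_is_multiplicative_under_concatenation(a, b):
    assert degeneracy(a + b) == degeneracy(a) * degeneracy(b)


def test_expansions_enumerate_the_degeneracy():
    exps = list(expansions("ARN"))
    assert len(exps) == degeneracy("ARN") == 8
    assert len(set(exps)) == 8
    assert all(set(e) <= set("ACGT") for e in exps)


def test_iupac_match_equals_set_membership_exhaustively():
    for code, bases in IUPAC_SETS.items():
        for base in "ACGT":
            assert iupac_match(code, base) == (base in bases)


def test_iupac_match_ambiguous_template_modes():
    with pytest.raises(ValidationError):
        iupac_match("N", "R")                       # strict default
    assert iupac_match("Y", "R", ambiguous_template="intersect") is False
    assert iupac_match("N", "R", ambiguous_template="intersect") is True


def _brute_force_sites(template, primer, max_mismatch):
    """Independent sliding-window oracle over both strands."""
    hits = []
    k = len(primer.sequence)
    for start in range(len(template) - k + 1):
        window = template[start: start + k]
        for strand, target in (("+", window),
                               ("-", reverse_complement(window))):
            mm = sum(t not in IUPAC_SETS[p]
                     for p, t in zip(primer.sequence, target))
            if mm <= max_mismatch:
                hits.append((start, start + k, strand, mm))
    return hits


def test_find_binding_sites_matches_bruteforce_oracle():
    rng = np.random.default_rng(8)
    primer = DegeneratePrimer("p", "ACNTGY", "forward")
    for _ in range(30):
        template = "".join(rng.choice(list("ACGT"), size=60))
        for max_mm in (0, 1):
            got = [(s.start, s.end, s.strand, s.mismatches)
                   for s in find_binding_sites(template, primer, max_mm)]
            assert got == _brute_force_sites(template, primer, max_mm)


def test_embedded_expansion_found_at_known_offset():
    rng = np.random.default_rng(9)
    primer = DegeneratePrimer("fw", "CARGCNTAYAC", "forward")
    for _ in range(20):
        exp = list(expansions(primer))[
            rng.integers(0, degeneracy(primer))
        ]
        left = "".join(rng.choice(list("ACGT"), size=30))
        right = "".join(rng.choice(list("ACGT"), size=30))
        template = left + exp + right
        plus = [s for s in find_binding_sites(template, primer, 0)
                if s.strand == "+"]
        assert (30, 30 + len(primer), "+", 0) in [
            (s.start, s.end, s.strand, s.mismatches) for s in plus
        ]
        # the reverse-complement template carries the site on the minus
        # strand at the mirrored offset
        rc = reverse_complement(template)
        minus = [s for s in find_binding_sites(rc, primer, 0)
                 if s.strand == "-"]
        assert any(s.start == 30 for s in minus)


def test_primer_longer_than_template_yields_no_sites():
    primer = DegeneratePrimer("p", "ACGTACGTAC", "forward")
    assert find_binding_sites("ACGT", primer, 0) == []


def test_template_must_be_plain_bases():
    primer = DegeneratePrimer("p", "ACGT", "forward")
    with pytest.raises(ValidationError):
        find_binding_sites("ACGN", primer, 0)


@pytest.mark.parametrize("pair_index", range(4))
def test_packaged_pairs_amplify_published_product_sizes(pair_index):
    """Templates built from each pair's own expansions yield exactly one
    product of the published fragment length (160/128/145/164 bp)."""
    fw, rev, expected_bp = primer_pairs()[pair_index]
    rng = np.random.default_rng(100 + pair_index)
    template, fw_start = embed_amplicon(fw, rev, expected_bp, rng)
    products = predict_amplicons(template, fw, rev)
    assert len(products) == 1
    (product,) = products
    assert product.product_length == expected_bp
    assert product.forward_site.start == fw_start
    assert product.mismatches == 0


def test_no_reverse_site_means_no_product():
    rng = np.random.default_rng(10)
    fw, rev, _ = primer_pairs()[0]
    exp = next(expansions(fw))
    template = "".join(rng.choice(list("ACGT"), size=40)) + exp
    assert predict_amplicons(template, fw, rev) == []


def test_multiple_site_pairs_enumerated_within_size_range():
    fw = DegeneratePrimer("f", "ACGTAC", "forward")
    rev = DegeneratePrimer("r", "GGATCC", "reverse")
    unit = "ACGTAC" + "T" * 10 + reverse_complement("GGATCC")
    template = unit + "A" * 5 + unit
    products = predict_amplicons(template, fw, rev)
    # 2 forward x 2 reverse sites, 3 orderings compatible
    assert len(products) == 3
    lengths = sorted(p.product_length for p in products)
    assert lengths[0] == len(unit)
    within = predict_amplicons(template, fw, rev,
                               size_range=(1, len(unit)))
    assert len(within) == 2


def test_product_length_invariant_under_reverse_complement_role_swap():
    fw, rev, expected_bp = primer_pairs()[1]
    rng = np.random.default_rng(11)
    template, _ = embed_amplicon(fw, rev, expected_bp, rng)
    swapped_fw = DegeneratePrimer(rev.name, rev.sequence, "forward")
    swapped_rev = DegeneratePrimer(fw.name, fw.sequence, "reverse")
    mirrored = predict_amplicons(reverse_complement(template),
                                 swapped_fw, swapped_rev)
    assert [p.product_length for p in mirrored] == [expected_bp]


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("AAAA", (8, 8)),
        ("GGGG", (16, 16)),
        ("AN", (4, 6)),     # Wallace rule over GC-min/max expansions
        ("SW", (6, 6)),     # S always GC (4), W always AT (2)
    ],
)
def test_wallace_tm_range(seq, expected):
    assert melting_temperature_range(seq) == expected


@settings(derandomize=True, max_examples=50)
@given(iupac_strings)
def test_tm_range_brackets_every_expansion(seq):
    lo, hi = melting_temperature_range(seq)
    assert lo <= hi
    exps = list(expansions(seq)) if degeneracy(seq) <= 64 else []
    for e in exps:
        tm = 2 * sum(c in "AT" for c in e) + 4 * sum(c in "GC" for c in e)
        assert lo <= tm <= hi


def test_packaged_primer_table_contents():
    df = load_packaged_primers()
    assert len(df) == 8 and set(df.pair) == {"Dfd1", "Scr1", "Ubx3", "abdA"}
    pairs = primer_pairs()
    assert [frag for _, _, frag in pairs] == [160, 128, 145, 164]
    assert all(120 <= frag <= 164 for _, _, frag in pairs)
    fw = next(fw for fw, _, _ in pairs if fw.name == "Dfd1fw")
    assert degeneracy(fw) == 64


def test_primer_validation():
    with pytest.raises(ValidationError):
        DegeneratePrimer("bad", "ACGX", "forward")
    with pytest.raises(ValidationError):
        DegeneratePrimer("bad", "ACGT", "sideways")
    with pytest.raises(ValidationError):
        predict_amplicons("ACGT",
                          DegeneratePrimer("a", "AC", "reverse"),
                          DegeneratePrimer("b", "GT", "reverse"))
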