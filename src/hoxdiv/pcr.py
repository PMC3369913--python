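"""Degenerate-primer modelling and in-silico PCR.

The primer pairs validated here are short oligonucleotides written with
IUPAC ambiguity codes so that one primer anneals to a family of homeobox
targets; the degeneracy of a primer is the number of plain-base
oligonucleotides it expands to. Binding-site search slides the primer
along the template (both strands; reverse-orientation primers are matched
against the reverse complement) counting mismatches uniformly across
positions — no 3'-weighting. Product lengths are reported *inclusive of
both primer footprints*, the convention under which the packaged primer
pairs yield their published 120-164 bp products on templates built from
their own expansions.

Melting temperatures use the Wallace rule Tm = 2(A+T) + 4(G+C), reported
as the (min, max) range over GC-minimal and GC-maximal expansions of the
degenerate positions; this is advisory output only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from math import prod
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError

#: IUPAC nucleotide codes -> base sets (the 15 standard codes).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ORIENTATIONS = ("forward", "reverse")


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded PCR primer, written 5'->3'."""

    name: str
    sequence: str
    orientation: str
    reported_annealing_c: float | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(
                f"primer {self.name!r}: illegal IUPAC character(s) "
                f"{sorted(bad)}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"primer {self.name!r}: orientation must be one of "
                f"{ORIENTATIONS}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """Primer footprint on the template, plus-strand 0-based half-open."""

    start: int
    end: int
    strand: str       # "+" or "-"
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product."""

    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.product_length <= 0:
            raise ValidationError("product_length must be > 0")


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of plain-base expansions (product of per-code cardinalities)."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ValidationError(f"illegal IUPAC character(s) {sorted(bad)}")
    return prod(len(IUPAC_SETS[c]) for c in seq)


def expansions(primer: DegeneratePrimer | str) -> Iterator[str]:
    """All plain-base expansions, in lexicographic base order."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    pools = [sorted(IUPAC_SETS[c]) for c in seq.upper()]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def iupac_match(primer_char: str, template_char: str,
                ambiguous_template: str = "strict") -> bool:
    """True iff the template base lies in the primer code's base set.

    ``ambiguous_template`` controls non-ACGT template characters:
    "strict" raises; "intersect" matches when the two base sets overlap.
    """
    p = primer_char.upper()
    t = template_char.upper()
    if p not in IUPAC_SETS:
        raise ValidationError(f"illegal primer character {primer_char!r}")
    if t in "ACGT":
        return t in IUPAC_SETS[p]
    if ambiguous_template == "strict":
        raise ValidationError(
            f"ambiguous template base {template_char!r} (strict mode)"
        )
    if t not in IUPAC_SETS:
        raise ValidationError(f"illegal template character {template_char!r}")
    return bool(IUPAC_SETS[p] & IUPAC_SETS[t])


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _mismatches(primer_seq: str, window: str) -> int:
    return sum(
        0 if iupac_match(p, t) else 1 for p, t in zip(primer_seq, window)
    )


def find_binding_sites(template: str, primer: DegeneratePrimer,
                       max_mismatch: int = 0) -> list[BindingSite]:
    """All footprints of the primer on either strand, ≤ max_mismatch.

    Plus-strand sites are windows of the template matched directly;
    minus-strand sites are windows whose reverse complement the primer
    matches. Reverse-orientation primers bind the minus strand of their
    amplicon, so their productive sites carry strand "-". A primer longer
    than the template yields an empty list. Coordinates are always given
    on the plus strand.
    """
    template = template.upper().replace("U", "T")
    bad = set(template) - set("ACGT")
    if bad:
        raise ValidationError(
            f"template must be plain A/C/G/T; found {sorted(bad)}"
        )
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    k = len(primer)
    n = len(template)
    sites: list[BindingSite] = []
    if k > n:
        return sites
    for start in range(n - k + 1):
        window = template[start: start + k]
        mm_plus = _mismatches(primer.sequence, window)
        if mm_plus <= max_mismatch:
            sites.append(BindingSite(start, start + k, "+", mm_plus))
        mm_minus = _mismatches(primer.sequence, reverse_complement(window))
        if mm_minus <= max_mismatch:
            sites.append(BindingSite(start, start + k, "-", mm_minus))
    return sites


def predict_amplicons(
    template: str,
    fw_primer: DegeneratePrimer,
    rev_primer: DegeneratePrimer,
    max_mismatch: int = 0,
    size_range: tuple[int, int] | None = None,
    template_id: str = "template",
) -> list[AmpliconPrediction]:
    """All products between a plus-strand forward footprint and a
    downstream minus-strand reverse footprint.

    Product length = reverse_site.end - forward_site.start (inclusive of
    both primer footprints). ``size_range`` is an inclusive (lo, hi)
    filter in bp.
    """
    if fw_primer.orientation != "forward":
        raise ValidationError(f"{fw_primer.name!r} is not a forward primer")
    if rev_primer.orientation != "reverse":
        raise ValidationError(f"{rev_primer.name!r} is not a reverse primer")
    fw_sites = [s for s in find_binding_sites(template, fw_primer,
                                              max_mismatch)
                if s.strand == "+"]
    rev_sites = [s for s in find_binding_sites(template, rev_primer,
                                               max_mismatch)
                 if s.strand == "-"]
    out: list[AmpliconPrediction] = []
    for f in fw_sites:
        for r in rev_sites:
            if r.start < f.start or r.end <= f.start:
                continue
            length = r.end - f.start
            if size_range is not None and not (
                size_range[0] <= length <= size_range[1]
            ):
                continue
            out.append(
                AmpliconPrediction(
                    template_id=template_id,
                    forward_site=f,
                    reverse_site=r,
                    product_length=length,
                    mismatches=f.mismatches + r.mismatches,
                )
            )
    return out


def melting_temperature_range(
    primer: DegeneratePrimer | str,
) -> tuple[float, float]:
    """Wallace-rule Tm over GC-minimal and GC-maximal expansions."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    seq = seq.upper().replace("U", "T")
    lo = hi = 0.0
    for c in seq:
        bases = IUPAC_SETS.get(c)
        if bases is None:
            raise ValidationError(f"illegal IUPAC character {c!r}")
        has_at = bool(bases & {"A", "T"})
        has_gc = bool(bases & {"G", "C"})
        lo += 2 if has_at else 4
        hi += 4 if has_gc else 2
    return lo, hi


def load_packaged_primers(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged primer-pair table (pair, name, sequence, orientation,
    annealing °C, expected fragment length in bp)."""
    if path is None:
        ref = resources.files("hoxdiv.data") / "primers.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def primer_pairs(df: pd.DataFrame | None = None
                 ) -> list[tuple[DegeneratePrimer, DegeneratePrimer, int]]:
    """(forward, reverse, expected fragment bp) per packaged pair."""
    if df is None:
        df = load_packaged_primers()
    out = []
    for pair, sub in df.groupby("pair", sort=False):
        fw = sub[sub.orientation == "forward"].iloc[0]
        rv = sub[sub.orientation == "reverse"].iloc[0]
        out.append(
            (
                DegeneratePrimer(fw["name"], fw.sequence, "forward",
                                 float(fw.annealing_c)),
                DegeneratePrimer(rv["name"], rv.sequence, "reverse",
                                 float(rv.annealing_c)),
                int(fw.fragment_bp),
            )
        )
    return out


def embed_amplicon(
    fw_primer: DegeneratePrimer,
    rev_primer: DegeneratePrimer,
    product_length: int,
    rng,
    flank: int = 20,
) -> tuple[str, int]:
    """Construct a plain-base template containing one product of exactly
    ``product_length`` bp: a random expansion of the forward primer, a
    random insert, and the reverse complement of a random expansion of
    the reverse primer, inside random flanks.

    Returns (template, forward-site start). Used to validate the product
    length convention against published fragment sizes.
    """
    insert_len = product_length - len(fw_primer) - len(rev_primer)
    if insert_len < 0:
        raise ValidationError(
            "product_length shorter than the two primer footprints"
        )
    bases = "ACGT"

    def rand_seq(k: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=k))

    def rand_expansion(primer: DegeneratePrimer) -> str:
        return "".join(
            sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))]
            for c in primer.sequence
        )

    fw_exp = rand_expansion(fw_primer)
    rev_exp = rand_expansion(rev_primer)
    left = rand_seq(flank)
    template = (left + fw_exp + rand_seq(insert_len)
                + reverse_complement(rev_exp) + rand_seq(flank))
    return template, len(left)
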