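"""Synthetic homeobox-fragment generator with prescribed divergence.

Each taxon group is simulated as a *star phylogeny*: every lineage
evolves independently from one random ancestral fragment, so the
expected pairwise divergence is controlled exactly and mirrors how a
fossil age bounds the pairwise split (each lineage carries half of the
pair's divergence, rate x age / 2).

Per site and lineage the number of substitution events is
Poisson-distributed. Two saturation models map the target pairwise
p-distance p* = rate x age / 100 to the per-lineage event intensity h:

``linear``
    p* is taken at face value as the expected pairwise mismatch
    proportion. Events replace the site with a base drawn uniformly from
    the full alphabet, under which the pairwise mismatch probability is
    0.75 (1 - exp(-2h)); h is chosen by inverting that curve so that
    E[p-hat] = p* exactly. Targets at or above the 0.75 asymptote are
    capped just below it.
``jukes-cantor``
    p* is read off the Jukes-Cantor saturation curve
    p = 0.75 (1 - exp(-(4/3) d)), with d the expected pairwise
    substitutions per site; events replace the site with one of the
    three *other* bases. Raises "saturated" for p* >= 0.75.

Both models therefore produce an unbiased estimator of the target
p-distance; they differ in event semantics and in the substitution load
they record. All randomness flows from the single spec seed, so bundles
are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .rates import load_reference_rate_table
from .seqio import AlignedSequenceSet, SequenceRecord, write_fasta

SATURATION_MODELS = ("linear", "jukes-cantor")

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class GroupSpec:
    """One simulated (gene, group) cell: its size, age and true rate."""

    gene: str
    group: str
    super_label: str
    n_taxa: int
    age_my: float
    rate_percent_per_my: float

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValidationError("n_taxa must be >= 2")
        if self.age_my <= 0:
            raise ValidationError("age_my must be > 0")
        if self.rate_percent_per_my < 0:
            raise ValidationError("rate must be >= 0")

    @property
    def target_p(self) -> float:
        """Expected pairwise p-distance, as a proportion."""
        return self.rate_percent_per_my * self.age_my / 100.0


@dataclass(frozen=True)
class SimulationSpec:
    """Full study-shaped simulation design."""

    groups: tuple[GroupSpec, ...]
    sites: int = 75
    alphabet: str = "nt"
    seed: int = 0
    saturation_model: str = "linear"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("simulation spec has no groups")
        if self.sites < 1:
            raise ValidationError("sites must be >= 1")
        if self.saturation_model not in SATURATION_MODELS:
            raise ValidationError(
                f"unknown saturation model {self.saturation_model!r}"
            )
        keys = [(g.gene, g.group) for g in self.groups]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (gene, group) in spec")


def _alphabet_array(alphabet: str) -> np.ndarray:
    if alphabet == "nt":
        return _NT
    if alphabet == "aa":
        return _AA
    raise ValidationError(f"unknown alphabet {alphabet!r}")


def _lineage_intensity(target_p: float, saturation_model: str,
                       n_states: int) -> float:
    """Per-site, per-lineage Poisson intensity h for a target pairwise p."""
    cap = 1.0 - 1.0 / n_states          # 0.75 for nucleotides
    if target_p < 0:
        raise ValidationError("target p must be >= 0")
    if saturation_model == "linear":
        p_eff = min(target_p, cap * (1.0 - 1e-9))
        # uniform replacement over all states: p = cap (1 - exp(-2h))
        return -0.5 * math.log1p(-p_eff / cap)
    # jukes-cantor: events go to the other n-1 states;
    # p = cap (1 - exp(-(n/(n-1)) d)) with d the pairwise load = 2h
    if target_p >= cap:
        raise ValidationError(
            f"saturated: target p {target_p:.3f} >= {cap} under the "
            "jukes-cantor model"
        )
    rate_factor = n_states / (n_states - 1.0)
    d = -math.log1p(-target_p / cap) / rate_factor
    return d / 2.0


def pairwise_substitution_load(target_p: float,
                               saturation_model: str = "linear",
                               n_states: int = 4) -> float:
    """Expected substitutions per site on a pair path, by model."""
    h = _lineage_intensity(target_p, saturation_model, n_states)
    return 2.0 * h


def simulate_group(
    label: str,
    n_taxa: int,
    sites: int,
    age_my: float,
    rate_percent_per_my: float,
    saturation_model: str = "linear",
    seed: int | np.random.SeedSequence | None = 0,
    alphabet: str = "nt",
) -> AlignedSequenceSet:
    """Simulate one star-phylogeny group of aligned fragments.

    Taxon ids are ``{label}_t01`` … ``{label}_tNN``. Rate 0 yields
    identical sequences. The same seed always yields the same output.
    """
    if n_taxa < 2:
        raise ValidationError("n_taxa must be >= 2")
    if sites < 1:
        raise ValidationError("sites must be >= 1")
    states = _alphabet_array(alphabet)
    n_states = len(states)
    target_p = rate_percent_per_my * age_my / 100.0
    h = _lineage_intensity(target_p, saturation_model, n_states)
    rng = np.random.default_rng(seed)

    ancestor = rng.integers(0, n_states, size=sites)
    records = []
    width = max(2, len(str(n_taxa)))
    for t in range(n_taxa):
        seq = ancestor.copy()
        hits = rng.poisson(h, size=sites)
        for i in np.nonzero(hits)[0]:
            for _ in range(int(hits[i])):
                if saturation_model == "linear":
                    seq[i] = rng.integers(0, n_states)
                else:  # jukes-cantor: jump to one of the other states
                    step = rng.integers(1, n_states)
                    seq[i] = (seq[i] + step) % n_states
        records.append(
            SequenceRecord(
                id=f"{label}_t{t + 1:0{width}d}",
                sequence="".join(states[seq]),
                alphabet=alphabet,
            )
        )
    return AlignedSequenceSet(tuple(records), alphabet=alphabet)


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of a generated pipeline-ready input bundle."""

    root: Path
    fasta_by_gene: dict[str, Path]
    group_table: Path
    calibration_table: Path
    manifest: Path


def generate_study_fixture(spec: SimulationSpec,
                           outdir: str | Path) -> FixtureBundle:
    """Write a complete input bundle (FASTA per gene, group TSV,
    calibration TSV, ground-truth manifest JSON) for the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(spec.seed)
    children = root_ss.spawn(len(spec.groups))

    genes: dict[str, list] = {}
    group_rows: list[tuple[str, str, str]] = []
    calibrations: dict[str, float] = {}
    for gspec, child in zip(spec.groups, children):
        label = f"{gspec.gene}_{gspec.group.replace(' ', '-')}"
        aligned = simulate_group(
            label, gspec.n_taxa, spec.sites, gspec.age_my,
            gspec.rate_percent_per_my, spec.saturation_model,
            seed=child, alphabet=spec.alphabet,
        )
        genes.setdefault(gspec.gene, []).extend(aligned.records)
        for rec in aligned.records:
            group_rows.append((rec.id, gspec.group, gspec.super_label))
        prior = calibrations.get(gspec.group)
        if prior is not None and prior != gspec.age_my:
            raise ValidationError(
                f"group {gspec.group!r} given two ages "
                f"({prior}, {gspec.age_my})"
            )
        calibrations[gspec.group] = gspec.age_my

    fasta_by_gene = {}
    for gene, records in genes.items():
        path = outdir / f"{gene}.fasta"
        write_fasta(records, path)
        fasta_by_gene[gene] = path

    group_table = outdir / "groups.tsv"
    with open(group_table, "w") as fh:
        fh.write("taxon_id\tgroup\tsuper_label\n")
        seen = set()
        for taxon, group, super_label in group_rows:
            if taxon in seen:
                raise ValidationError(f"duplicate simulated taxon {taxon!r}")
            seen.add(taxon)
            fh.write(f"{taxon}\t{group}\t{super_label}\n")

    calibration_table = outdir / "calibrations.tsv"
    with open(calibration_table, "w") as fh:
        fh.write("group\tage_my\tfossil_name\treference\n")
        for group, age in calibrations.items():
            fh.write(f"{group}\t{age}\tsynthetic\tsimulated fixture\n")

    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "sites": spec.sites,
                "alphabet": spec.alphabet,
                "saturation_model": spec.saturation_model,
                "groups": [asdict(g) for g in spec.groups],
            },
            fh,
            indent=2,
        )
    return FixtureBundle(outdir, fasta_by_gene, group_table,
                         calibration_table, manifest)


def study_shaped_spec(
    seed: int = 0,
    insect_rate: float = 0.06,
    non_insect_rate: float = 0.04,
    sites: int | None = None,
    saturation_model: str = "linear",
) -> SimulationSpec:
    """A simulation design with the reference study's layout.

    Takes gene/group structure, taxa counts, site counts and fossil ages
    from the packaged rate table (8 Hox genes x 6 taxon groups, 60 cells)
    and assigns one true rate per super-label: insect groups evolve at
    ``insect_rate`` %/My and all others at ``non_insect_rate`` %/My — the
    summary means reported for the real data. Used for power and
    end-to-end recovery experiments.
    """
    ref = load_reference_rate_table()
    groups = []
    for _, row in ref.iterrows():
        rate = insect_rate if row.super_label == "insect" else non_insect_rate
        groups.append(
            GroupSpec(
                gene=row.gene,
                group=row.group,
                super_label=row.super_label,
                n_taxa=int(row.n_taxa),
                age_my=float(row.age_my),
                rate_percent_per_my=rate,
            )
        )
    modal_sites = int(ref.n_sites.mode().iloc[0]) if sites is None else sites
    return SimulationSpec(
        groups=tuple(groups),
        sites=modal_sites,
        alphabet="nt",
        seed=seed,
        saturation_model=saturation_model,
    )
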