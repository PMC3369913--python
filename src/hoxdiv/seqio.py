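"""Sequence and metadata I/O.

Defines the aligned-fragment container consumed by every downstream stage
(distances, rate calibration, tree building, classification) together with
readers for the three tabular/sequence formats the pipeline accepts:
FASTA alignments, a taxon -> group assignment table, and a fossil
calibration table (the latter is parsed in :mod:`hoxdiv.rates`).

Sequences are stored uppercase; ``U`` is normalised to ``T`` in nucleotide
input (GenBank mRNA entries). Gap ``-`` and missing characters
(``?``/``N``/``X``) are retained verbatim here — how they are treated is a
distance-stage decision, not a parsing decision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FormatError, ValidationError

#: IUPAC nucleotide codes (incl. ambiguity), gap and missing markers.
NT_ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")
#: The 20 amino acids plus ambiguity X / B / Z / J, stop *, gap and missing.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJ*-?")

ALPHABETS = {"nt": NT_ALPHABET, "aa": AA_ALPHABET}

#: Characters treated as unresolved (gap or missing) per alphabet; used by
#: the distance stage. Ambiguity codes never count as match or mismatch.
NT_UNRESOLVED = frozenset("RYSWKMBDHVN-?")
AA_UNRESOLVED = frozenset("XBZJ*-?")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned homeobox fragment.

    Parameters
    ----------
    id : str
        Unique taxon/clone label (first whitespace-delimited header token).
    sequence : str
        Residues over the declared alphabet, stored uppercase.
    alphabet : {"nt", "aa"}
    description : str
        Full FASTA header (may equal ``id``).
    """

    id: str
    sequence: str
    alphabet: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        if not self.id:
            raise ValidationError("record id must be non-empty")
        seq = self.sequence.upper()
        if self.alphabet == "nt":
            seq = seq.replace("U", "T")
        if not seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - ALPHABETS[self.alphabet]
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"record {self.id!r}: illegal {self.alphabet} character "
                f"{seq[pos]!r} at position {pos + 1}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A set of equal-length aligned fragments (L = "nos. of sites")."""

    records: tuple[SequenceRecord, ...]
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("aligned set must contain >= 1 record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {', '.join(dupes)}")
        L = len(self.records[0])
        offenders = [r.id for r in self.records if len(r) != L]
        if offenders:
            raise ValidationError(
                "aligned records differ in length; offending ids: "
                + ", ".join(offenders)
            )
        for r in self.records:
            if r.alphabet != self.alphabet:
                raise ValidationError(
                    f"record {r.id!r} alphabet {r.alphabet!r} != set "
                    f"alphabet {self.alphabet!r}"
                )

    @property
    def length(self) -> int:
        """Alignment length L in sites."""
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, taxon_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == taxon_id:
                return r
        raise KeyError(taxon_id)

    def subset(self, taxon_ids: Iterable[str]) -> "AlignedSequenceSet":
        wanted = list(taxon_ids)
        missing = [t for t in wanted if t not in self.ids]
        if missing:
            raise ValidationError(f"unknown taxa: {', '.join(missing)}")
        keep = tuple(r for r in self.records if r.id in set(wanted))
        return AlignedSequenceSet(keep, alphabet=self.alphabet)


@dataclass
class GroupAssignment:
    """taxon id -> group label, plus group -> {insect, non-insect}."""

    taxon_to_group: dict[str, str]
    group_super: dict[str, str] = field(default_factory=dict)

    SUPER_LABELS = ("insect", "non-insect")

    def __post_init__(self) -> None:
        if not self.taxon_to_group:
            raise ValidationError("no groups: assignment table is empty")
        for g, s in self.group_super.items():
            if s not in self.SUPER_LABELS:
                raise ValidationError(
                    f"group {g!r}: unknown super_label {s!r} "
                    f"(expected one of {self.SUPER_LABELS})"
                )

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.taxon_to_group.values():
            seen.setdefault(g)
        return tuple(seen)

    def members(self, group: str) -> tuple[str, ...]:
        out = tuple(t for t, g in self.taxon_to_group.items() if g == group)
        if not out:
            raise ValidationError(f"group {group!r} has no members")
        return out


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Ids are the first whitespace-delimited token of the header; the full
    header is retained as ``description``. Order is preserved. An empty
    file yields an empty list.
    """
    records: list[SequenceRecord] = []
    with open(path) as handle:
        head = handle.read(1)
        if not head:
            return records
        if head != ">":
            raise FormatError(f"{path}: not FASTA (first character {head!r})")
        handle.seek(0)
        for bio in SeqIO.parse(handle, "fasta"):
            if not bio.id:
                raise FormatError(f"{path}: FASTA entry with empty header")
            records.append(
                SequenceRecord(
                    id=bio.id,
                    sequence=str(bio.seq),
                    alphabet=alphabet,
                    description=bio.description,
                )
            )
    return records


def write_fasta(records: Sequence[SequenceRecord] | AlignedSequenceSet,
                path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    recs = records.records if isinstance(records, AlignedSequenceSet) else records
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id,
                   description=r.description if r.description != r.id else "")
        for r in recs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(bio)


def build_aligned_set(records: Sequence[SequenceRecord],
                      alphabet: str | None = None) -> AlignedSequenceSet:
    """Assemble records into a length-validated :class:`AlignedSequenceSet`."""
    if not records:
        raise ValidationError("cannot build an aligned set from 0 records")
    if alphabet is None:
        alphabet = records[0].alphabet
    return AlignedSequenceSet(tuple(records), alphabet=alphabet)


def read_group_table(path: str | Path) -> GroupAssignment:
    """Read a TSV with columns ``taxon_id``, ``group``, ``super_label``."""
    taxon_to_group: dict[str, str] = {}
    group_super: dict[str, str] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.strip():
            raise ValidationError(f"{path}: no groups (empty table)")
        cols = header.rstrip("\n").split("\t")
        required = ["taxon_id", "group", "super_label"]
        if cols[: len(required)] != required:
            raise FormatError(
                f"{path}: expected columns {required}, found {cols}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            taxon, group, super_label = parts[0], parts[1], parts[2]
            if taxon in taxon_to_group:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate taxon id {taxon!r}"
                )
            prior = group_super.get(group)
            if prior is not None and prior != super_label:
                raise ValidationError(
                    f"{path}:{lineno}: group {group!r} has conflicting "
                    f"super_labels {prior!r} and {super_label!r}"
                )
            taxon_to_group[taxon] = group
            group_super[group] = super_label
    if not taxon_to_group:
        raise ValidationError(f"{path}: no groups (no data rows)")
    return GroupAssignment(taxon_to_group, group_super)


def fasta_roundtrip_stable(records: Sequence[SequenceRecord]) -> bool:
    """True if write->read reproduces the records (used by property tests)."""
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=None)
    writer.write_file(
        [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    )
    buf.seek(0)
    parsed = [
        SequenceRecord(id=b.id, sequence=str(b.seq),
                       alphabet=records[0].alphabet)
        for b in SeqIO.parse(buf, "fasta")
    ]
    return [(r.id, r.sequence) for r in parsed] == [
        (r.id, r.sequence) for r in records
    ]
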