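"""Distance-based assignment of homeodomain fragments to Hox families.

A query fragment aligned to the common homeodomain frame (amino-acid
positions 1-60) is scored against per-family reference panels by mean
p-distance over the positions resolved in both query and panel member.
The family with the smallest mean distance wins; the gap to the runner-up
is the assignment margin.

Short fragments are the known failure mode: Scr and Antp homeodomains are
identical over positions 20-45, so a query covering only that window ties
between the two families and must be reported as ambiguous rather than
forced into either. Assignments therefore carry an ``ambiguous`` flag
(tie or margin below threshold), the candidate families when ambiguous,
the covered positions, and a ``short_window`` flag when fewer than
``min_window`` positions are covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .distance import p_distance
from .errors import UndefinedResultError, ValidationError
from .seqio import AA_UNRESOLVED, AlignedSequenceSet, SequenceRecord

#: Canonical insect Hox/homeotic family labels, anterior to posterior.
HOX_FAMILIES = ("lab", "pb", "Hox3", "Dfd", "Scr", "ftz", "Antp",
                "Ubx", "abd-A", "Abd-B")

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class HoxReferencePanel:
    """Aligned reference members of one Hox family (common frame)."""

    family: str
    members: AlignedSequenceSet

    @property
    def length(self) -> int:
        return self.members.length


@dataclass(frozen=True)
class AssignmentResult:
    query_id: str
    best_family: str
    best_distance: float
    margin: float | None          # None when only one panel is scorable
    ambiguous: bool
    candidates: tuple[str, ...]   # best family first
    covered_positions: tuple[int, ...]  # 1-based frame coordinates
    short_window: bool
    distances: Mapping[str, float] = field(default_factory=dict)


def covered_positions(query: SequenceRecord) -> tuple[int, ...]:
    """1-based positions where the query carries a resolved residue."""
    return tuple(
        i + 1
        for i, c in enumerate(query.sequence)
        if c not in AA_UNRESOLVED
    )


def translate_query(record: SequenceRecord, frame: int = 0) -> SequenceRecord:
    """Translate a nucleotide fragment into the amino-acid frame.

    Standard genetic code; codons containing anything but A/C/G/T
    translate to X; a trailing partial codon is dropped. The reading
    frame (0, 1 or 2) must be supplied by the caller.
    """
    if record.alphabet != "nt":
        raise ValidationError("translate_query expects a nucleotide record")
    if frame not in (0, 1, 2):
        raise ValidationError("frame must be 0, 1 or 2")
    nt = record.sequence[frame:]
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i: i + 3]
        if set(codon) <= set("ACGT"):
            aa.append(str(Seq(codon).translate()))
        else:
            aa.append("X")
    if not aa:
        raise ValidationError(f"query {record.id!r}: no complete codon")
    return SequenceRecord(id=record.id, sequence="".join(aa), alphabet="aa",
                          description=record.description)


def _mean_panel_distance(query: SequenceRecord,
                         panel: HoxReferencePanel) -> float | None:
    """Mean p-distance from the query to the panel members over shared
    resolved positions; None if no member shares a resolved position."""
    dists = []
    for member in panel.members.records:
        try:
            dists.append(
                p_distance(query.sequence, member.sequence, alphabet="aa")
            )
        except UndefinedResultError:
            continue
    if not dists:
        return None
    return sum(dists) / len(dists)


def assign_family(
    query: SequenceRecord,
    panels: Sequence[HoxReferencePanel],
    ambiguity_margin: float = 0.0,
    min_window: int = 30,
) -> AssignmentResult:
    """Assign a query fragment to the closest Hox family panel.

    The query must be aligned to the panels' coordinate frame (equal
    length; unresolved characters mark uncovered positions). Ambiguity is
    declared on an exact tie for best distance or a runner-up margin
    below ``ambiguity_margin``.
    """
    if not panels:
        raise ValidationError("no reference panels supplied")
    L = panels[0].length
    for p in panels[1:]:
        if p.length != L:
            raise ValidationError("panels are not in a common frame")
    if len(query) != L:
        raise ValidationError(
            f"query {query.id!r} length {len(query)} != panel frame {L}"
        )
    fams = [p.family for p in panels]
    if len(set(fams)) != len(fams):
        raise ValidationError("family labels must be unique across panels")

    scores: dict[str, float] = {}
    for panel in panels:
        dist = _mean_panel_distance(query, panel)
        if dist is not None:
            scores[panel.family] = dist
    if not scores:
        raise ValidationError(
            f"query {query.id!r}: no overlapping resolved positions with "
            "any panel"
        )
    ranked = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    best_family, best_dist = ranked[0]
    margin = (ranked[1][1] - best_dist) if len(ranked) > 1 else None
    tied = [f for f, dv in ranked if dv - best_dist <= _TIE_TOL]
    ambiguous = len(tied) > 1 or (
        margin is not None and margin < ambiguity_margin
    )
    if ambiguous:
        thresh = max(ambiguity_margin, _TIE_TOL)
        candidates = tuple(f for f, dv in ranked if dv - best_dist <= thresh)
    else:
        candidates = (best_family,)
    covered = covered_positions(query)
    return AssignmentResult(
        query_id=query.id,
        best_family=best_family,
        best_distance=best_dist,
        margin=margin,
        ambiguous=ambiguous,
        candidates=candidates,
        covered_positions=covered,
        short_window=len(covered) < min_window,
        distances=dict(ranked),
    )


def diagnostic_positions(panel_a: HoxReferencePanel,
                         panel_b: HoxReferencePanel) -> list[int]:
    """1-based frame positions whose observed residue sets are disjoint.

    These are the positions that can in principle discriminate the two
    families; unresolved characters are ignored when collecting each
    panel's residue set at a position.
    """
    if panel_a.length != panel_b.length:
        raise ValidationError("panels are not in a common frame")
    out = []
    for i in range(panel_a.length):
        set_a = {
            r.sequence[i] for r in panel_a.members.records
            if r.sequence[i] not in AA_UNRESOLVED
        }
        set_b = {
            r.sequence[i] for r in panel_b.members.records
            if r.sequence[i] not in AA_UNRESOLVED
        }
        if set_a and set_b and not (set_a & set_b):
            out.append(i + 1)
    return out
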