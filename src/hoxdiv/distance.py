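"""Uncorrected p-distances and within-group mean divergences.

The headline statistic of the whole pipeline is the *p*-distance: the
proportion of aligned sites at which two fragments carry different
resolved characters. No multiple-hit correction is applied anywhere in
the rate path — saturation therefore biases the resulting rates downward,
which is an acknowledged property of the analysis, not a defect.

Two deletion modes are exposed:

``pairwise``
    Sites where either member of the pair is unresolved are dropped for
    that pair only (the default; appropriate for fragmentary data).
``complete``
    Sites where *any* sequence in the set is unresolved are masked for
    every pair (a complete-deletion mask over the whole set).

Ambiguity codes (``N``, ``R``, ``Y`` … for nucleotides; ``X`` … for amino
acids) count as missing — never as a match or mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import UndefinedResultError, ValidationError
from .seqio import (AA_UNRESOLVED, NT_UNRESOLVED, AlignedSequenceSet,
                    GroupAssignment)

DELETION_MODES = ("pairwise", "complete")


def _unresolved(alphabet: str) -> frozenset[str]:
    return NT_UNRESOLVED if alphabet == "nt" else AA_UNRESOLVED


def p_distance(seq_a: str, seq_b: str, deletion_mode: str = "pairwise",
               alphabet: str = "nt",
               mask: Sequence[bool] | None = None) -> float:
    """Proportion of differing resolved sites between two aligned sequences.

    Parameters
    ----------
    mask : optional boolean sequence
        Sites flagged True are excluded before comparison (used by the
        complete-deletion mode; ignored under pairwise deletion unless
        supplied explicitly).

    Raises
    ------
    ValidationError
        If the sequences differ in length.
    UndefinedResultError
        If no site is resolved in both sequences: the distance is
        *undefined*, explicitly not 0.
    """
    if deletion_mode not in DELETION_MODES:
        raise ValidationError(f"unknown deletion_mode {deletion_mode!r}")
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"length mismatch: {len(seq_a)} vs {len(seq_b)} sites"
        )
    unresolved = _unresolved(alphabet)
    diffs = 0
    comparable = 0
    for i, (a, b) in enumerate(zip(seq_a.upper(), seq_b.upper())):
        if mask is not None and mask[i]:
            continue
        if a in unresolved or b in unresolved:
            continue
        comparable += 1
        if a != b:
            diffs += 1
    if comparable == 0:
        raise UndefinedResultError(
            "p-distance undefined: no site resolved in both sequences"
        )
    return diffs / comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances.

    ``values[i, j]`` is NaN where the distance is undefined (no comparable
    sites); ``defined`` flags those cells. Diagonal is zero by construction.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        v = self.values
        if v.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValidationError("diagonal must be zero")
        finite = ~np.isnan(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValidationError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_phylip(self, path: str | Path) -> None:
        """Write as a PHYLIP square matrix (relaxed label width)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.values):
                cells = " ".join(f"{x:.6f}" for x in row)
                fh.write(f"{lab}  {cells}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                cells = "\t".join("NA" if math.isnan(x) else f"{x:.6f}"
                                  for x in row)
                fh.write(f"{lab}\t{cells}\n")


def complete_deletion_mask(aligned: AlignedSequenceSet) -> np.ndarray:
    """True at sites where any sequence in the set is unresolved."""
    unresolved = _unresolved(aligned.alphabet)
    mask = np.zeros(aligned.length, dtype=bool)
    for rec in aligned.records:
        for i, c in enumerate(rec.sequence):
            if c in unresolved:
                mask[i] = True
    return mask


def distance_matrix(aligned: AlignedSequenceSet,
                    deletion_mode: str = "pairwise") -> DistanceMatrix:
    """All pairwise p-distances of an aligned set.

    Each cell is computed by the same per-pair path as :func:`p_distance`
    (no accumulation shortcuts), so the matrix and per-pair routes agree
    exactly. Undefined pairs are stored as NaN rather than raising.
    """
    if len(aligned) < 2:
        raise ValidationError("distance matrix needs >= 2 records")
    mask = (complete_deletion_mask(aligned)
            if deletion_mode == "complete" else None)
    n = len(aligned)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = p_distance(
                    aligned.records[i].sequence,
                    aligned.records[j].sequence,
                    deletion_mode="pairwise" if mask is None else "complete",
                    alphabet=aligned.alphabet,
                    mask=mask,
                )
            except UndefinedResultError:
                d = math.nan
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(aligned.ids, vals)


@dataclass(frozen=True)
class GroupDistanceSummary:
    """Mean within-group pairwise p-distance, in percent."""

    group: str
    n_taxa: int
    n_sites: int
    mean_p_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_p_percent <= 100.0:
            raise ValidationError("mean p%% outside [0, 100]")

    def rounded(self, ndigits: int = 1) -> float:
        """Report-time rounding (1 decimal mirrors the rate-table layout)."""
        return round(self.mean_p_percent, ndigits)


def within_group_mean(aligned: AlignedSequenceSet, groups: GroupAssignment,
                      group_label: str,
                      deletion_mode: str = "pairwise") -> GroupDistanceSummary:
    """Arithmetic mean p-distance over all C(n,2) pairs in one group, x100.

    Undefined pairs (no comparable sites) are excluded from the mean; a
    group whose pairs are all undefined raises.
    """
    members = [t for t in groups.members(group_label) if t in aligned.ids]
    if len(members) < 2:
        raise ValidationError(
            f"group {group_label!r}: mean undefined for fewer than 2 "
            "members present in the alignment"
        )
    sub = aligned.subset(members)
    dm = distance_matrix(sub, deletion_mode=deletion_mode)
    iu = np.triu_indices(dm.n, k=1)
    pairs = dm.values[iu]
    pairs = pairs[~np.isnan(pairs)]
    if pairs.size == 0:
        raise UndefinedResultError(
            f"group {group_label!r}: every pair undefined"
        )
    return GroupDistanceSummary(
        group=group_label,
        n_taxa=len(members),
        n_sites=aligned.length,
        mean_p_percent=float(pairs.mean()) * 100.0,
    )
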