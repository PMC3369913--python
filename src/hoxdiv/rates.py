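"""Fossil-calibrated divergence rates.

The conversion at the heart of the analysis is the quotient

    rate (% per My) = mean within-group p-distance (%) / fossil age (My)

where the fossil age is the minimum age of the group's oldest crown-group
fossil. Ages are treated as fixed constants; no uncertainty is propagated
through the quotient. Rates are reported to 3 decimals; summary statistics
always use the unrounded values.

A transcription of the study's published per-gene, per-group table
(p-distances, taxa/site counts, fossil ages and printed rates) ships as a
packaged fixture so the full arithmetic can be reproduced without any
sequence download; :func:`load_reference_rate_table` returns it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distance import GroupDistanceSummary
from .errors import ValidationError


@dataclass(frozen=True)
class FossilCalibration:
    """Minimum age (My) of a taxon group, with its supporting fossil."""

    group: str
    age_my: float
    fossil_name: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.age_my > 0:
            raise ValidationError(
                f"calibration {self.group!r}: age must be > 0 My"
            )


@dataclass(frozen=True)
class RateEstimate:
    """One (gene, group) divergence-rate row."""

    gene: str
    group: str
    n_taxa: int
    n_sites: int
    mean_p_percent: float
    age_my: float
    rate_percent_per_my: float
    super_label: str = ""

    def __post_init__(self) -> None:
        if self.rate_percent_per_my < 0:
            raise ValidationError("rate must be >= 0")
        expected = self.mean_p_percent / self.age_my
        if not math.isclose(self.rate_percent_per_my, expected,
                            rel_tol=0, abs_tol=1e-12):
            raise ValidationError(
                f"{self.gene}/{self.group}: rate != mean_p_percent / age_my"
            )

    @property
    def rate_rounded(self) -> float:
        return round(self.rate_percent_per_my, 3)


def divergence_rate(mean_p_percent: float, age_my: float) -> float:
    """Absolute divergence rate in % per million years."""
    if age_my <= 0:
        raise ValidationError("age_my must be > 0")
    if mean_p_percent < 0:
        raise ValidationError("mean_p_percent must be >= 0")
    return mean_p_percent / age_my


@dataclass(frozen=True)
class RateTable:
    """Collection of :class:`RateEstimate` rows, unique per (gene, group)."""

    rows: tuple[RateEstimate, ...]

    def __post_init__(self) -> None:
        keys = [(r.gene, r.group) for r in self.rows]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (gene, group) rows: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def rates(self, super_label: str | None = None) -> np.ndarray:
        """Unrounded rate values, optionally filtered by super-label."""
        sel = [r.rate_percent_per_my for r in self.rows
               if super_label is None or r.super_label == super_label]
        return np.asarray(sel, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.rows],
                "group": [r.group for r in self.rows],
                "super_label": [r.super_label for r in self.rows],
                "n_taxa": [r.n_taxa for r in self.rows],
                "n_sites": [r.n_sites for r in self.rows],
                "mean_p_percent": [r.mean_p_percent for r in self.rows],
                "age_my": [r.age_my for r in self.rows],
                "rate_percent_per_my": [r.rate_percent_per_my
                                        for r in self.rows],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write with report-time rounding: p% to 1 decimal, rate to 3."""
        df = self.to_frame()
        df["mean_p_percent"] = df["mean_p_percent"].round(1)
        df["rate_percent_per_my"] = df["rate_percent_per_my"].map(
            lambda r: f"{r:.3f}"
        )
        df.to_csv(path, sep="\t", index=False)


def build_rate_table(
    summaries: Sequence[tuple[str, GroupDistanceSummary]],
    calibrations: Iterable[FossilCalibration],
    super_labels: dict[str, str] | None = None,
) -> RateTable:
    """Combine (gene, group-summary) pairs with fossil ages into rates.

    Parameters
    ----------
    summaries : sequence of (gene label, GroupDistanceSummary)
    calibrations : fossil calibrations; every summary group needs one
    super_labels : optional group -> {insect, non-insect} map
    """
    cal = {c.group: c for c in calibrations}
    rows = []
    for gene, s in summaries:
        if s.group not in cal:
            raise ValidationError(
                f"no fossil calibration for group {s.group!r}"
            )
        age = cal[s.group].age_my
        rows.append(
            RateEstimate(
                gene=gene,
                group=s.group,
                n_taxa=s.n_taxa,
                n_sites=s.n_sites,
                mean_p_percent=s.mean_p_percent,
                age_my=age,
                rate_percent_per_my=divergence_rate(s.mean_p_percent, age),
                super_label=(super_labels or {}).get(s.group, ""),
            )
        )
    return RateTable(tuple(rows))


@dataclass(frozen=True)
class RateSummary:
    """Mean, dispersion and n of a set of rates (one value per gene x group).

    Both SD and SE are reported: published dispersion figures for pooled
    non-insect rates are consistent with an SD, while the insect figure is
    an SE, so neither convention is forced on the reader.
    """

    super_label: str
    n: int
    mean: float
    sd: float        # sample SD, n-1 denominator; NaN when n == 1
    se: float        # sd / sqrt(n); NaN when n == 1


def group_rate_summary(table: RateTable, super_label: str) -> RateSummary:
    """Summarise one rate value per (gene, group) row under a super-label."""
    vals = table.rates(super_label)
    if vals.size == 0:
        raise ValidationError(f"no rates with super_label {super_label!r}")
    if vals.size == 1:
        return RateSummary(super_label, 1, float(vals[0]),
                           math.nan, math.nan)
    sd = float(vals.std(ddof=1))
    return RateSummary(
        super_label,
        int(vals.size),
        float(vals.mean()),
        sd,
        sd / math.sqrt(vals.size),
    )


def read_calibration_table(path: str | Path) -> list[FossilCalibration]:
    """Read a TSV with columns group, age_my, fossil_name, reference."""
    df = pd.read_csv(path, sep="\t")
    required = {"group", "age_my"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: calibration table needs columns {sorted(required)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            FossilCalibration(
                group=str(row["group"]),
                age_my=float(row["age_my"]),
                fossil_name=str(row.get("fossil_name", "") or ""),
                reference=str(row.get("reference", "") or ""),
            )
        )
    if not out:
        raise ValidationError(f"{path}: empty calibration table")
    return out


def load_packaged_calibrations() -> list[FossilCalibration]:
    """The packaged fossil calibration table (six groups, 195–528 My)."""
    with resources.as_file(
        resources.files("hoxdiv.data") / "calibrations.tsv"
    ) as p:
        return read_calibration_table(p)


def load_reference_rate_table(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged transcription of the published per-gene rate table.

    Columns: gene, group, super_label, n_taxa, n_sites, mean_p_percent,
    age_my, printed_rate. 60 rows; 8 of them Insecta (one per Hox gene).
    """
    if path is None:
        ref = resources.files("hoxdiv.data") / "published_rates.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def rate_table_from_precomputed(df: pd.DataFrame) -> RateTable:
    """Build a :class:`RateTable` from precomputed-distance rows.

    Expects columns gene, group, n_taxa, n_sites, mean_p_percent, age_my
    and optionally super_label; the rate column is recomputed from scratch.
    """
    rows = []
    for _, r in df.iterrows():
        rows.append(
            RateEstimate(
                gene=str(r["gene"]),
                group=str(r["group"]),
                n_taxa=int(r["n_taxa"]),
                n_sites=int(r["n_sites"]),
                mean_p_percent=float(r["mean_p_percent"]),
                age_my=float(r["age_my"]),
                rate_percent_per_my=divergence_rate(
                    float(r["mean_p_percent"]), float(r["age_my"])
                ),
                super_label=str(r.get("super_label", "") or ""),
            )
        )
    return RateTable(tuple(rows))
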