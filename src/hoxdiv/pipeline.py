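"""End-to-end orchestration: distances -> rates -> comparison -> trees.

Two input modes are supported:

* **full-sequence mode** — per-gene FASTA alignments plus a group table
  and a calibration table; within-group mean p-distances are computed
  from the sequences;
* **precomputed-distance mode** — a TSV of (gene, group, n_taxa,
  n_sites, mean p%) rows, joined against the calibration table. This is
  the mode that reproduces the published rate arithmetic exactly without
  any sequence data.

Both modes feed the identical downstream path (rate table, super-label
summaries, Mann-Whitney comparison, optional NJ tree per gene), so when
the sequence-derived mean p%% equals the precomputed value the results
coincide.

Every run writes an effective-config snapshot and a stage-by-stage log;
on failure all partial outputs of the run are removed and the error is
re-raised with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import classify as _classify
from .compare import ComparisonResult, mann_whitney_u
from .distance import distance_matrix, within_group_mean
from .errors import HoxdivError, ValidationError
from .nj import neighbor_joining, to_newick
from .rates import (FossilCalibration, RateSummary, RateTable,
                    build_rate_table, group_rate_summary,
                    load_packaged_calibrations, rate_table_from_precomputed,
                    read_calibration_table)
from .seqio import (AlignedSequenceSet, build_aligned_set, read_fasta,
                    read_group_table)

logger = logging.getLogger("hoxdiv")


@dataclass
class AnalysisConfig:
    """Run configuration for :func:`run_rate_analysis`.

    Exactly one of ``fasta_by_gene`` (full-sequence mode) or
    ``precomputed_table`` (precomputed-distance mode) must be given.
    """

    output_dir: Path
    fasta_by_gene: Mapping[str, Path] | None = None
    group_table: Path | None = None
    calibration_table: Path | None = None  # None -> packaged calibrations
    precomputed_table: Path | None = None
    deletion_mode: str = "pairwise"
    comparison_method: str = "auto"
    ambiguity_margin: float = 0.0
    seed: int = 0
    p_percent_decimals: int = 1
    rate_decimals: int = 3
    write_trees: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if (self.fasta_by_gene is None) == (self.precomputed_table is None):
            raise ValidationError(
                "config must set exactly one of fasta_by_gene / "
                "precomputed_table"
            )
        if self.p_percent_decimals <= 0 or self.rate_decimals <= 0:
            raise ValidationError("precision settings must be positive")
        for path in self._input_paths():
            if not Path(path).exists():
                raise ValidationError(f"input path does not exist: {path}")

    def _input_paths(self) -> list[Path]:
        paths: list[Path] = []
        if self.fasta_by_gene:
            paths.extend(self.fasta_by_gene.values())
        for p in (self.group_table, self.calibration_table,
                  self.precomputed_table):
            if p is not None:
                paths.append(p)
        return paths

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: ({g: str(p) for g, p in v.items()} if isinstance(v, dict)
                else str(v) if isinstance(v, Path) else v)
            for k, v in d.items()
        }


@dataclass
class RateAnalysisReport:
    """In-memory result of a rate-analysis run."""

    rate_table: RateTable
    summaries: dict[str, RateSummary]
    comparison: ComparisonResult
    output_files: list[Path] = field(default_factory=list)


def _configure_logging(run_log: Path) -> logging.Handler:
    handler = logging.FileHandler(run_log)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and h.stream is sys.stderr for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setLevel(logging.WARNING)
        logger.addHandler(stream)
    return handler


def _calibrations(config: AnalysisConfig) -> list[FossilCalibration]:
    if config.calibration_table is None:
        return load_packaged_calibrations()
    return read_calibration_table(config.calibration_table)


def _rate_table_from_sequences(config: AnalysisConfig) -> RateTable:
    if config.group_table is None:
        raise ValidationError("full-sequence mode requires group_table")
    groups = read_group_table(config.group_table)
    calibrations = _calibrations(config)
    summaries = []
    for gene, fasta in config.fasta_by_gene.items():
        records = read_fasta(fasta)
        if not records:
            logger.warning("gene %s: empty FASTA, skipped", gene)
            continue
        aligned = build_aligned_set(records)
        present = [t for t in aligned.ids if t in groups.taxon_to_group]
        gene_groups = sorted({groups.taxon_to_group[t] for t in present})
        for g in gene_groups:
            members = [t for t in groups.members(g) if t in aligned.ids]
            if len(members) < 2:
                logger.warning("gene %s group %s: <2 members, skipped",
                               gene, g)
                continue
            summaries.append(
                (gene, within_group_mean(aligned, groups, g,
                                         deletion_mode=config.deletion_mode))
            )
        logger.info("gene %s: %d sites, %d groups summarised",
                    gene, aligned.length, len(gene_groups))
    return build_rate_table(summaries, calibrations,
                            super_labels=groups.group_super)


def _rate_table_precomputed(config: AnalysisConfig) -> RateTable:
    df = pd.read_csv(config.precomputed_table, sep="\t")
    required = {"gene", "group", "n_taxa", "n_sites", "mean_p_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"precomputed table missing columns {sorted(missing)}"
        )
    if "age_my" not in df.columns:
        ages = {c.group: c.age_my for c in _calibrations(config)}
        unknown = sorted(set(df.group) - set(ages))
        if unknown:
            raise ValidationError(
                f"no fossil calibration for group(s) {unknown}"
            )
        df = df.assign(age_my=df.group.map(ages))
    logger.info("precomputed-distance mode: %d rows", len(df))
    return rate_table_from_precomputed(df)


def run_rate_analysis(config: AnalysisConfig) -> RateAnalysisReport:
    """Run the full divergence-rate analysis and write the report bundle.

    Outputs in ``config.output_dir``: rate_table.tsv, summary.json,
    comparison.json, effective_config.json, run.log and (optionally)
    one Newick tree per gene.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = _configure_logging(outdir / "run.log")
    written.append(outdir / "run.log")
    stage = "configuration"
    try:
        snap = outdir / "effective_config.json"
        snap.write_text(json.dumps(config.snapshot(), indent=2))
        written.append(snap)

        stage = "distance/rate-table"
        if config.precomputed_table is not None:
            table = _rate_table_precomputed(config)
        else:
            table = _rate_table_from_sequences(config)
        if len(table) == 0:
            raise ValidationError("rate table is empty")
        table_path = outdir / "rate_table.tsv"
        table.to_tsv(table_path)
        written.append(table_path)
        logger.info("rate table: %d (gene, group) rows", len(table))

        stage = "super-label summary"
        labels = sorted({r.super_label for r in table.rows if r.super_label})
        summaries = {lab: group_rate_summary(table, lab) for lab in labels}
        summary_path = outdir / "summary.json"
        summary_path.write_text(
            json.dumps({lab: dataclasses.asdict(s)
                        for lab, s in summaries.items()}, indent=2)
        )
        written.append(summary_path)

        stage = "group comparison"
        if {"insect", "non-insect"} <= set(summaries):
            comparison = mann_whitney_u(
                table.rates("insect"),
                table.rates("non-insect"),
                method=config.comparison_method,
            )
        else:
            raise ValidationError(
                "comparison needs both insect and non-insect rates"
            )
        cmp_path = outdir / "comparison.json"
        cmp_path.write_text(comparison.to_json())
        written.append(cmp_path)
        logger.info("U=%.1f (n1=%d, n2=%d), two-sided p=%.3g [%s]",
                    comparison.U, comparison.n1, comparison.n2,
                    comparison.p_two_sided, comparison.method)

        if config.write_trees and config.fasta_by_gene:
            stage = "NJ trees"
            for gene, fasta in config.fasta_by_gene.items():
                records = read_fasta(fasta)
                if len(records) < 3:
                    continue
                dm = distance_matrix(build_aligned_set(records),
                                     deletion_mode=config.deletion_mode)
                tree_path = outdir / f"{gene}.nwk"
                tree_path.write_text(to_newick(neighbor_joining(dm)) + "\n")
                written.append(tree_path)

        return RateAnalysisReport(table, summaries, comparison, written)
    except Exception as exc:
        for path in written:
            if path.name != "run.log":
                path.unlink(missing_ok=True)
        raise HoxdivError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_classification(
    query_fasta: Path,
    panel_fastas: Mapping[str, Path],
    output_path: Path | None = None,
    ambiguity_margin: float = 0.0,
    min_window: int = 30,
) -> pd.DataFrame:
    """Assign each query fragment to a Hox family; write a report TSV.

    Queries and panels are amino-acid FASTA aligned to the common
    homeodomain frame. An empty query file yields an empty report with a
    warning. Ambiguous queries list their candidate families.
    """
    panels = []
    for family, path in panel_fastas.items():
        records = read_fasta(path, alphabet="aa")
        if not records:
            raise ValidationError(f"panel {family!r}: empty FASTA")
        panels.append(
            _classify.HoxReferencePanel(family, build_aligned_set(records))
        )
    queries = read_fasta(query_fasta, alphabet="aa")
    if not queries:
        logger.warning("empty query file %s", query_fasta)
    rows = []
    for q in queries:
        res = _classify.assign_family(
            q, panels, ambiguity_margin=ambiguity_margin,
            min_window=min_window,
        )
        rows.append(
            {
                "query_id": res.query_id,
                "best_family": res.best_family,
                "best_distance": round(res.best_distance, 6),
                "margin": ("" if res.margin is None
                           else round(res.margin, 6)),
                "ambiguous": res.ambiguous,
                "candidates": ",".join(res.candidates),
                "n_covered": len(res.covered_positions),
                "short_window": res.short_window,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["query_id", "best_family", "best_distance", "margin",
                 "ambiguous", "candidates", "n_covered", "short_window"],
    )
    if output_path is not None:
        df.to_csv(output_path, sep="\t", index=False)
    return df
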