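"""Accounting summaries and end-to-end pipeline orchestration.

The per-library summary mirrors the standard tag-DGE accounting table:
clean tags, unambiguously mapped tags (count and % of clean tags),
unambiguous tag-matched genes (count and % of all reference genes),
and unknown tags (count and % of clean tags), with a totals row
and a rounded-mean row. Percentages always recompute from the absolute
numbers of their own row, to two decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crossval as crossval_mod
from .detest import DEThresholds, call_all
from .preprocess import TagLibrary, filter_raw_tags, write_filter_log
from .quantify import MULTIREAD_CAP, ExpressionMatrix
from .refdb import ReferenceTagDB, build_db
from .tagmap import MappingResult, map_library
from .trajectory import (
    StageDesign,
    cluster_profiles,
    default_design,
    process_venn,
    updown_histogram,
)

TOTAL_ROW = "Total"
AVERAGE_ROW = "Average"


def format_percent(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to two decimals, as printed in
    accounting tables (e.g. 1361344/3574921 -> 38.08)."""
    if denominator == 0:
        return float("nan")
    # round-half-up at the second decimal; banker's rounding would turn
    # e.g. 0.125 into 0.12
    return float(np.floor(numerator / denominator * 10000 + 0.5) / 100)


def format_percent_str(numerator: float, denominator: float) -> str:
    value = format_percent(numerator, denominator)
    return "nan" if np.isnan(value) else f"{value:.2f}"


def summary_table(
    rows: pd.DataFrame | Sequence[Mapping],
    reference_gene_total: int | None = None,
) -> pd.DataFrame:
    """Accounting table with per-library rows plus Total and Average.

    ``rows`` needs columns: library, clean_tags, unambiguous_tags,
    unambiguous_genes, unknown_tags (missing count columns are simply
    omitted from the output). Averages are rounded to the nearest
    integer; percentages recompute from each row's own numbers.
    """
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=["library", "clean_tags", "unambiguous_tags",
                     "unambiguous_pct", "unambiguous_genes",
                     "unambiguous_genes_pct", "unknown_tags", "unknown_pct"]
        ).set_index("library")
    table = table.set_index("library")
    count_cols = [c for c in ("clean_tags", "unambiguous_tags",
                              "unambiguous_genes", "unknown_tags")
                  if c in table.columns]
    table = table[count_cols]
    totals = table.sum()
    means = table.mean().map(lambda v: int(np.floor(v + 0.5)))
    table.loc[TOTAL_ROW] = totals
    table.loc[AVERAGE_ROW] = means
    table = table.astype("int64")

    def pct_column(name, num_col, den):
        """Row-wise percentage; the Average row carries the mean of the
        per-library percentages (the printed-table convention), not the
        ratio of the column means."""
        values = {}
        for label, row in table.iterrows():
            denominator = den if isinstance(den, (int, float)) else row[den]
            values[label] = format_percent(row[num_col], denominator)
        library_pcts = [v for k, v in values.items()
                        if k not in (TOTAL_ROW, AVERAGE_ROW)]
        values[AVERAGE_ROW] = float(
            np.floor(np.mean(library_pcts) * 100 + 0.5) / 100
        )
        table[name] = pd.Series(values)

    if "unambiguous_tags" in table.columns and "clean_tags" in table.columns:
        pct_column("unambiguous_pct", "unambiguous_tags", "clean_tags")
    if "unambiguous_genes" in table.columns and reference_gene_total:
        pct_column("unambiguous_genes_pct", "unambiguous_genes",
                   reference_gene_total)
    if "unknown_tags" in table.columns and "clean_tags" in table.columns:
        pct_column("unknown_pct", "unknown_tags", "clean_tags")
    return table


def summary_from_mappings(
    mappings: Mapping[str, MappingResult],
    db: ReferenceTagDB | None = None,
) -> pd.DataFrame:
    rows = [
        {
            "library": label,
            "clean_tags": m.clean_tag_total,
            "unambiguous_tags": m.unambiguous_tag_total,
            "unambiguous_genes": m.unambiguous_gene_count,
            "unknown_tags": m.unknown_tag_total,
        }
        for label, m in mappings.items()
    ]
    total = db.gene_count if db is not None else None
    return summary_table(rows, reference_gene_total=total)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    fasta: str | Path
    tag_paths: Mapping[str, str | Path]          # stage label -> raw tag TSV
    stages: Sequence[str] | None = None          # order; default: tag_paths order
    design: StageDesign | None = None
    ct_path: str | Path | None = None
    ct_baseline: str | None = None
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    adaptor_prefixes: tuple[str, ...] = ()
    multiread_cap: int = MULTIREAD_CAP
    cluster_k: int | str = 5
    seed: int = 0
    outdir: str | Path = "tagdge_out"

    def __post_init__(self):
        if self.stages is None:
            self.stages = tuple(self.tag_paths)
        missing = [s for s in self.stages if s not in self.tag_paths]
        if missing:
            raise ValueError(f"no tag file for stage(s): {missing}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class PipelineResult:
    db: ReferenceTagDB
    clean: dict[str, TagLibrary]
    mappings: dict[str, MappingResult]
    matrix: ExpressionMatrix
    de_results: dict
    histogram: pd.DataFrame
    venn: pd.DataFrame
    clusters: object
    summary: pd.DataFrame
    correlation: pd.DataFrame | None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """refdb -> preprocess -> tagmap -> quantify -> detest -> trajectory
    -> crossval (optional), writing all outputs plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "refdb"
    try:
        db = build_db(config.fasta)
        db.to_tsv(outdir / "refdb.tsv")

        stage = "preprocess"
        clean: dict[str, TagLibrary] = {}
        for label in config.stages:
            raw = TagLibrary.from_tsv(config.tag_paths[label], label=label)
            clean[label] = filter_raw_tags(raw, config.adaptor_prefixes)
        write_filter_log(clean, outdir / "filter_log.jsonl")

        stage = "tagmap"
        mappings = {label: map_library(lib, db) for label, lib in clean.items()}
        summary = summary_from_mappings(mappings, db)
        summary.to_csv(outdir / "mapping_summary.tsv", sep="\t",
                       lineterminator="\n")

        stage = "quantify"
        matrix = ExpressionMatrix.from_mappings(
            mappings, genes=db.gene_ids, cap=config.multiread_cap
        )
        matrix.to_tsv(outdir / "expression_matrix.tsv")

        stage = "detest"
        design = config.design or _design_for(config.stages)
        de_results = call_all(matrix, design.comparisons, config.thresholds)
        for (a, b), table in de_results.items():
            table.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t",
                         float_format="%.6g", lineterminator="\n")

        stage = "trajectory"
        histogram = updown_histogram(de_results, design)
        histogram.to_csv(outdir / "updown_histogram.tsv", sep="\t",
                         lineterminator="\n")
        venn = process_venn(de_results, design)
        venn.to_csv(outdir / "process_venn.tsv", sep="\t", lineterminator="\n")
        de_genes = sorted(
            set().union(*(set(t.index[t["is_de"]]) for t in de_results.values()))
        )
        clusters = None
        if len(de_genes) >= 6:
            clusters = cluster_profiles(
                matrix.tpm, genes=de_genes, k=config.cluster_k, seed=config.seed
            )
            clusters.assignments.to_csv(outdir / "clusters.tsv", sep="\t",
                                        lineterminator="\n")
            clusters.centroids.to_csv(outdir / "centroids.tsv", sep="\t",
                                      float_format="%.6g", lineterminator="\n")
            if clusters.fom is not None:
                clusters.fom.rename_axis("k").to_csv(
                    outdir / "fom.tsv", sep="\t", lineterminator="\n"
                )

        stage = "crossval"
        correlation = None
        if config.ct_path is not None:
            ct = crossval_mod.read_ct_table(config.ct_path)
            baseline = config.ct_baseline or config.stages[0]
            qpcr = crossval_mod.relative_expression(ct, baseline)
            rnaseq = crossval_mod.rnaseq_log2_ratio(matrix, baseline)
            overall = crossval_mod.platform_correlation(
                rnaseq.loc[rnaseq.index.intersection(qpcr.index)],
                np.log2(qpcr), grouping="overall",
            )
            per_stage = crossval_mod.platform_correlation(
                rnaseq.loc[rnaseq.index.intersection(qpcr.index)],
                np.log2(qpcr), grouping="per-stage",
            )
            correlation = pd.concat([overall, per_stage], ignore_index=True)
            correlation.to_csv(outdir / "platform_correlation.tsv", sep="\t",
                               float_format="%.6g", index=False,
                               lineterminator="\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    inputs = {str(config.fasta): _sha256(Path(config.fasta))}
    for label in config.stages:
        path = Path(config.tag_paths[label])
        inputs[str(path)] = _sha256(path)
    if config.ct_path is not None:
        inputs[str(config.ct_path)] = _sha256(Path(config.ct_path))
    outputs = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "tagdge",
        "version": _version(),
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "multiread_cap": config.multiread_cap,
        "stages": list(config.stages),
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        db=db, clean=clean, mappings=mappings, matrix=matrix,
        de_results=de_results, histogram=histogram, venn=venn,
        clusters=clusters, summary=summary, correlation=correlation,
    )


def _design_for(stages: Sequence[str]) -> StageDesign:
    default = default_design()
    if tuple(stages) == default.stages:
        return default
    # unlabeled designs: one window covering every consecutive comparison
    stages = tuple(stages)
    return StageDesign(stages=stages, windows={"all": tuple(zip(stages[:-1],
                                                                stages[1:]))})


def _version() -> str:
    from . import __version__

    return __version__
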