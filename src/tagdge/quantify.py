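"""Gene-level expression: counts, multi-read distribution, TPM, saturation.

Expression of a gene in a library is the number of tags unambiguously
assigned to it. Tags matching 2..20 genes are then distributed across
their candidate genes in proportion to each gene's unambiguous count
(one proportional pass; equal split when no candidate has unique
evidence); tags matching more than 20 genes are discarded but counted.
TPM normalizes to tags per million *clean* tags of the library — note
this denominator includes unknown tags, so TPMs of two libraries remain
comparable even when their mappable fractions differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import TagLibrary
from .refdb import ReferenceTagDB
from .tagmap import AMBIGUOUS, UNAMBIGUOUS, MappingResult

MULTIREAD_CAP = 20
TPM_SCALE = 1_000_000


def gene_counts(mapping: MappingResult) -> pd.Series:
    """Unambiguous tag count per gene (count-weighted over tags)."""
    totals: dict[str, int] = {}
    for tag, assignment in mapping.assignments.items():
        if assignment.status == UNAMBIGUOUS:
            (gene,) = assignment.genes
            totals[gene] = totals.get(gene, 0) + mapping.counts[tag]
    return pd.Series(totals, dtype=float).sort_index()


def distribute_multireads(
    mapping: MappingResult,
    counts: pd.Series,
    cap: int = MULTIREAD_CAP,
) -> tuple[pd.Series, float]:
    """Allocate ambiguous tags proportionally to unambiguous evidence.

    Returns (distributed counts per gene, discarded mass from tags whose
    gene set exceeds ``cap``). Mass is conserved:
    distributed.sum() + discarded == unambiguous_total + ambiguous_total.
    """
    distributed = counts.astype(float).copy()
    discarded = 0.0
    extra: dict[str, float] = {}
    for tag, assignment in mapping.assignments.items():
        if assignment.status != AMBIGUOUS:
            continue
        genes = sorted(assignment.genes)
        if len(genes) > cap:
            discarded += mapping.counts[tag]
            continue
        weights = np.array([counts.get(g, 0.0) for g in genes], dtype=float)
        if weights.sum() == 0:
            weights = np.ones(len(genes))
        shares = mapping.counts[tag] * weights / weights.sum()
        for gene, share in zip(genes, shares):
            extra[gene] = extra.get(gene, 0.0) + share
    if extra:
        extra_s = pd.Series(extra)
        distributed = distributed.add(extra_s, fill_value=0.0)
    return distributed.sort_index(), discarded


def tpm(distributed: pd.Series, clean_tag_total: int) -> pd.Series:
    """Tags per million clean tags."""
    if clean_tag_total <= 0:
        raise ValueError("clean_tag_total must be positive")
    return distributed / clean_tag_total * TPM_SCALE


@dataclass
class ExpressionMatrix:
    """Gene x stage expression with raw, distributed and TPM layers."""

    counts: pd.DataFrame        # raw unambiguous counts
    distributed: pd.DataFrame   # after multi-read allocation (fractional)
    tpm: pd.DataFrame
    clean_totals: pd.Series     # per-stage clean tag totals
    discarded: pd.Series        # per-stage mass lost to >cap multireads

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @classmethod
    def from_mappings(
        cls,
        mappings: Mapping[str, MappingResult],
        clean_totals: Mapping[str, int] | None = None,
        genes: Sequence[str] | None = None,
        cap: int = MULTIREAD_CAP,
    ) -> "ExpressionMatrix":
        """Quantify every stage; ``clean_totals`` defaults to the mapped
        libraries' clean totals (identical when nothing was discarded
        upstream of mapping)."""
        stage_counts: dict[str, pd.Series] = {}
        stage_distributed: dict[str, pd.Series] = {}
        discarded: dict[str, float] = {}
        totals: dict[str, int] = {}
        for stage, mapping in mappings.items():
            raw = gene_counts(mapping)
            dist, lost = distribute_multireads(mapping, raw, cap=cap)
            stage_counts[stage] = raw
            stage_distributed[stage] = dist
            discarded[stage] = lost
            totals[stage] = (
                clean_totals[stage] if clean_totals is not None
                else mapping.clean_tag_total
            )
        index = pd.Index(genes) if genes is not None else None
        counts_df = pd.DataFrame(stage_counts).fillna(0.0)
        dist_df = pd.DataFrame(stage_distributed).fillna(0.0)
        if index is not None:
            counts_df = counts_df.reindex(index, fill_value=0.0)
            dist_df = dist_df.reindex(index, fill_value=0.0)
        counts_df = counts_df.sort_index()
        dist_df = dist_df.sort_index()
        totals_s = pd.Series(totals)[counts_df.columns]
        tpm_df = dist_df.div(totals_s, axis=1) * TPM_SCALE
        return cls(
            counts=counts_df,
            distributed=dist_df,
            tpm=tpm_df,
            clean_totals=totals_s,
            discarded=pd.Series(discarded)[counts_df.columns],
        )

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            {"count": self.counts, "distributed": self.distributed, "tpm": self.tpm},
            axis=1,
        )
        out.columns = [f"{stage}_{layer}" for layer, stage in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def saturation_curve(
    lib: TagLibrary,
    db: ReferenceTagDB,
    fractions: Sequence[float],
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes detected (>=1 unambiguous tag) vs sequencing effort.

    For each fraction of the library, tags are subsampled without
    replacement (prefixes of one shuffle per replicate, so detected
    counts are non-decreasing in the fraction within every replicate)
    and the number of genes with unambiguous evidence is counted.
    """
    from .tagmap import map_library  # local import to avoid cycle at module load

    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    mapping = map_library(lib, db)
    tags = sorted(lib.tags)
    gene_of = np.array(
        [
            next(iter(mapping.assignments[t].genes))
            if mapping.assignments[t].status == UNAMBIGUOUS
            else ""
            for t in tags
        ],
        dtype=object,
    )
    counts = np.array([lib.tags[t] for t in tags])
    pool = np.repeat(np.arange(len(tags)), counts)
    total = pool.size
    rng = np.random.default_rng(seed)
    fracs = sorted(fractions)
    detected = np.zeros((reps, len(fracs)))
    for r in range(reps):
        order = rng.permutation(pool)
        for j, f in enumerate(fracs):
            m = max(1, int(round(f * total)))
            prefix = order[:m]
            genes = {g for g in gene_of[np.unique(prefix)] if g}
            detected[r, j] = len(genes)
    return pd.DataFrame(
        {
            "fraction": fracs,
            "tags_sampled": [max(1, int(round(f * total))) for f in fracs],
            "genes_detected": detected.mean(axis=0),
        }
    )
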