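"""Synthetic tag-DGE data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a toy transcriptome in which a configurable fraction of genes carries a
usable NlaIII (CATG) site; stage-dependent true abundances built from
five archetype trajectories (plus flat genes) over the nine-stage
somatic-embryogenesis design; and per-stage tag libraries drawn
multinomially from the canonical (3'-most sense) tag of each taggable
gene, corrupted by per-base sequencing error and contaminated with
adaptor tags, N-containing tags, singleton error tags, and
off-reference tags that model transcripts absent from the reference.

Only canonical tags are sequenced, matching the wet protocol; the
reference database still indexes every site on both strands, which
deliberately creates realistic ambiguous/unknown structure. Genes
without a usable site emit no tags at all (their abundance is
renormalized away), so the unknown-tag fraction is controlled purely by
``offref_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import TagLibrary
from .refdb import ANCHOR, TAG_LENGTH, ReferenceTagDB, build_db
from .trajectory import DEFAULT_STAGES

_BASES = np.array(list("ACGT"))

DEFAULT_ADAPTOR_PREFIX = "TCGGACTGT"

# Archetype trajectories in log2 units on a unit pseudo-time grid; they are
# interpolated to the configured stage count and scaled by de_log2fc / 2.
# Shapes: I up throughout; II down throughout; III up during
# dedifferentiation then down; IV down/low during dedifferentiation then up;
# V complex (peaks at 48h and EC, dip at NEC) with half of its genes flipped
# in sign, giving the two opposed sub-clusters.
ARCHETYPE_TEMPLATES: dict[str, np.ndarray] = {
    "flat": np.zeros(9),
    "I": np.linspace(0.0, 6.0, 9),
    "II": np.linspace(0.0, -6.0, 9),
    "III": np.array([0.0, 1.5, 3.0, 4.0, 4.0, 2.0, 0.5, -1.0, -2.0]),
    "IV": np.array([0.0, -1.5, -3.0, -4.0, -4.0, -2.0, -0.5, 1.0, 2.0]),
    "V": np.array([0.0, 1.5, 3.0, 4.5, 0.5, 4.0, 1.5, 0.5, -0.5]),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (300, 2000)
    stages: tuple[str, ...] = DEFAULT_STAGES
    library_depth: int = 300_000
    base_error_rate: float = 0.005
    adaptor_fraction: float = 0.01
    n_fraction: float = 0.01
    singleton_fraction: float = 0.02
    offref_fraction: float = 0.5
    taggable_fraction: float = 0.94
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "flat": 0.5, "I": 0.1, "II": 0.1, "III": 0.1, "IV": 0.1, "V": 0.1,
        }
    )
    de_log2fc: float = 2.0
    abundance_log2_sd: float = 4.0
    template_jitter_sd: float = 0.3
    adaptor_prefix: str = DEFAULT_ADAPTOR_PREFIX
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.library_depth < 1:
            raise ValueError("library_depth must be >= 1")
        if not self.stages:
            raise ValueError("at least one stage is required")
        for name in ("base_error_rate", "adaptor_fraction", "n_fraction",
                     "singleton_fraction", "offref_fraction", "taggable_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        mix = dict(self.archetype_mix)
        unknown = set(mix) - set(ARCHETYPE_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype_mix proportions must sum to 1")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _scrub_anchor(seq: str, rng: np.random.Generator) -> str:
    """Remove every CATG occurrence (palindromic, so this covers both
    strands) by mutating one base of each occurrence."""
    chars = list(seq)
    while True:
        pos = "".join(chars).find(ANCHOR)
        if pos == -1:
            return "".join(chars)
        alternatives = [b for b in "ACGT" if b != chars[pos + 1]]
        chars[pos + 1] = alternatives[rng.integers(0, 3)]


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], dict[str, str | None]]:
    """Random transcriptome; returns (records, canonical tag per gene).

    A fraction ``taggable_fraction`` of genes is guaranteed a full-length
    sense-strand CATG+17 site; the remainder carries no CATG at all.
    Reproducible bit-for-bit for a given seed.
    """
    rng = _rng(config, 1)
    lo, hi = config.gene_length_range
    if lo < TAG_LENGTH:
        raise ValueError(f"minimum gene length must be >= {TAG_LENGTH}")
    records: list[tuple[str, str]] = []
    canonical: dict[str, str | None] = {}
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if rng.random() < config.taggable_fraction:
            if not _has_full_site(seq):
                pos = int(rng.integers(0, length - TAG_LENGTH + 1))
                seq = seq[:pos] + ANCHOR + seq[pos + 4 :]
            canonical[gene_id] = _canonical_site(seq)
        else:
            seq = _scrub_anchor(seq, rng)
            canonical[gene_id] = None
        records.append((gene_id, seq))
    return records, canonical


def _has_full_site(seq: str) -> bool:
    pos = seq.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LENGTH <= len(seq):
            return True
        pos = seq.find(ANCHOR, pos + 1)
    return False


def _canonical_site(seq: str) -> str | None:
    """3'-most full-length sense-strand window."""
    best = None
    pos = seq.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LENGTH <= len(seq):
            best = seq[pos : pos + TAG_LENGTH]
        pos = seq.find(ANCHOR, pos + 1)
    return best


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Per-gene archetype and per-stage true relative abundance
    (each stage column sums to 1)."""

    archetype: pd.Series
    abundance: pd.DataFrame

    def log2_ratio(self, stage_a: str, stage_b: str) -> pd.Series:
        return np.log2(self.abundance[stage_b] / self.abundance[stage_a])

    def de_flags(self, comparisons, threshold: float = 1.0) -> pd.DataFrame:
        flags = {
            f"{a}->{b}": self.log2_ratio(a, b).abs() >= threshold
            for a, b in comparisons
        }
        return pd.DataFrame(flags)

    def to_tsv(self, path: str | Path) -> None:
        out = self.abundance.copy()
        out.insert(0, "archetype", self.archetype)
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.8g", lineterminator="\n")


def _stage_templates(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Templates interpolated to the configured stage count and scaled by
    de_log2fc (the stated shapes correspond to de_log2fc = 2)."""
    n = len(config.stages)
    grid = np.linspace(0.0, 1.0, n)
    base_grid = np.linspace(0.0, 1.0, 9)
    scale = config.de_log2fc / 2.0
    return {
        name: np.interp(grid, base_grid, template) * scale
        for name, template in ARCHETYPE_TEMPLATES.items()
    }


def simulate_truth(
    config: SimulationConfig, gene_ids: Sequence[str]
) -> SyntheticTruth:
    """Archetype assignment and true relative abundances for every gene."""
    rng = _rng(config, 2)
    genes = list(gene_ids)
    labels = sorted(config.archetype_mix)
    probs = np.array([config.archetype_mix[l] for l in labels])
    archetype = rng.choice(labels, size=len(genes), p=probs)
    templates = _stage_templates(config)
    base = rng.normal(0.0, config.abundance_log2_sd, size=len(genes))
    jitter = rng.normal(0.0, config.template_jitter_sd,
                        size=(len(genes), len(config.stages)))
    log2_levels = np.empty((len(genes), len(config.stages)))
    for i, label in enumerate(archetype):
        shape = templates[label]
        if label == "V" and rng.random() < 0.5:
            shape = -shape
        log2_levels[i] = base[i] + shape + jitter[i]
    levels = np.power(2.0, log2_levels)
    abundance = levels / levels.sum(axis=0, keepdims=True)
    return SyntheticTruth(
        archetype=pd.Series(archetype, index=genes, name="archetype"),
        abundance=pd.DataFrame(abundance, index=genes,
                               columns=list(config.stages)),
    )


# ---------------------------------------------------------------------------
# Library emission
# ---------------------------------------------------------------------------

def _mutate(tag: str, rng: np.random.Generator, n_errors: int) -> str:
    positions = rng.choice(TAG_LENGTH, size=n_errors, replace=False)
    chars = list(tag)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _apply_errors(
    tags: dict[str, int], error_rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Corrupt each emitted copy independently at ``error_rate`` per base."""
    if error_rate == 0:
        return tags
    p_any = 1.0 - (1.0 - error_rate) ** TAG_LENGTH
    # copies with >= 1 error get an error count from the truncated binomial
    m_values = np.arange(1, 5)
    from scipy.stats import binom as _binom

    pm = _binom.pmf(m_values, TAG_LENGTH, error_rate)
    pm = pm / pm.sum()
    out: dict[str, int] = {}
    for tag, count in tags.items():
        k = rng.binomial(count, p_any)
        if count - k > 0:
            out[tag] = out.get(tag, 0) + (count - k)
        if k:
            for m in rng.choice(m_values, size=k, p=pm):
                mutated = _mutate(tag, rng, int(m))
                out[mutated] = out.get(mutated, 0) + 1
    return out


def _is_mappable(tag: str, db: ReferenceTagDB) -> bool:
    from .tagmap import hamming1_neighbors

    if tag in db:
        return True
    return any(neighbor in db for neighbor in hamming1_neighbors(tag))


def _chunk_counts(total: int, chunk: int, rng: np.random.Generator) -> np.ndarray:
    if total == 0:
        return np.array([], dtype=int)
    n_species = max(1, int(round(total / chunk)))
    return rng.multinomial(total, np.full(n_species, 1.0 / n_species))


def simulate_libraries(
    reference: ReferenceTagDB | str | Path,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> dict[str, TagLibrary]:
    """One raw tag library per stage.

    ``library_depth`` is the clean-tag target: the multinomial signal
    draw plus off-reference tags sum to it, while adaptor, N and
    singleton contamination ride on top and are later removed by the
    clean-tag filter (error-derived singletons also shave a little).
    """
    db = reference if isinstance(reference, ReferenceTagDB) else build_db(reference)
    canonical = {g: db.canonical_tag(g) for g in truth.abundance.index}
    taggable = [g for g in truth.abundance.index if canonical[g] is not None]
    if not taggable:
        raise ValueError("no taggable genes to draw tags from")
    libraries: dict[str, TagLibrary] = {}
    for stage_idx, stage in enumerate(config.stages):
        if stage not in truth.abundance.columns:
            raise ValueError(f"stage label {stage!r} missing from truth")
        rng = _rng(config, 3, stage_idx)
        weights = truth.abundance.loc[taggable, stage].to_numpy()
        weights = weights / weights.sum()
        depth = config.library_depth
        n_offref = rng.binomial(depth, config.offref_fraction)
        signal = rng.multinomial(depth - n_offref, weights)
        tags: dict[str, int] = {}
        for gene, count in zip(taggable, signal):
            if count:
                tag = canonical[gene]
                tags[tag] = tags.get(tag, 0) + int(count)
        tags = _apply_errors(tags, config.base_error_rate, rng)
        # off-reference tags: CATG-anchored species unmappable even at
        # one mismatch, ~20 copies each
        for count in _chunk_counts(n_offref, 20, rng):
            if count == 0:
                continue
            while True:
                tag = ANCHOR + _random_seq(rng, TAG_LENGTH - 4)
                if not _is_mappable(tag, db):
                    break
            tags[tag] = tags.get(tag, 0) + int(count)
        # adaptor contamination, ~10 copies per species
        n_adaptor = rng.binomial(depth, config.adaptor_fraction)
        fill = TAG_LENGTH - len(config.adaptor_prefix)
        for count in _chunk_counts(n_adaptor, 10, rng):
            if count == 0:
                continue
            tag = config.adaptor_prefix + _random_seq(rng, fill)
            tags[tag] = tags.get(tag, 0) + int(count)
        # N-containing tags, ~5 copies per species
        n_with_n = rng.binomial(depth, config.n_fraction)
        for count in _chunk_counts(n_with_n, 5, rng):
            if count == 0:
                continue
            tag = list(_random_seq(rng, TAG_LENGTH))
            tag[rng.integers(0, TAG_LENGTH)] = "N"
            tag = "".join(tag)
            tags[tag] = tags.get(tag, 0) + int(count)
        # singleton error tags: distinct random species with count 1
        n_singleton = rng.binomial(depth, config.singleton_fraction)
        added = 0
        while added < n_singleton:
            tag = _random_seq(rng, TAG_LENGTH)
            if tag not in tags:
                tags[tag] = 1
                added += 1
        libraries[stage] = TagLibrary(label=stage, tags=tags)
    return libraries


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[list[tuple[str, str]], SyntheticTruth, dict[str, TagLibrary],
           ReferenceTagDB]:
    """Full synthetic dataset: transcriptome, truth, raw libraries, tag DB.

    When ``outdir`` is given, writes transcriptome.fasta, truth.tsv, one
    tags_<stage>.tsv per stage, and config.txt (flat key=value echo).
    """
    records, _ = simulate_transcriptome(config)
    db = ReferenceTagDB.from_records(records)
    truth = simulate_truth(config, [g for g, _ in records])
    libraries = simulate_libraries(db, truth, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "transcriptome.fasta")
        truth.to_tsv(outdir / "truth.tsv")
        for stage, lib in libraries.items():
            lib.to_tsv(outdir / f"tags_{stage}.tsv")
        with open(outdir / "config.txt", "w") as fh:
            for key, value in sorted(vars(config).items()):
                if isinstance(value, Mapping):
                    value = ",".join(f"{k}:{v}" for k, v in sorted(value.items()))
                elif isinstance(value, tuple):
                    value = ",".join(map(str, value))
                fh.write(f"{key}={value}\n")
    return records, truth, libraries, db
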