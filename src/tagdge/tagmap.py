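"""Tag-to-gene mapping with at most one mismatch.

A clean tag is looked up in the reference tag database first verbatim;
only if no exact site exists are its 63 Hamming-distance-1 neighbours
consulted (exact hits take precedence, the standard practice for tag
DGE, which avoids inflating ambiguity). The matched *gene set* decides
the status: one gene -> unambiguous, several -> ambiguous, none ->
unknown. Multiple sites inside one gene (either strand) still count as
one gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .preprocess import TagLibrary
from .refdb import ReferenceTagDB, TAG_LENGTH, VALID_BASES

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"

_BASES = "ACGT"


def hamming1_neighbors(tag: str) -> Iterator[str]:
    """The 3*len(tag) sequences at Hamming distance exactly 1."""
    for i, base in enumerate(tag):
        for alt in _BASES:
            if alt != base:
                yield tag[:i] + alt + tag[i + 1 :]


@dataclass(frozen=True)
class TagAssignment:
    status: str
    genes: frozenset[str]
    distance: int | None  # 0 or 1 for mapped tags, None for unknown


def map_tag(tag: str, db: ReferenceTagDB) -> TagAssignment:
    """Classify one clean tag against the reference DB."""
    if len(tag) != TAG_LENGTH or not set(tag) <= VALID_BASES:
        raise ValueError(f"not a clean tag: {tag!r}")
    exact = db.genes_for(tag)
    if exact:
        status = UNAMBIGUOUS if len(exact) == 1 else AMBIGUOUS
        return TagAssignment(status, exact, 0)
    genes: set[str] = set()
    for neighbor in hamming1_neighbors(tag):
        genes |= db.genes_for(neighbor)
    if genes:
        status = UNAMBIGUOUS if len(genes) == 1 else AMBIGUOUS
        return TagAssignment(status, frozenset(genes), 1)
    return TagAssignment(UNKNOWN, frozenset(), None)


@dataclass
class MappingResult:
    """Per-library classification of every distinct clean tag."""

    label: str
    assignments: dict[str, TagAssignment] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def _total(self, status: str) -> int:
        return sum(
            self.counts[t] for t, a in self.assignments.items() if a.status == status
        )

    def _distinct(self, status: str) -> int:
        return sum(1 for a in self.assignments.values() if a.status == status)

    @property
    def clean_tag_total(self) -> int:
        return sum(self.counts.values())

    @property
    def unambiguous_tag_total(self) -> int:
        return self._total(UNAMBIGUOUS)

    @property
    def ambiguous_tag_total(self) -> int:
        return self._total(AMBIGUOUS)

    @property
    def unknown_tag_total(self) -> int:
        return self._total(UNKNOWN)

    @property
    def distinct_unambiguous(self) -> int:
        return self._distinct(UNAMBIGUOUS)

    @property
    def distinct_ambiguous(self) -> int:
        return self._distinct(AMBIGUOUS)

    @property
    def distinct_unknown(self) -> int:
        return self._distinct(UNKNOWN)

    @property
    def unambiguous_genes(self) -> frozenset[str]:
        genes: set[str] = set()
        for tag, a in self.assignments.items():
            if a.status == UNAMBIGUOUS:
                genes |= a.genes
        return frozenset(genes)

    @property
    def unambiguous_gene_count(self) -> int:
        return len(self.unambiguous_genes)


def map_library(lib: TagLibrary, db: ReferenceTagDB) -> MappingResult:
    """Map every distinct tag of a clean library; deterministic."""
    result = MappingResult(label=lib.label)
    for tag in sorted(lib.tags):
        result.assignments[tag] = map_tag(tag, db)
        result.counts[tag] = lib.tags[tag]
    return result
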