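"""Virtual reference tag database for tag-based digital gene expression.

In an NlaIII/MmeI tag library, each transcript is represented by a 21-bp
signature: the 4-bp NlaIII recognition site (CATG) followed by the next
17 bp of cDNA. Mapping observed tags back to genes requires a database of
every such signature a reference transcriptome can produce. Because the
orientation of EST-derived unigenes is not guaranteed, tags are indexed on
both the sense sequence and its reverse complement.

The 3'-most sense-strand site is flagged *canonical*: it is the site the
wet protocol actually captures (NlaIII digestion retains the 3'-most
fragment bound to oligo-dT beads). The canonical flag is metadata for the
simulator; mapping uses every indexed site.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import reverse_complement

ANCHOR = "CATG"
ANCHOR_LEN = len(ANCHOR)
TAG_LENGTH = 21
VALID_BASES = frozenset("ACGT")

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class ReferenceTag:
    """One virtual 21-bp tag a gene can produce.

    ``offset`` is the 0-based position of the CATG start on the *sense*
    sequence for both strands (the NlaIII site is palindromic, so an
    antisense site always lines up with a sense-coordinate CATG).
    """

    sequence: str
    gene_id: str
    strand: str
    offset: int
    is_canonical: bool


def _windows(seq: str) -> Iterator[tuple[int, str]]:
    """Yield (start, 21-bp window) for every full-length CATG-anchored window.

    Windows containing characters outside {A,C,G,T} are skipped: they could
    never be observed as a clean tag.
    """
    start = seq.find(ANCHOR)
    while start != -1:
        window = seq[start : start + TAG_LENGTH]
        if len(window) == TAG_LENGTH and set(window) <= VALID_BASES:
            yield start, window
        start = seq.find(ANCHOR, start + 1)


def extract_reference_tags(gene_id: str, sequence: str) -> list[ReferenceTag]:
    """Extract every virtual tag of a gene, sense sites first (5'->3'),
    then antisense sites, deterministically ordered.

    The 3'-most full-length sense-strand site is flagged canonical. A gene
    with no full-length site on either strand returns an empty list.
    """
    seq = str(sequence).upper()
    if not seq:
        return []
    sense_sites = list(_windows(seq))
    canonical_offset = sense_sites[-1][0] if sense_sites else None
    tags = [
        ReferenceTag(window, gene_id, SENSE, start, start == canonical_offset)
        for start, window in sense_sites
    ]
    rc = reverse_complement(seq)
    n = len(seq)
    for start, window in _windows(rc):
        # CATG at rc position j pairs with the sense-coordinate CATG
        # starting at n - j - 4.
        tags.append(
            ReferenceTag(window, gene_id, ANTISENSE, n - start - ANCHOR_LEN, False)
        )
    return tags


class ReferenceTagDB:
    """Tag sequence -> reference sites index over a transcriptome."""

    def __init__(self, gene_ids: Iterable[str], tags: Iterable[ReferenceTag]):
        self.gene_ids: tuple[str, ...] = tuple(gene_ids)
        self._by_sequence: dict[str, tuple[ReferenceTag, ...]] = {}
        self._genes_by_sequence: dict[str, frozenset[str]] = {}
        self._canonical: dict[str, str] = {}
        self._all_tags: tuple[ReferenceTag, ...] = tuple(tags)
        taggable: set[str] = set()
        grouped: dict[str, list[ReferenceTag]] = {}
        for tag in self._all_tags:
            grouped.setdefault(tag.sequence, []).append(tag)
            taggable.add(tag.gene_id)
            if tag.is_canonical:
                self._canonical[tag.gene_id] = tag.sequence
        known = set(self.gene_ids)
        unknown = taggable - known
        if unknown:
            raise ValueError(f"tags reference unknown genes: {sorted(unknown)[:5]}")
        for seq, sites in grouped.items():
            self._by_sequence[seq] = tuple(sites)
            self._genes_by_sequence[seq] = frozenset(t.gene_id for t in sites)
        self._taggable = frozenset(taggable)

    # -- size accounting -------------------------------------------------
    @property
    def gene_count(self) -> int:
        return len(self.gene_ids)

    @property
    def taggable_gene_count(self) -> int:
        return len(self._taggable)

    @property
    def taggable_fraction(self) -> float:
        return self.taggable_gene_count / self.gene_count if self.gene_count else 0.0

    @property
    def taggable_genes(self) -> frozenset[str]:
        return self._taggable

    @property
    def untaggable_genes(self) -> frozenset[str]:
        return frozenset(self.gene_ids) - self._taggable

    @property
    def distinct_tag_count(self) -> int:
        return len(self._by_sequence)

    # -- lookup ----------------------------------------------------------
    def __contains__(self, sequence: str) -> bool:
        return sequence in self._by_sequence

    def sites(self, sequence: str) -> tuple[ReferenceTag, ...]:
        return self._by_sequence.get(sequence, ())

    def genes_for(self, sequence: str) -> frozenset[str]:
        return self._genes_by_sequence.get(sequence, frozenset())

    def canonical_tag(self, gene_id: str) -> str | None:
        """The sequenced (3'-most sense) tag of a gene, or None."""
        return self._canonical.get(gene_id)

    def iter_tags(self) -> Iterator[ReferenceTag]:
        return iter(self._all_tags)

    def iter_sequences(self) -> Iterator[str]:
        return iter(self._by_sequence)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "ReferenceTagDB":
        gene_ids: list[str] = []
        seen: set[str] = set()
        tags: list[ReferenceTag] = []
        for gene_id, seq in records:
            if gene_id in seen:
                raise ValueError(f"duplicate FASTA id: {gene_id!r}")
            seen.add(gene_id)
            gene_ids.append(gene_id)
            tags.extend(extract_reference_tags(gene_id, seq))
        if not gene_ids:
            raise ValueError("no records")
        return cls(gene_ids, tags)

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["tag", "gene_id", "strand", "offset", "canonical"])
            for tag in self._all_tags:
                writer.writerow(
                    [tag.sequence, tag.gene_id, tag.strand, tag.offset,
                     int(tag.is_canonical)]
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTagDB":
        tags: list[ReferenceTag] = []
        gene_ids: list[str] = []
        seen: set[str] = set()
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header != ["tag", "gene_id", "strand", "offset", "canonical"]:
                raise ValueError(f"unrecognized tag DB header: {header}")
            for row in reader:
                seq, gene_id, strand, offset, canonical = row
                tags.append(
                    ReferenceTag(seq, gene_id, strand, int(offset), bool(int(canonical)))
                )
                if gene_id not in seen:
                    seen.add(gene_id)
                    gene_ids.append(gene_id)
        # Genes with no tags are lost in TSV form; the TSV carries taggable
        # genes only, so counts reconstructed from it refer to those.
        return cls(gene_ids, tags)


def build_db(fasta_path: str | Path) -> ReferenceTagDB:
    """Build the virtual tag database from a multi-FASTA transcriptome."""
    records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta"))
    return ReferenceTagDB.from_records(records)
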