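"""Raw-tag cleaning.

A *clean tag* is a 21-bp sequence that (1) does not start with a known
adaptor prefix, (2) contains only A/C/G/T, and (3) occurs more than once
in its library (copy-number-1 tags are overwhelmingly sequencing errors).
Rules are applied in that fixed order so the removal counters are
unambiguous; singleton status is evaluated on the library after the
adaptor and N filters.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .refdb import TAG_LENGTH, VALID_BASES


@dataclass
class TagCounters:
    raw_tag_total: int = 0
    clean_tag_total: int = 0
    removed_adaptor: int = 0
    removed_N: int = 0
    removed_singleton: int = 0
    removed_malformed: int = 0

    def reconciles(self) -> bool:
        return self.raw_tag_total == (
            self.clean_tag_total
            + self.removed_adaptor
            + self.removed_N
            + self.removed_singleton
            + self.removed_malformed
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class TagLibrary:
    """One library: a tag -> count multiset plus accounting counters."""

    label: str
    tags: dict[str, int] = field(default_factory=dict)
    counters: TagCounters = field(default_factory=TagCounters)

    @property
    def total(self) -> int:
        return sum(self.tags.values())

    @property
    def distinct(self) -> int:
        return len(self.tags)

    # -- TSV I/O (tag<TAB>count) ----------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["tag", "count"])
            for tag in sorted(self.tags):
                writer.writerow([tag, self.tags[tag]])

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "TagLibrary":
        tags: dict[str, int] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header != ["tag", "count"]:
                raise ValueError(f"unrecognized tag library header: {header}")
            for tag, count in reader:
                count = int(count)
                if count <= 0:
                    raise ValueError(f"non-positive count for tag {tag!r}")
                tags[tag] = tags.get(tag, 0) + count
        return cls(label=label or Path(path).stem, tags=tags)


def filter_raw_tags(
    raw: TagLibrary, adaptor_prefixes: Sequence[str] = ()
) -> TagLibrary:
    """Apply the clean-tag definition: malformed-length, adaptor, N,
    then singleton removal. Returns a new library; the input is untouched.
    """
    counters = TagCounters(raw_tag_total=raw.total)
    survivors: dict[str, int] = {}
    for tag, count in raw.tags.items():
        if len(tag) != TAG_LENGTH:
            counters.removed_malformed += count
        elif any(tag.startswith(prefix) for prefix in adaptor_prefixes):
            counters.removed_adaptor += count
        elif not set(tag) <= VALID_BASES:
            counters.removed_N += count
        else:
            survivors[tag] = count
    clean = {tag: c for tag, c in survivors.items() if c > 1}
    counters.removed_singleton = sum(c for c in survivors.values() if c == 1)
    counters.clean_tag_total = sum(clean.values())
    assert counters.reconciles()
    return TagLibrary(label=raw.label, tags=clean, counters=counters)


def write_filter_log(libraries: Mapping[str, TagLibrary], path: str | Path) -> None:
    """One JSON-lines record per library with the full counter set."""
    with open(path, "w") as fh:
        for label, lib in libraries.items():
            record = {"library": label, **lib.counters.as_dict()}
            fh.write(json.dumps(record) + "\n")
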