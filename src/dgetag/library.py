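"""Tag library container: a multiset of fixed-length tag sequences.

A DGE library is a collection of short (typically 21 nt) sequence tags
with copy counts.  Libraries are read from tag-count TSV files
(columns ``tag``, ``count``) or from FASTQ, and written back to either
format.  FASTQ output uses a constant dummy quality string because copy
counts, not base qualities, are the unit of information in DGE.
"""

from __future__ import annotations

import os
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO


@dataclass
class TagLibrary:
    """Multiset of same-length tags with copy counts for one strain."""

    counts: dict[str, int] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.counts}
        if len(lengths) > 1:
            raise ValueError(f"tags have mixed lengths: {sorted(lengths)}")
        bad = [t for t, c in self.counts.items() if c <= 0]
        if bad:
            raise ValueError(f"non-positive copy counts for {len(bad)} tags")

    # -- basic accounting ------------------------------------------------
    @property
    def tag_length(self) -> int | None:
        """Common tag length, or None for an empty library."""
        for tag in self.counts:
            return len(tag)
        return None

    @property
    def distinct(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, tag: str) -> int:
        return self.counts[tag]

    def __contains__(self, tag: str) -> bool:
        return tag in self.counts

    def items(self) -> Iterable[tuple[str, int]]:
        return self.counts.items()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_tags(cls, tags: Iterable[str], name: str = "") -> "TagLibrary":
        """Build a library from an iterable of (repeated) tag sequences."""
        return cls(dict(Counter(tags)), name=name)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], name: str = "") -> "TagLibrary":
        return cls(dict(counts), name=name)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, name: str = "") -> "TagLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": "int64"})
        if not {"tag", "count"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'tag' and 'count'")
        return cls(dict(zip(df["tag"], df["count"])), name=name or os.path.basename(str(path)))

    @classmethod
    def from_fastq(cls, path: str | os.PathLike, name: str = "") -> "TagLibrary":
        tags = (str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq"))
        return cls.from_tags(tags, name=name or os.path.basename(str(path)))

    # -- output ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"tag": list(self.counts), "count": list(self.counts.values())}
        )
        return df.sort_values(["count", "tag"], ascending=[False, True], ignore_index=True)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_fastq(self, path: str | os.PathLike) -> None:
        """Expand counts into one FASTQ record per copy (dummy qualities)."""
        with open(path, "w") as fh:
            i = 0
            for tag, count in sorted(self.counts.items()):
                qual = "I" * len(tag)
                for _ in range(count):
                    fh.write(f"@tag_{i}\n{tag}\n+\n{qual}\n")
                    i += 1
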