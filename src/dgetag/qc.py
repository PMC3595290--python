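"""Raw-tag QC: filtering and the library accounting ledger.

Raw DGE tags are cleaned in three ordered steps — (1) tags containing
any N, (2) tags matching an adaptor sequence, (3) tags whose remaining
copy number is exactly 1 — and every removal class is recorded so the
ledger reproduces the arithmetic identities of a standard DGE library
characteristics table:

    clean_total    = raw_total    - N_total    - adaptor_total - singleton_total
    clean_distinct = raw_distinct - N_distinct - adaptor_distinct - singleton_distinct

The singleton step runs after the first two removals, so a copy-1 tag
containing an N is attributed to the N class, matching the row order of
the ledger.  Copy-number-threshold rows (>=2, >5, >10, >20, >50, >100)
summarise the clean library's count distribution.
"""

from __future__ import annotations

import json
import os
from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd

from dgetag.library import TagLibrary

DEFAULT_THRESHOLDS: tuple[int, ...] = (2, 5, 10, 20, 50, 100)


def _threshold_label(i: int, t: int) -> str:
    # first row is inclusive (>=2 == all clean tags), the rest strict
    return f"CopyNum >= {t}" if i == 0 else f"CopyNum > {t}"


@dataclass
class QCAccounting:
    """Per-library removal ledger plus copy-number-threshold rows."""

    raw_distinct: int = 0
    raw_total: int = 0
    n_containing_distinct: int = 0
    n_containing_total: int = 0
    adaptor_distinct: int = 0
    adaptor_total: int = 0
    singleton_distinct: int = 0
    singleton_total: int = 0
    clean_distinct: int = 0
    clean_total: int = 0
    threshold_rows: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        """Raise if the conservation identities do not hold."""
        if self.singleton_distinct != self.singleton_total:
            raise AssertionError("copy-1 tags must have distinct == total")
        if self.clean_total != (
            self.raw_total - self.n_containing_total - self.adaptor_total - self.singleton_total
        ):
            raise AssertionError("clean_total does not balance the ledger")
        if self.clean_distinct != (
            self.raw_distinct
            - self.n_containing_distinct
            - self.adaptor_distinct
            - self.singleton_distinct
        ):
            raise AssertionError("clean_distinct does not balance the ledger")
        prev = None
        for _, d, t in self.threshold_rows:
            if prev is not None and (d > prev[0] or t > prev[1]):
                raise AssertionError("threshold rows must be nonincreasing")
            prev = (d, t)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Raw Data", self.raw_distinct, self.raw_total),
            ("Tags Containing N", self.n_containing_distinct, self.n_containing_total),
            ("Adaptors", self.adaptor_distinct, self.adaptor_total),
            ("Tag CopyNum = 1", self.singleton_distinct, self.singleton_total),
            ("Clean Tag", self.clean_distinct, self.clean_total),
            *self.threshold_rows,
        ]
        return pd.DataFrame(rows, columns=["row", "distinct", "total"])

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {row: {"distinct": int(d), "total": int(t)}
                   for row, d, t in self.to_frame().itertuples(index=False)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


_MIN_ADAPTOR_PREFIX = 8  # shortest shared leading stretch counted as contamination


def _matches_adaptor(tag: str, adaptors: Sequence[str], prefix: bool) -> bool:
    if prefix:
        return any(
            len(os.path.commonprefix([tag, a])) >= min(_MIN_ADAPTOR_PREFIX, len(a))
            for a in adaptors
        )
    return tag in adaptors


def filter_tags(
    raw: TagLibrary,
    adaptor_sequences: Sequence[str] = (),
    *,
    prefix_match: bool = False,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> tuple[TagLibrary, QCAccounting]:
    """Remove N-containing, adaptor, and copy-number-1 tags, with ledger.

    Adaptor matching is exact full-tag equality by default; set
    ``prefix_match`` to also drop tags sharing a prefix with an adaptor.
    Returns the clean library and the fully populated accounting.
    """
    adaptors = tuple(a.upper() for a in adaptor_sequences)
    acc = QCAccounting(raw_distinct=raw.distinct, raw_total=raw.total)

    survivors: dict[str, int] = {}
    for tag, count in raw.items():
        if "N" in tag:
            acc.n_containing_distinct += 1
            acc.n_containing_total += count
        elif adaptors and _matches_adaptor(tag, adaptors, prefix_match):
            acc.adaptor_distinct += 1
            acc.adaptor_total += count
        elif count == 1:
            acc.singleton_distinct += 1
            acc.singleton_total += 1
        else:
            survivors[tag] = count

    clean = TagLibrary(survivors, name=raw.name)
    acc.clean_distinct = clean.distinct
    acc.clean_total = clean.total
    acc.threshold_rows = threshold_table(clean, thresholds)
    acc.validate()
    return clean, acc


def threshold_table(
    clean: TagLibrary, thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> list[tuple[str, int, int]]:
    """Copy-number-threshold rows (distinct tags, summed copies).

    The first threshold is inclusive (copy number >= t); subsequent ones
    are strict (> t), matching the conventional ledger labels.
    """
    rows = []
    for i, t in enumerate(thresholds):
        if i == 0:
            kept = [c for c in clean.counts.values() if c >= t]
        else:
            kept = [c for c in clean.counts.values() if c > t]
        rows.append((_threshold_label(i, t), len(kept), sum(kept)))
    return rows


def ledger_from_components(
    raw_distinct: int,
    raw_total: int,
    n_containing_distinct: int,
    n_containing_total: int,
    adaptor_distinct: int,
    adaptor_total: int,
    singletons: int,
) -> QCAccounting:
    """Complete a ledger from its printed removal classes by arithmetic.

    Useful for checking a published characteristics table: the clean
    counts are derived purely from the conservation identities.
    """
    acc = QCAccounting(
        raw_distinct=raw_distinct,
        raw_total=raw_total,
        n_containing_distinct=n_containing_distinct,
        n_containing_total=n_containing_total,
        adaptor_distinct=adaptor_distinct,
        adaptor_total=adaptor_total,
        singleton_distinct=singletons,
        singleton_total=singletons,
    )
    acc.clean_distinct = (
        raw_distinct - n_containing_distinct - adaptor_distinct - singletons
    )
    acc.clean_total = raw_total - n_containing_total - adaptor_total - singletons
    acc.validate()
    return acc
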