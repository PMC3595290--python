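"""Per-gene tag counting and tags-per-million normalisation.

Expression of a gene in one library is the number of unambiguous clean
tags assigned to it ("raw intensity"), normalised to tags per million
clean tags:

    tpm = raw_count / clean_total * 1e6

Genes with zero unambiguous tags are reported at a floor TPM (default
0.01) so that fold changes stay finite; the raw count keeps the true
zero, and a ``detected`` flag distinguishes floored values.  The TPM
denominator is the total number of clean tags in the library, not the
mapped subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from dgetag.index import VirtualTagIndex, assign_tag
from dgetag.library import TagLibrary

TPM_FLOOR = 0.01


@dataclass
class GeneCounts:
    """Unambiguous per-gene tag counts plus the excluded-tag tallies."""

    counts: pd.Series  # gene id -> copies of uniquely assigned clean tags
    ambiguous_total: int
    unmapped_total: int

    @property
    def assigned_total(self) -> int:
        return int(self.counts.sum())


def count_genes(clean: TagLibrary, index: VirtualTagIndex, genes=None) -> GeneCounts:
    """Assign every clean tag and sum unique-copy counts per gene.

    ``genes`` fixes the output universe (all index genes by default);
    genes with no assigned tags get count 0.  Copies of ambiguous and
    unmapped tags are tallied separately, never attributed to genes.
    """
    totals: dict[str, int] = {}
    ambiguous = 0
    unmapped = 0
    for tag, copies in clean.items():
        a = assign_tag(tag, index)
        if a.status == "unique":
            totals[a.gene] = totals.get(a.gene, 0) + copies
        elif a.status == "ambiguous":
            ambiguous += copies
        else:
            unmapped += copies
    if genes is None:
        universe = sorted({g for gs in index.exact_map.values() for g in gs})
    else:
        universe = list(genes)
    counts = pd.Series(
        [totals.get(g, 0) for g in universe], index=universe, dtype="int64", name="raw_count"
    )
    return GeneCounts(counts=counts, ambiguous_total=ambiguous, unmapped_total=unmapped)


def tpm_normalize(
    counts: pd.Series, clean_total: int, floor: float = TPM_FLOOR
) -> pd.Series:
    """Tags per million clean tags, with zero counts floored.

    Raises on a non-positive library size.  The floor applies only to
    zero-count genes; any positive count keeps its exact TPM.
    """
    if clean_total <= 0:
        raise ValueError(f"clean_total must be positive, got {clean_total}")
    tpm = counts.astype(float) / clean_total * 1e6
    tpm[counts == 0] = floor
    return tpm.rename("tpm")


def expression_table(
    counts: GeneCounts | pd.Series, clean_total: int, floor: float = TPM_FLOOR
) -> pd.DataFrame:
    """Gene table with raw_count, tpm (floored), and detection flag."""
    raw = counts.counts if isinstance(counts, GeneCounts) else counts
    return pd.DataFrame(
        {
            "raw_count": raw.astype("int64"),
            "tpm": tpm_normalize(raw, clean_total, floor),
            "detected": raw > 0,
        }
    )
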