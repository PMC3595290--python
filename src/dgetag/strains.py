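"""Three-strain expression partitioning and complementation categories.

For a homokaryon pair (P1, P2) and their heterokaryon (H), this module
computes the 8-region detection Venn partition, pairwise fold-change
gene sets, and the heterokaryon-complementation categories:

    A - no detectable expression in P1, high in P2
    B - no detectable expression in P2, high in P1
    C - extreme low expression in both parents, boosted in H

"Expressed" defaults to >= 1 unambiguous clean tag, the weakest
count-based rule; undetected genes carry the floor TPM (0.01).  Fold
comparisons use floored TPM so zero-count genes have finite ratios.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

from dgetag.quantify import TPM_FLOOR


@dataclass
class VennResult:
    """Counts for the 8 detection patterns across an ordered strain triple."""

    strains: tuple[str, ...]
    regions: dict[tuple[bool, ...], int]
    pct_expressed_any: float

    @property
    def total(self) -> int:
        return sum(self.regions.values())

    def region(self, *detected_in: str) -> int:
        key = tuple(s in detected_in for s in self.strains)
        return self.regions[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**{s: k[i] for i, s in enumerate(self.strains)}, "genes": v}
            for k, v in sorted(self.regions.items(), reverse=True)
        ]
        return pd.DataFrame(rows)


def pct_expressed_any(total_genes: int, undetected_in_all: int) -> float:
    """Percentage of the reference genes detected in at least one strain."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    return round((total_genes - undetected_in_all) / total_genes * 100, 2)


def venn_partition(
    detected: Mapping[str, pd.Series], min_count: int | None = None
) -> VennResult:
    """Partition the gene universe by detection pattern across strains.

    ``detected`` maps strain name to either a boolean detection Series or
    a raw-count Series (then ``min_count``, default 1, is the detection
    rule).  All series must share one gene universe.
    """
    strains = tuple(detected)
    series = {}
    for s, v in detected.items():
        if v.dtype == bool:
            series[s] = v
        else:
            series[s] = v >= (1 if min_count is None else min_count)
    first = series[strains[0]]
    for s in strains[1:]:
        if not series[s].index.equals(first.index):
            raise ValueError(f"strain {s!r} has a different gene universe")
    flags = pd.DataFrame(series)
    regions = {
        pattern: 0 for pattern in itertools.product([True, False], repeat=len(strains))
    }
    for pattern, count in flags.value_counts().items():
        regions[tuple(pattern)] = int(count)
    none = regions[tuple([False] * len(strains))]
    return VennResult(
        strains=strains,
        regions=regions,
        pct_expressed_any=pct_expressed_any(len(first), none),
    )


def fold_classify(
    tpm1: pd.Series, tpm2: pd.Series, k: float
) -> tuple[pd.Index, pd.Index]:
    """Genes whose floored TPM differs by at least k-fold between strains.

    Returns (up, down): up = tpm2/tpm1 >= k (higher in the second
    strain), down = tpm1/tpm2 >= k.
    """
    if k <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {k}")
    if not tpm1.index.equals(tpm2.index):
        raise ValueError("TPM series must share one gene universe")
    up = tpm1.index[tpm2 / tpm1 >= k]
    down = tpm1.index[tpm1 / tpm2 >= k]
    return up, down


def complementation_classify(
    tpm_p1: pd.Series,
    tpm_p2: pd.Series,
    tpm_h: pd.Series,
    *,
    counts_p1: pd.Series | None = None,
    counts_p2: pd.Series | None = None,
    undetected_tpm: float = TPM_FLOOR,
    low_tpm: float = 20.0,
    high_tpm: float = 50.0,
    min_fold: float = 3.0,
) -> pd.Series:
    """Assign each gene a complementation category: A, B, C, or none.

    "Undetected" means zero unambiguous tags when raw counts are
    supplied, otherwise TPM at the reporting floor.  The categories are
    mutually exclusive by construction: A and B require high expression
    (>= high_tpm) in the detected parent, which is incompatible with C's
    low-parent condition (<= low_tpm) and with being undetected.
    """
    if not (tpm_p1.index.equals(tpm_p2.index) and tpm_p1.index.equals(tpm_h.index)):
        raise ValueError("TPM series must share one gene universe")
    undet1 = (counts_p1 == 0) if counts_p1 is not None else (tpm_p1 <= undetected_tpm)
    undet2 = (counts_p2 == 0) if counts_p2 is not None else (tpm_p2 <= undetected_tpm)

    cat_a = undet1 & (tpm_p2 >= high_tpm)
    cat_b = undet2 & (tpm_p1 >= high_tpm)
    cat_c = (
        (tpm_p1 <= low_tpm)
        & (tpm_p2 <= low_tpm)
        & (tpm_h >= high_tpm)
        & (tpm_h >= min_fold * tpm_p1)
        & (tpm_h >= min_fold * tpm_p2)
        & ~cat_a
        & ~cat_b
    )
    out = pd.Series("none", index=tpm_p1.index, name="category")
    out[cat_c] = "C"
    out[cat_b] = "B"
    out[cat_a] = "A"
    return out
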