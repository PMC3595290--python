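"""CAZyme family-abundance matrices and double hierarchical clustering.

Carbohydrate-active enzymes (CAZymes) fall into four classes relevant to
biomass degradation — glycoside hydrolases (GH), glycosyltransferases
(GT), polysaccharide lyases (PL) and carbohydrate esterases (CE) — each
subdivided into numbered families (GH10, PL1, ...).  This module builds
and interrogates genome x family count matrices: per-class totals,
lineage averages, genome ranking, per-class maxima, and double
(row and column) agglomerative clustering with heatmap export.
"""

from __future__ import annotations

import math
import os
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

CAZY_CLASSES = ("GH", "GT", "PL", "CE")
_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE)\d*[a-z]?$")


def family_class(family: str) -> str:
    """Class of a CAZy family name, e.g. 'GH10' -> 'GH'."""
    m = _FAMILY_RE.match(family)
    if not m:
        raise ValueError(f"cannot resolve CAZy class of family {family!r}")
    return m.group(1)


@dataclass
class FamilyAbundanceMatrix:
    """Genome x family nonnegative gene counts with a family->class map."""

    counts: pd.DataFrame  # index: genomes, columns: families
    class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("family counts must be nonnegative")
        for fam in self.counts.columns:
            if fam not in self.class_map:
                self.class_map[fam] = family_class(fam)
        unknown = set(self.class_map.values()) - set(CAZY_CLASSES)
        if unknown:
            raise ValueError(f"unknown CAZy classes: {sorted(unknown)}")

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def class_total(self, genome: str, cls: str) -> int:
        fams = [f for f in self.counts.columns if self.class_map[f] == cls]
        return int(self.counts.loc[genome, fams].sum())

    def class_totals_frame(self) -> pd.DataFrame:
        """Genome x class totals (columns ordered GH, GT, PL, CE)."""
        data = {
            cls: self.counts[[f for f in self.families if self.class_map[f] == cls]].sum(axis=1)
            for cls in CAZY_CLASSES
        }
        return pd.DataFrame(data, index=self.counts.index).astype(int)

    def grand_totals(self) -> pd.Series:
        return self.counts.sum(axis=1).astype(int)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FamilyAbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.counts.to_csv(path, sep="\t")


def class_totals(
    annotation: pd.DataFrame | pd.Series | Mapping[str, str],
    class_map: Optional[Mapping[str, str]] = None,
) -> tuple[pd.Series, int]:
    """Per-class gene counts and the grand total from a gene->family table.

    ``annotation`` is a gene->family mapping (Series/dict) or a DataFrame
    with columns ``gene`` and ``family``.  Families missing from
    ``class_map`` fall back to name-prefix resolution; unresolvable rows
    raise with the offending entries listed.
    """
    if isinstance(annotation, pd.DataFrame):
        fams = pd.Series(annotation["family"].to_numpy(), index=annotation["gene"])
    elif isinstance(annotation, pd.Series):
        fams = annotation
    else:
        fams = pd.Series(dict(annotation))

    bad: list[tuple[str, str]] = []
    classes = []
    for gene, fam in fams.items():
        try:
            cls = class_map[fam] if class_map and fam in class_map else family_class(str(fam))
        except ValueError:
            bad.append((str(gene), str(fam)))
            continue
        classes.append(cls)
    if bad:
        raise ValueError(f"unresolvable CAZy families: {bad}")
    counted = pd.Series(classes).value_counts()
    totals = pd.Series({c: int(counted.get(c, 0)) for c in CAZY_CLASSES}, name="genes")
    return totals, int(totals.sum())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def lineage_average(
    matrix: FamilyAbundanceMatrix, genomes: Sequence[str], cls: str
) -> int:
    """Mean class total over a genome subset, rounded half away from zero."""
    if len(genomes) == 0:
        raise ValueError("genome subset must be non-empty")
    totals = [matrix.class_total(g, cls) for g in genomes]
    return _round_half_away(float(np.mean(totals)))


def rank_by_total(matrix: FamilyAbundanceMatrix, genome: str) -> int:
    """Descending rank of a genome's grand CAZyme total (ties -> min rank)."""
    totals = matrix.grand_totals()
    if genome not in totals.index:
        raise KeyError(f"unknown genome {genome!r}")
    return int((totals > totals[genome]).sum()) + 1


def max_in_lineage(
    matrix: FamilyAbundanceMatrix, genomes: Sequence[str], cls: str
) -> tuple[list[str], int]:
    """Genome(s) with the largest class total in a subset, and that total."""
    if len(genomes) == 0:
        raise ValueError("genome subset must be non-empty")
    totals = {g: matrix.class_total(g, cls) for g in genomes}
    best = max(totals.values())
    return [g for g in genomes if totals[g] == best], best


@dataclass
class BiclusterResult:
    """Row/column leaf orders and merge trees from double clustering."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: Optional[np.ndarray]
    col_linkage: Optional[np.ndarray]
    degenerate: bool = False


def _cluster_axis(data: np.ndarray, metric: str, method: str):
    if data.shape[0] < 2:
        return None, [0]
    Z = linkage(pdist(data, metric=metric), method=method)
    return Z, list(leaves_list(Z))


def bicluster(
    matrix: pd.DataFrame | FamilyAbundanceMatrix,
    metric: str = "euclidean",
    method: str = "average",
) -> BiclusterResult:
    """Independent agglomerative clustering of rows and columns.

    Defaults (Euclidean distance on raw counts, average linkage) are a
    declared convention; they are configurable and leaf order is the
    only contract — the exact dendrogram shape depends on the choices.
    A constant matrix yields a valid but arbitrary order and is flagged.
    """
    df = matrix.counts if isinstance(matrix, FamilyAbundanceMatrix) else matrix
    values = df.to_numpy(dtype=float)
    degenerate = bool(np.ptp(values) == 0)
    row_Z, row_idx = _cluster_axis(values, metric, method)
    col_Z, col_idx = _cluster_axis(values.T, metric, method)
    return BiclusterResult(
        row_order=[df.index[i] for i in row_idx],
        col_order=[df.columns[i] for i in col_idx],
        row_linkage=row_Z,
        col_linkage=col_Z,
        degenerate=degenerate,
    )


def linkage_to_newick(Z: Optional[np.ndarray], labels: Sequence[str]) -> str:
    """Newick serialisation of a scipy linkage matrix (single leaf ok)."""
    if Z is None:
        if len(labels) != 1:
            raise ValueError("linkage required for more than one leaf")
        return f"{labels[0]};"
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(labels))
    return str(tree).strip()


def plot_heatmap(
    matrix: pd.DataFrame | FamilyAbundanceMatrix,
    result: BiclusterResult,
    path: str | os.PathLike,
    vmax: float = 20.0,
) -> None:
    """Clustered heatmap with the colour scale clipped at >vmax."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.counts if isinstance(matrix, FamilyAbundanceMatrix) else matrix
    ordered = df.loc[result.row_order, result.col_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(ordered.columns)), max(4, 0.25 * len(ordered.index)))
    )
    im = ax.imshow(ordered.to_numpy(), cmap="hot", vmin=0, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"gene count (clipped at >{vmax:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
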