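"""Virtual-tag index and one-mismatch tag-to-gene assignment.

NlaIII cuts transcripts at CATG; MmeI then releases a short fragment
downstream of the cut, so every observed DGE tag is a CATG anchor plus
~17 nt of downstream transcript sequence.  The "virtual" tag index
enumerates every such window in the predicted gene models, which is the
reference an observed tag is matched against.

Assignment gives strict priority to exact matches; only when a tag has
no exact hit is its Hamming-distance-1 neighbourhood consulted.  A tag
whose winning priority level spans several genes is ambiguous and is
excluded from expression counting.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from typing import Optional

ANCHOR = "CATG"
DEFAULT_TAG_LENGTH = 21  # 4 nt CATG anchor + 17 nt MmeI-released downstream
_BASES = "ACGT"


@dataclass(frozen=True)
class TagAssignment:
    """Outcome of matching one observed tag against the index."""

    tag: str
    status: str  # "unique" | "ambiguous" | "unmapped"
    gene: Optional[str] = None  # present iff status == "unique"
    match_type: Optional[str] = None  # "exact" | "one_mismatch"


@dataclass
class VirtualTagIndex:
    """Map from tag sequence to the set of genes containing that window."""

    tag_length: int
    exact_map: dict[str, frozenset[str]]
    gene_count: int

    def __contains__(self, tag: str) -> bool:
        return tag in self.exact_map

    def __len__(self) -> int:
        return len(self.exact_map)

    def genes_exact(self, tag: str) -> frozenset[str]:
        return self.exact_map.get(tag, frozenset())

    def genes_one_mismatch(self, tag: str) -> frozenset[str]:
        """Union of gene sets over all Hamming-distance-1 neighbours."""
        hits: set[str] = set()
        get = self.exact_map.get
        for i, orig in enumerate(tag):
            head, tail = tag[:i], tag[i + 1 :]
            for base in _BASES:
                if base == orig:
                    continue
                found = get(head + base + tail)
                if found:
                    hits.update(found)
        return frozenset(hits)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tgenes\n")
            for tag in sorted(self.exact_map):
                fh.write(f"{tag}\t{','.join(sorted(self.exact_map[tag]))}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "VirtualTagIndex":
        exact: dict[str, frozenset[str]] = {}
        genes: set[str] = set()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag\t"):
                raise ValueError(f"{path}: expected 'tag\\tgenes' header")
            for line in fh:
                tag, ids = line.rstrip("\n").split("\t")
                gset = frozenset(ids.split(","))
                exact[tag] = gset
                genes.update(gset)
        lengths = {len(t) for t in exact}
        if len(lengths) > 1:
            raise ValueError("index contains mixed tag lengths")
        return cls(tag_length=lengths.pop() if lengths else DEFAULT_TAG_LENGTH,
                   exact_map=exact, gene_count=len(genes))


def _iter_gene_seqs(genes) -> Iterable[tuple[str, str]]:
    """Accept {id: seq} mappings or iterables of (id, seq) / SeqRecord."""
    if isinstance(genes, Mapping):
        yield from ((str(g), str(s)) for g, s in genes.items())
        return
    for item in genes:
        if hasattr(item, "id") and hasattr(item, "seq"):
            yield str(item.id), str(item.seq)
        else:
            gene, seq = item
            yield str(gene), str(seq)


def iter_catg_windows(seq: str, tag_length: int) -> Iterable[str]:
    """Yield every sense-strand CATG-anchored window of tag_length nt.

    Windows truncated by the transcript end or containing any non-ACGT
    character (e.g. N) are skipped.
    """
    seq = seq.upper()
    start = seq.find(ANCHOR)
    while start != -1:
        window = seq[start : start + tag_length]
        if len(window) == tag_length and all(b in _BASES for b in window):
            yield window
        start = seq.find(ANCHOR, start + 1)


def three_prime_tag(seq: str, tag_length: int = DEFAULT_TAG_LENGTH) -> Optional[str]:
    """Tag emitted by the NlaIII/MmeI chemistry: the 3'-most usable window.

    Returns None when the transcript has no CATG site with enough clean
    downstream sequence; such a gene yields no tags at all.
    """
    last = None
    for window in iter_catg_windows(seq, tag_length):
        last = window
    return last


def extract_virtual_tags(genes, tag_length: int = DEFAULT_TAG_LENGTH) -> VirtualTagIndex:
    """Build the reference index from all CATG windows of all transcripts.

    Every sense-strand CATG occurrence with at least ``tag_length - 4``
    downstream nucleotides contributes one entry; the same window seen in
    several genes maps to the set of those genes.  The index is
    deliberately broader than the emission model (which uses only the
    3'-most site per transcript): internal-site tags arise in real
    libraries from incomplete digestion, and indexing them only adds
    ambiguity, which is excluded downstream anyway.
    """
    if tag_length < 5:
        raise ValueError(f"tag_length must be >= 5, got {tag_length}")
    building: dict[str, set[str]] = {}
    n_genes = 0
    for gene, seq in _iter_gene_seqs(genes):
        n_genes += 1
        for window in iter_catg_windows(seq, tag_length):
            building.setdefault(window, set()).add(gene)
    exact = {tag: frozenset(gs) for tag, gs in building.items()}
    return VirtualTagIndex(tag_length=tag_length, exact_map=exact, gene_count=n_genes)


def assign_tag(tag: str, index: VirtualTagIndex) -> TagAssignment:
    """Classify one observed tag as unique, ambiguous, or unmapped.

    Exact hits take strict priority over one-mismatch hits, which
    minimises false ambiguity: a tag that is an exact window of exactly
    one gene is unique even if its distance-1 neighbourhood spans others.
    """
    if len(tag) != index.tag_length:
        raise ValueError(
            f"tag length {len(tag)} does not match index tag_length {index.tag_length}"
        )
    genes = index.genes_exact(tag)
    match_type = "exact"
    if not genes:
        genes = index.genes_one_mismatch(tag)
        match_type = "one_mismatch"
    if not genes:
        return TagAssignment(tag, "unmapped")
    if len(genes) == 1:
        return TagAssignment(tag, "unique", gene=next(iter(genes)), match_type=match_type)
    return TagAssignment(tag, "ambiguous", match_type=match_type)
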