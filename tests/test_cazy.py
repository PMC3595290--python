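"""CAZyme matrix arithmetic and double clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dgetag import datasets
from dgetag.cazy import (
    FamilyAbundanceMatrix,
    bicluster,
    class_totals,
    family_class,
    lineage_average,
    linkage_to_newick,
    max_in_lineage,
    rank_by_total,
)


class TestClassTotals:
    def test_reference_genome_totals(self):
        m = datasets.cazyme_class_counts()
        row = m.class_totals_frame().loc["V. volvacea"]
        assert tuple(row) == (191, 44, 19, 31)
        assert m.grand_totals()["V. volvacea"] == 285

    def test_empty_annotation(self):
        totals, grand = class_totals({})
        assert grand == 0 and (totals == 0).all()

    def test_toy_annotation_hand_enumeration(self):
        ann = {
            "g1": "GH10", "g2": "GH43", "g3": "GH10",
            "g4": "GT2", "g5": "PL1", "g6": "CE12", "g7": "CE4",
        }
        totals, grand = class_totals(ann)
        assert totals.to_dict() == {"GH": 3, "GT": 1, "PL": 1, "CE": 2}
        assert grand == 7

    def test_unknown_family_reported(self):
        with pytest.raises(ValueError, match="g2"):
            class_totals({"g1": "GH10", "g2": "XX9"})

    def test_family_class_parsing(self):
        assert family_class("GH10") == "GH"
        assert family_class("GH5b") == "GH"
        with pytest.raises(ValueError):
            family_class("AA9x7")


class TestLineageStats:
    def test_basidiomycete_class_means(self):
        m = datasets.cazyme_class_counts()
        sub = datasets.BASIDIOMYCETES
        assert lineage_average(m, sub, "GH") == 161
        assert lineage_average(m, sub, "GT") == 65
        assert lineage_average(m, sub, "PL") == 8
        assert lineage_average(m, sub, "CE") == 24

    def test_single_genome_subset(self):
        m = datasets.cazyme_class_counts()
        assert lineage_average(m, ["V. volvacea"], "PL") == 19

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            lineage_average(datasets.cazyme_class_counts(), [], "GH")

    def test_polysaccharide_lyase_maximum(self):
        m = datasets.cazyme_class_counts()
        genomes, count = max_in_lineage(m, datasets.BASIDIOMYCETES, "PL")
        assert genomes == ["V. volvacea"] and count == 19

    def test_all_equal_column_full_tie(self):
        df = pd.DataFrame({"GH": [3, 3, 3]}, index=list("abc"))
        m = FamilyAbundanceMatrix(df)
        genomes, count = max_in_lineage(m, list("abc"), "GH")
        assert genomes == ["a", "b", "c"] and count == 3

    def test_max_agrees_with_brute_force(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            rng.integers(0, 30, (5, 3)), index=list("vwxyz"), columns=["GH1", "GH2", "PL9"]
        )
        m = FamilyAbundanceMatrix(df)
        genomes, count = max_in_lineage(m, list("vwxyz"), "GH")
        totals = {g: int(df.loc[g, ["GH1", "GH2"]].sum()) for g in df.index}
        assert count == max(totals.values())
        assert set(genomes) == {g for g, t in totals.items() if t == count}


class TestRank:
    def test_reference_rank_seventh_of_fifteen(self):
        m = datasets.cazyme_class_counts()
        assert len(m.genomes) == 15
        assert rank_by_total(m, "V. volvacea") == 7

    def test_single_genome(self):
        m = FamilyAbundanceMatrix(pd.DataFrame({"GH1": [5]}, index=["only"]))
        assert rank_by_total(m, "only") == 1

    def test_ties_take_minimum_rank(self):
        m = FamilyAbundanceMatrix(
            pd.DataFrame({"GH1": [5, 5, 2]}, index=["a", "b", "c"])
        )
        assert rank_by_total(m, "a") == rank_by_total(m, "b") == 1
        assert rank_by_total(m, "c") == 3

    def test_unknown_genome_rejected(self):
        with pytest.raises(KeyError):
            rank_by_total(datasets.cazyme_class_counts(), "E. coli")


def naive_average_linkage(points: np.ndarray):
    """Brute-force UPGMA: exhaustive pairwise agglomeration oracle."""
    dist = {
        frozenset({i, j}): float(np.linalg.norm(points[i] - points[j]))
        for i, j in itertools.combinations(range(len(points)), 2)
    }
    clusters = {i: frozenset({i}) for i in range(len(points))}
    merges = []
    while len(clusters) > 1:
        best, height = None, np.inf
        for a, b in itertools.combinations(clusters, 2):
            pairs = [dist[frozenset({i, j})] for i in clusters[a] for j in clusters[b]]
            d = float(np.mean(pairs))
            if d < height:
                best, height = (a, b), d
        a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[len(points) + len(merges)] = merged
        merges.append((merged, height))
    return merges


class TestBicluster:
    def test_identical_columns_merge_first(self):
        df = pd.DataFrame(
            {"a": [1, 5, 9], "b": [1, 5, 9], "c": [9, 0, 2]}, index=list("xyz")
        )
        res = bicluster(df)
        first = sorted(res.col_linkage[0, :2].astype(int))
        assert [df.columns[i] for i in first] == ["a", "b"]
        assert res.col_linkage[0, 2] == 0.0

    def test_merge_order_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.uniform(0, 10, (4, 4)), index=list("abcd"))
        res = bicluster(df, metric="euclidean", method="average")
        oracle = naive_average_linkage(df.to_numpy())
        assert res.row_linkage[:, 2] == pytest.approx([h for _, h in oracle])
        # reconstruct member sets from the scipy linkage
        members = {i: frozenset({i}) for i in range(4)}
        for k, (i, j, _, _) in enumerate(res.row_linkage):
            members[4 + k] = members[int(i)] | members[int(j)]
        assert [members[4 + k] for k in range(3)] == [m for m, _ in oracle]

    def test_single_row_matrix(self):
        df = pd.DataFrame([[1, 2, 3]], index=["only"], columns=list("abc"))
        res = bicluster(df)
        assert res.row_order == ["only"] and res.row_linkage is None
        assert len(res.col_order) == 3

    def test_constant_matrix_flagged(self):
        df = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("xyz"))
        res = bicluster(df)
        assert res.degenerate
        assert sorted(res.row_order) == list("abc")

    def test_leaf_orders_are_permutations(self):
        m = datasets.cazyme_class_counts()
        res = bicluster(m.counts)
        assert sorted(res.row_order) == sorted(m.genomes)
        assert sorted(res.col_order) == sorted(m.families)
        assert np.all(np.diff(res.row_linkage[:, 2]) >= 0)

    def test_newick_roundtrip_leaves(self):
        m = datasets.cazyme_class_counts()
        res = bicluster(m.counts)
        nwk = linkage_to_newick(res.col_linkage, m.families)
        for fam in m.families:
            assert fam in nwk
        assert linkage_to_newick(None, ["leaf"]) == "leaf;"
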