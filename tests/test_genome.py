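"""Gene-map queries against hand examples and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from zripple.genome import (
    GENE_COLUMNS,
    GeneMap,
    GeneMapError,
    IntervalSet,
    body_distance,
    classify_orientation,
)
from conftest import random_map


class TestOrientation:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ("-", "+", "divergent"),
            ("+", "-", "convergent"),
            ("+", "+", "cooriented"),
            ("-", "-", "cooriented"),
        ],
    )
    def test_classes(self, left, right, expected):
        assert classify_orientation(left, right) == expected

    def test_missing_strand_raises(self):
        with pytest.raises(GeneMapError):
            classify_orientation(".", "+")


class TestNearestDownstream:
    def test_simple_pair_gap(self, tiny_map):
        pair = tiny_map.nearest_downstream("A")
        assert pair.neighbor == "B"
        assert pair.gap_bp == 499  # 2500 - 2000 - 1
        assert pair.orientation == "convergent"
        assert not pair.overlapping

    def test_beyond_max_gap_returns_none(self, tiny_map):
        assert tiny_map.nearest_downstream("C", max_gap=100_000) is None
        assert tiny_map.nearest_downstream("E", max_gap=100_000).neighbor == "F"

    def test_overlapping_neighbor_flagged(self, tiny_map):
        pair = tiny_map.nearest_downstream("B")
        assert pair.neighbor == "C"
        assert pair.overlapping
        assert pair.gap_bp < 0

    def test_chromosome_terminal_gene(self, tiny_map):
        assert tiny_map.nearest_downstream("D") is None

    def test_matches_brute_force_scan(self):
        """Vectorized table equals an exhaustive all-pairs scan."""
        rng = np.random.default_rng(21)
        for trial in range(5):
            gmap = random_map(rng)
            table = gmap.nearest_downstream_table(max_gap=60_000)
            got = {r.focal: r.neighbor for r in table.itertuples()}
            loci = gmap.loci
            for _, f in loci.iterrows():
                cands = loci[
                    (loci["chrom"] == f["chrom"]) & (loci["start"] > f["start"])
                ].sort_values(["start", "end", "gene"])
                expect = None
                if len(cands):
                    nb = cands.iloc[0]
                    overlapping = nb["start"] <= f["end"]
                    gap = nb["start"] - f["end"] - 1
                    if overlapping or gap <= 60_000:
                        expect = nb["gene"]
                assert got.get(f["gene"]) == expect

    def test_single_result_per_focal(self):
        rng = np.random.default_rng(22)
        gmap = random_map(rng)
        table = gmap.nearest_downstream_table(max_gap=10**9)
        assert not table["focal"].duplicated().any()


class TestFlankingPair:
    def test_middle_gene_has_both_flanks(self, tiny_map):
        flanks = tiny_map.flanking_pair("B", max_gap=100_000)
        assert flanks is not None
        up, down = flanks
        assert up.focal == "A" and up.neighbor == "B"
        assert down.neighbor == "C"

    def test_terminal_gene_none(self, tiny_map):
        assert tiny_map.flanking_pair("A") is None
        assert tiny_map.flanking_pair("D") is None

    def test_far_flank_none(self, tiny_map):
        assert tiny_map.flanking_pair("F", max_gap=1_000) is None


class TestNeighborsWithin:
    def test_isolated_gene_empty(self, tiny_map):
        assert tiny_map.neighbors_within("D", radius=100_000) == []

    def test_boundary_uses_le_rule(self):
        records = [
            ("x", "chr1", 1, 100, "+"),
            ("near", "chr1", 100_100, 100_200, "+"),   # gap 99,999
            ("far", "chr1", 200_102, 200_300, "+"),    # gap 100,001 from x
        ]
        gmap = GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))
        assert gmap.neighbors_within("x", radius=100_000) == ["near"]

    def test_symmetry_and_brute_force(self):
        rng = np.random.default_rng(23)
        gmap = random_map(rng, n=40)
        radius = 30_000
        sets = gmap.neighbor_sets_within(radius)
        loci = gmap.loci.set_index("gene")
        for g1, neigh in sets.items():
            for g2 in neigh:
                assert g1 in sets[g2]  # symmetry
        for g1 in loci.index:  # brute-force distance matrix
            expect = []
            for g2 in loci.index:
                if g1 == g2 or loci.loc[g1, "chrom"] != loci.loc[g2, "chrom"]:
                    continue
                d = body_distance(
                    loci.loc[g1, "start"], loci.loc[g1, "end"],
                    loci.loc[g2, "start"], loci.loc[g2, "end"],
                )
                if d <= radius:
                    expect.append(g2)
            assert sorted(sets[g1]) == sorted(expect)


class TestOverlaps:
    def test_touching_is_not_overlap(self):
        records = [
            ("A", "chr1", 1, 100, "+"),
            ("B", "chr1", 50, 150, "+"),
            ("C", "chr1", 151, 200, "+"),
        ]
        gmap = GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))
        adj = gmap.detect_overlaps().set_index(["left", "right"])
        assert adj.loc[("A", "B"), "overlapping"]
        assert not adj.loc[("B", "C"), "overlapping"]

    def test_matches_interval_tree_oracle(self):
        rng = np.random.default_rng(24)
        gmap = random_map(rng, n=50)
        adj = gmap.detect_overlaps()
        loci = gmap.loci.set_index("gene")
        trees = {}
        for chrom, sub in gmap.loci.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                (s, e + 1, g) for g, s, e in zip(sub["gene"], sub["start"], sub["end"])
            )
        for row in adj.itertuples():
            right = loci.loc[row.right]
            hits = {
                iv.data
                for iv in trees[right["chrom"]].overlap(
                    right["start"], right["end"] + 1
                )
            }
            hits.discard(row.right)
            # the adjacency flag concerns genes at or before `right` in sort order
            upstream_hits = {
                g for g in hits
                if (loci.loc[g, "start"], loci.loc[g, "end"], g)
                <= (right["start"], right["end"], row.right)
            }
            assert row.overlapping == bool(upstream_hits)


class TestIntervalOverlap:
    def test_bed_convention_boundary(self):
        gmap = GeneMap(
            pd.DataFrame([("G", "chr1", 1001, 2000, "+")], columns=GENE_COLUMNS)
        )
        away = IntervalSet("a", pd.DataFrame(
            [("chr1", 2000, 3000)], columns=["chrom", "start", "end"]))
        near = IntervalSet("b", pd.DataFrame(
            [("chr1", 1999, 2100)], columns=["chrom", "start", "end"]))
        assert not gmap.gene_interval_overlap(away)["G"]
        assert gmap.gene_interval_overlap(near)["G"]

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(25)
        gmap = random_map(rng, n=20, chroms=2)
        iv_rows = [
            (f"chr{rng.integers(1, 3)}", int(s := rng.integers(0, 150_000)),
             int(s + rng.integers(1, 40_000)))
            for _ in range(15)
        ]
        ivs = IntervalSet("x", pd.DataFrame(iv_rows, columns=["chrom", "start", "end"]))
        got = gmap.gene_interval_overlap(ivs)
        for _, g in gmap.loci.iterrows():
            covered = np.zeros(g["end"] - g["start"] + 1, dtype=bool)
            for chrom, s0, e0 in iv_rows:
                if chrom != g["chrom"]:
                    continue
                lo = max(s0 + 1, g["start"]) - g["start"]
                hi = min(e0, g["end"]) - g["start"]
                if hi >= lo:
                    covered[lo : hi + 1] = True
            assert got[g["gene"]] == covered.any()

    def test_malformed_bed_line_number(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t10\t20\nchr1\toops\t30\n")
        with pytest.raises(GeneMapError, match="2"):
            IntervalSet.from_bed(bad)


class TestWindowQuery:
    def test_empty_region(self, tiny_map):
        assert tiny_map.window_query("chr1", 100_000, 10_000) == []

    def test_straddling_gene_included(self, tiny_map):
        assert "D" in tiny_map.window_query("chr1", 499_000, 1_500)

    def test_unknown_chromosome(self, tiny_map):
        with pytest.raises(GeneMapError):
            tiny_map.window_query("chr9", 1, 10)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(26)
        gmap = random_map(rng, n=40)
        for _ in range(10):
            chrom = f"chr{rng.integers(1, 4)}"
            pos, win = int(rng.integers(1, 250_000)), int(rng.integers(1, 50_000))
            got = set(gmap.window_query(chrom, pos, win))
            expect = {
                g["gene"]
                for _, g in gmap.loci.iterrows()
                if g["chrom"] == chrom
                and g["start"] <= pos + win
                and g["end"] >= pos - win
            }
            assert got == expect


class TestValidation:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            [("A", "chr1", 1, 10, "+"), ("A", "chr1", 20, 30, "-")],
            columns=GENE_COLUMNS,
        )
        with pytest.raises(GeneMapError, match="duplicate"):
            GeneMap(df)

    def test_orientation_partitions_nearest_pairs(self):
        rng = np.random.default_rng(27)
        gmap = random_map(rng, n=80)
        table = gmap.nearest_downstream_table(max_gap=10**9)
        nonover = table[~table["overlapping"]]
        counts = nonover["orientation"].value_counts()
        assert counts.sum() == len(nonover)
        assert set(counts.index) <= {"divergent", "convergent", "cooriented"}

    def test_tsv_round_trip(self, tiny_map, tmp_path):
        path = tmp_path / "map.tsv"
        tiny_map.to_tsv(path)
        again = GeneMap.from_tsv(path)
        pd.testing.assert_frame_equal(tiny_map.loci, again.loci)
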