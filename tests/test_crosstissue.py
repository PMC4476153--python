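"""Concertedness, TSU, chromatin chi-squares, and track correlations."""

import numpy as np
import pandas as pd
import pytest

from zripple.crosstissue import (
    cluster_peak_enrichment,
    concerted_cluster_scan,
    concerted_expectation,
    scalar_track_correlation,
    tsu_classify,
    tsu_neighbor_test,
    two_cell_chisq,
    z_sum,
    zsum_distribution_test,
)
from zripple.genome import IntervalSet
from zripple.neighborstats import run_edges
from zripple.pipeline import sign_wide, z_series, z_wide


class TestZSum:
    def test_all_positive(self):
        signs = pd.DataFrame([[1] * 6], columns=list("abcdef"))
        assert z_sum(signs).iloc[0] == 6

    def test_balanced(self):
        signs = pd.DataFrame([[1, 1, 1, -1, -1, -1]])
        assert z_sum(signs).iloc[0] == 0

    def test_zero_contributes_nothing(self):
        signs = pd.DataFrame([[1, 1, 1, 0, -1, -1]])
        assert z_sum(signs).iloc[0] == 1

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            z_sum(pd.DataFrame([[2, 0, 0]]))


class TestConcertedExpectation:
    def test_printed_proportions_product(self):
        props = (0.4916, 0.49996, 0.4999, 0.4999, 0.4999, 0.4999)
        prop, count = concerted_expectation(props, 13_027)
        assert prop == pytest.approx(0.015356, rel=1e-3)
        assert count == pytest.approx(prop * 13_027)

    def test_reduces_to_power(self):
        prop, _ = concerted_expectation([0.5] * 6, 100)
        assert prop == pytest.approx(0.015625)

    def test_zero_proportion_kills_product(self):
        prop, count = concerted_expectation([0.5, 0.0, 0.5], 10)
        assert prop == 0.0 and count == 0.0


class TestZsumDistribution:
    def test_histogram_total_conserved(self, null_study):
        *_, z_table = null_study
        sw = sign_wide(z_table, "male")
        res = zsum_distribution_test(sw, n_rand=60, seed=0)
        assert res.observed.sum() == len(sw)
        assert res.expected.sum() == pytest.approx(len(sw))

    def test_concerted_excess_detected(self, tree):
        from zripple.pipeline import compute_z_table
        from zripple.simulate import SimConfig, generate_gene_map, simulate_expression

        cfg = SimConfig(
            n_genes=500, n_chromosomes=3, seed=2, shift_prob=0.5,
            shift_sd=1.5, concerted_fraction=1.0,
        )
        gmap = generate_gene_map(cfg)
        ds, _ = simulate_expression(gmap, cfg)
        z_table = compute_z_table(ds, tree)
        sw = sign_wide(z_table, "male")
        res = zsum_distribution_test(sw, n_rand=200, seed=3)
        assert res.concerted_fold > 2
        assert res.p_empirical < 0.01


class TestConcertedClusterScan:
    def _ordered(self, flags, chroms):
        return pd.Series(flags), pd.Series(chroms)

    def test_no_concerted_genes(self):
        flags, chroms = self._ordered([0] * 20, ["chr1"] * 20)
        table = concerted_cluster_scan(flags, chroms, n_rand=50, seed=0)
        assert (table["observed"] == 0).all()
        assert (table["empirical_p"] == 1.0).all()

    def test_planted_triples_significant(self):
        flags = [0] * 10 + [1, 1, 1] + [0] * 10 + [1, 1, 1] + [0] * 30 + [1, 1, 1]
        flags += [0] * 60
        chroms = ["chr1"] * len(flags)
        table = concerted_cluster_scan(
            pd.Series(flags), pd.Series(chroms), n_rand=600, seed=1
        )
        row = table[(table["sign"] == 1) & (table["size"] == 3)].iloc[0]
        assert row["observed"] == 3
        assert row["empirical_p"] < 0.05

    def test_broken_by_intervening_gene(self):
        flags = [1, 1, 0, 1, 1]
        table = concerted_cluster_scan(
            pd.Series(flags), pd.Series(["chr1"] * 5), n_rand=20, seed=0
        )
        row = table[(table["sign"] == 1) & (table["size"] == 2)].iloc[0]
        assert row["observed"] == 2
        assert table[(table["sign"] == 1) & (table["size"] == 4)]["observed"].sum() == 0


class TestTSU:
    def test_relaxed_but_not_strict(self):
        z = pd.DataFrame([[1.5, -0.2, 0.0, -1.0, 0.0, 0.3]],
                         columns=list("abcdef"), index=["g"])
        out = tsu_classify(z)
        assert bool(out.loc["g", "relaxed"]) and not bool(out.loc["g", "strict"])
        assert out.loc["g", "focal_tissue"] == "a"

    def test_strict(self):
        z = pd.DataFrame([[1.5, 0.0, 0.0, -1.0, 0.0, -0.3]],
                         columns=list("abcdef"), index=["g"])
        out = tsu_classify(z)
        assert bool(out.loc["g", "strict"])

    def test_two_high_tissues_neither(self):
        z = pd.DataFrame([[1.5, 1.2, 0.0, -1.0, 0.0, -0.3]],
                         columns=list("abcdef"), index=["g"])
        out = tsu_classify(z)
        assert not out.loc["g", ["strict", "relaxed"]].any()

    def test_strict_implies_relaxed(self, clustered_study):
        *_, z_table = clustered_study
        out = tsu_classify(z_wide(z_table, "male"))
        assert (out["relaxed"] | ~out["strict"]).all()

    def test_neighbor_test_runs_and_calibrates_shape(self, clustered_study):
        _, gmap, _, _, z_table = clustered_study
        zw = z_wide(z_table, "male")
        res = tsu_neighbor_test(zw, gmap, proximity="near")
        assert res.df == len(res.per_tissue) - 1
        assert res.fisher_df == 2 * len(res.per_tissue)
        assert 0 <= res.p_value <= 1

    def test_fisher_of_unit_ps_is_zero(self):
        assert -2 * np.log(1.0) * 5 == 0.0


class TestTwoCellChisq:
    def test_observed_equals_expected(self):
        res = two_cell_chisq(100, 100, 40, 40)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_margins_conserved(self):
        res = two_cell_chisq(5_923, 6_495, 5_108, 4_981.5)
        assert res.E_plus + res.E_minus == pytest.approx(res.O_plus + res.O_minus)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_cell_chisq(10, 10, 11, 0)


class TestClusterPeakEnrichment:
    def _clusters(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [1_000, 20_000, 40_000, 60_000],
                "end": [5_000, 25_000, 45_000, 65_000],
                "sign": [1, 1, -1, -1],
            }
        )

    def test_peaks_on_positive_clusters_only(self):
        peaks = IntervalSet(
            "gained",
            pd.DataFrame(
                [("chr1", 1_500, 2_000), ("chr1", 21_000, 22_000)],
                columns=["chrom", "start", "end"],
            ),
        )
        res = cluster_peak_enrichment(self._clusters(), peaks)
        assert res["defined"]
        assert res["plus_with_peak"] == 2 and res["minus_with_peak"] == 0
        assert res["chi2"] > 0

    def test_no_clusters_undefined(self):
        res = cluster_peak_enrichment(
            pd.DataFrame(columns=["chrom", "start", "end", "sign"]),
            IntervalSet("x", pd.DataFrame([("chr1", 1, 2)],
                                          columns=["chrom", "start", "end"])),
        )
        assert not res["defined"]

    def test_flags_match_interval_overlap(self, clustered_study):
        """Cluster peak flags equal gene_interval_overlap on cluster spans."""
        _, gmap, _, _, z_table = clustered_study
        sub = z_table[
            (z_table["tissue"] == "brain")
            & (z_table["sex"] == "male")
            & (~z_table["excluded"])
        ].set_index("gene")
        loci = gmap.loci[gmap.loci["gene"].isin(sub.index)]
        spec = run_edges(
            sub.loc[loci["gene"], "sign"].reset_index(drop=True),
            loci["chrom"].reset_index(drop=True),
            loci["start"].reset_index(drop=True),
            loci["end"].reset_index(drop=True),
        )
        # build cluster spans from run bounds
        clusters = []
        for chrom, csub in loci.groupby("chrom", sort=False):
            csub = csub[sub.loc[csub["gene"], "sign"].to_numpy() != 0]
            arr = sub.loc[csub["gene"], "sign"].to_numpy()
            breaks = np.nonzero(arr[1:] != arr[:-1])[0] + 1
            bounds = np.concatenate([[0], breaks, [arr.size]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                clusters.append(
                    {
                        "chrom": chrom,
                        "start": int(csub["start"].iloc[a]),
                        "end": int(csub["end"].iloc[b - 1]),
                        "sign": int(arr[a]),
                    }
                )
        clusters = pd.DataFrame(clusters)
        rng = np.random.default_rng(3)
        rows = [
            ("chr1", int(s), int(s + 2_000))
            for s in rng.integers(1, 2_000_000, size=40)
        ]
        peaks = IntervalSet("p", pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        res = cluster_peak_enrichment(clusters, peaks)
        from zripple.genome import GeneMap, GENE_COLUMNS

        span_map = GeneMap(
            pd.DataFrame(
                [
                    (f"c{i}", r["chrom"], r["start"], r["end"], "+")
                    for i, r in clusters.iterrows()
                ],
                columns=GENE_COLUMNS,
            )
        )
        flags = span_map.gene_interval_overlap(peaks)
        signs = clusters["sign"].to_numpy()
        order = [f"c{i}" for i in range(len(clusters))]
        f = flags[order].to_numpy()
        assert res["plus_with_peak"] == int(np.sum((signs > 0) & f))
        assert res["minus_with_peak"] == int(np.sum((signs < 0) & f))


class TestScalarTrack:
    def test_track_equal_to_scores(self, clustered_study):
        *_, z_table = clustered_study
        s = z_series(z_table, "brain", "male")
        res = scalar_track_correlation(s, s)
        assert res.rho == pytest.approx(1.0)

    def test_coupled_tracks_signed(self, tree):
        from zripple.pipeline import compute_z_table
        from zripple.simulate import (
            SimConfig, generate_annotations, generate_gene_map,
            simulate_expression,
        )

        cfg = SimConfig(n_genes=800, n_chromosomes=3, seed=4, shift_prob=0.5,
                        shift_sd=1.5)
        gmap = generate_gene_map(cfg)
        ds, truth = simulate_expression(gmap, cfg)
        _, tracks = generate_annotations(gmap, truth, coupling=0.9, config=cfg)
        z_table = compute_z_table(ds, tree)
        s = z_series(z_table, "brain", "male")
        assert scalar_track_correlation(s, tracks["hmc"]).rho > 0
        assert scalar_track_correlation(s, tracks["mc"]).rho < 0
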