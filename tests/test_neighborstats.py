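"""Spatial statistics: correlations, runs, randomization machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zripple.genome import GENE_COLUMNS, GeneMap
from zripple.neighborstats import (
    bin_means,
    bonferroni,
    cluster_spectrum_test,
    distance_decay,
    empirical_p,
    large_cluster_excess,
    mann_whitney,
    neighbor_correlation,
    neighbor_pairs,
    run_edges,
    run_randomization_test,
    spearman,
    subset_mc,
)
from zripple.pipeline import z_series


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0, 20.0, 30.0, 31.0, 40.0, 41.0, 50.0])
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_matches_direct_rank_computation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle)
        assert res.p_value == pytest.approx(stats.spearmanr(x, y).pvalue, rel=1e-6)

    def test_exact_small_n_matches_enumeration(self):
        """Exact permutation P equals a brute-force enumeration via scipy."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 3.0, 9.0, 1.0])
        res = spearman(x, y)
        obs = stats.spearmanr(x, y).statistic
        hits = total = 0
        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, perm).statistic
            hits += abs(r) >= abs(obs) - 1e-12
            total += 1
        assert res.rho == pytest.approx(obs)
        assert res.p_value == pytest.approx(hits / total)

    def test_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.defined

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = spearman(x, y)
        b = spearman(np.exp(x), y**3)
        assert a.rho == pytest.approx(b.rho)


class TestMannWhitney:
    def test_identical_distributions_central(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    def test_disjoint_extreme(self):
        u, p = mann_whitney([10.0, 11.0, 12.0, 13.0, 14.0], [1.0, 2.0, 3.0, 4.0])
        assert u == 20.0
        assert p < 0.05

    def test_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=12)
        b = rng.normal(size=9)
        b[0] = a[0]  # plant a tie
        u, _ = mann_whitney(a, b)
        oracle = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        assert u == pytest.approx(oracle)


class TestEmpiricalP:
    def test_minimal_p_at_ten_thousand(self):
        assert empirical_p(0, 10_000) == pytest.approx(9.999e-05, rel=1e-4)

    def test_all_extreme_gives_one(self):
        assert empirical_p(10, 10) == 1.0

    def test_arithmetic(self):
        assert empirical_p(4, 9_999) == pytest.approx(5e-4)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            empirical_p(5, 4)

    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.2, 10) == 1.0
        assert bonferroni(0.001, 10) == pytest.approx(0.01)


class TestRunEdges:
    def test_worked_sequence(self):
        # +++-+++ has two edges and clusters of sizes 3, 1, 3
        signs = pd.Series([1, 1, 1, -1, 1, 1, 1])
        chroms = pd.Series(["chr1"] * 7)
        spec = run_edges(signs, chroms)
        assert spec.edge_count == 2
        assert sorted(spec.clusters["size"]) == [1, 3, 3]

    def test_uniform_sequence(self):
        spec = run_edges(pd.Series([1] * 9), pd.Series(["chr1"] * 9))
        assert spec.edge_count == 0
        assert list(spec.clusters["size"]) == [9]

    def test_zeros_removed_before_runs(self):
        spec = run_edges(pd.Series([1, 0, 1, -1, 0, -1]), pd.Series(["chr1"] * 6))
        assert spec.edge_count == 1
        assert spec.n_signed == 4

    def test_matches_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(6)
        signs = pd.Series(rng.choice([-1, 1], size=200))
        chroms = pd.Series(rng.choice(["chr1", "chr2", "chr3"], size=200))
        spec = run_edges(signs, chroms)
        oracle = 0
        for c in ("chr1", "chr2", "chr3"):
            arr = signs[chroms == c].tolist()
            oracle += sum(a != b for a, b in zip(arr, arr[1:]))
        assert spec.edge_count == oracle
        # cluster sizes sum to the signed gene count, per invariant
        assert spec.clusters["size"].sum() == spec.n_signed
        assert spec.edge_count == len(spec.clusters) - spec.n_chromosomes


class TestRunRandomization:
    def test_perfectly_clustered_minimal_p(self):
        signs = pd.Series([1] * 20 + [-1] * 20)
        chroms = pd.Series(["chr1"] * 40)
        mc, env, spec = run_randomization_test(signs, chroms, n_rand=400, seed=0)
        assert spec.edge_count == 1
        assert mc.empirical_p == pytest.approx(1 / 401)
        assert env.lower <= env.mean <= env.upper

    def test_randomization_preserves_counts(self):
        """Within-chromosome sign permutation is count-preserving by
        construction; the null mean must match the closed-form expectation
        for exchangeable signs."""
        rng = np.random.default_rng(7)
        n_pos, n_neg = 30, 10
        signs = pd.Series(rng.permutation([1] * n_pos + [-1] * n_neg))
        chroms = pd.Series(["chr1"] * (n_pos + n_neg))
        _, env, _ = run_randomization_test(signs, chroms, n_rand=3_000, seed=1)
        n = n_pos + n_neg
        expect = 2 * n_pos * n_neg / n  # E[edges] = (n-1) * 2 p+ p- (hypergeom.)
        assert env.mean == pytest.approx(expect * (n - 1) / n, rel=0.05)

    def test_agrees_with_naive_reimplementation(self):
        """Empirical P matches an independent loop-based randomization."""
        rng = np.random.default_rng(8)
        signs = pd.Series(rng.choice([1, -1], size=18))
        chroms = pd.Series(["chr1"] * 10 + ["chr2"] * 8)
        mc, _, spec = run_randomization_test(signs, chroms, n_rand=4_000, seed=2)
        hits = 0
        M = 4_000
        for _ in range(M):
            tot = 0
            for c in ("chr1", "chr2"):
                arr = rng.permutation(signs[chroms == c].to_numpy())
                tot += int(np.sum(arr[1:] != arr[:-1]))
            hits += tot <= spec.edge_count
        assert mc.empirical_p == pytest.approx((hits + 1) / (M + 1), abs=0.03)


class TestClusterSpectrum:
    def test_alternating_all_singletons(self):
        signs = pd.Series([1, -1] * 10)
        spec = run_edges(signs, pd.Series(["chr1"] * 20))
        assert (spec.clusters["size"] == 1).all()

    def test_size_count_conservation(self):
        rng = np.random.default_rng(9)
        signs = pd.Series(rng.choice([1, -1], size=100))
        chroms = pd.Series(["chr1"] * 50 + ["chr2"] * 50)
        table = cluster_spectrum_test(signs, chroms, n_rand=50, seed=0)
        assert (table["size"] * table["observed"]).sum() == 100

    def test_blocked_signal_exceeds_null_tail(self, clustered_study):
        cfg, gmap, _, _, z_table = clustered_study
        scores = z_series(z_table, "brain", "male")
        loci = gmap.loci[gmap.loci["gene"].isin(scores.index)]
        signs = pd.Series(
            np.sign(scores[loci["gene"]].to_numpy()).astype(int)
        )
        res = large_cluster_excess(
            signs, loci["chrom"].reset_index(drop=True), min_size=5,
            n_rand=300, seed=1,
        )
        assert res["observed"] > res["null_q975"]


class TestNeighborCorrelation:
    def test_window_mode_isolated_genes_undefined(self):
        records = [(f"g{i}", "chr1", 1 + i * 10**6, 1000 + i * 10**6, "+")
                   for i in range(5)]
        gmap = GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))
        scores = pd.Series([0.1, -0.2, 0.5, 0.0, 1.0],
                           index=[f"g{i}" for i in range(5)])
        res = neighbor_correlation(scores, gmap, mode="window")
        assert not res.defined

    def test_power_on_clustered_data(self, clustered_study):
        cfg, gmap, _, _, z_table = clustered_study
        scores = z_series(z_table, "brain", "male")
        for mode in ("downstream", "flank_pair", "window"):
            res = neighbor_correlation(scores, gmap, mode=mode)
            assert res.rho > 0
            assert res.p_value < 1e-3

    def test_overlapping_subset_disjoint_from_default(self, clustered_study):
        cfg, gmap, _, _, z_table = clustered_study
        scores = z_series(z_table, "brain", "male")
        a = neighbor_pairs(scores, gmap, mode="downstream", overlapping=False)
        b = neighbor_pairs(scores, gmap, mode="downstream", overlapping=True)
        assert set(a["focal"]).isdisjoint(set(b["focal"]))

    def test_fold_change_concordant_with_z(self, clustered_study):
        """Neighbor correlation on fold change is positive when it is on Z."""
        cfg, gmap, _, _, z_table = clustered_study
        sub = z_table[
            (z_table["tissue"] == "brain")
            & (z_table["sex"] == "male")
            & (~z_table["excluded"])
        ].set_index("gene")
        fold = sub["fold_change"].dropna()
        res_fold = neighbor_correlation(fold, gmap, mode="downstream")
        res_z = neighbor_correlation(sub["Z_mod"], gmap, mode="downstream")
        assert res_z.rho > 0
        assert res_fold.rho > 0


class TestBinMeans:
    def test_two_full_bins(self):
        rng = np.random.default_rng(10)
        f, n = rng.normal(size=1000), rng.normal(size=1000)
        table = bin_means(f, n, bin_size=500)
        assert len(table) == 2
        assert not table["partial"].any()

    def test_means_match_sorted_group_oracle(self):
        rng = np.random.default_rng(11)
        f, n = rng.normal(size=130), rng.normal(size=130)
        table = bin_means(f, n, bin_size=50)
        order = np.argsort(f, kind="stable")
        for b in range(3):
            idx = order[b * 50 : (b + 1) * 50]
            assert table.loc[b, "neighbor_mean"] == pytest.approx(n[idx].mean())
            assert table.loc[b, "focal_mean"] == pytest.approx(f[idx].mean())
        assert table.loc[2, "partial"]

    def test_sem_zero_for_constant_bin(self):
        f = np.arange(10, dtype=float)
        n = np.ones(10)
        table = bin_means(f, n, bin_size=5)
        assert (table["neighbor_sem"] == 0).all()


class TestSubsetMC:
    def test_whole_pool_gives_p_one(self):
        rng = np.random.default_rng(12)
        pairs = pd.DataFrame(
            {"focal_score": rng.normal(size=30), "neighbor_stat": rng.normal(size=30)}
        )
        mc, obs = subset_mc(pairs, pairs, n_draws=200, seed=0)
        assert mc.empirical_p == 1.0

    def test_planted_concordant_subset_small_p(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=400)
        noise = rng.normal(size=400)
        pairs = pd.DataFrame({"focal_score": x, "neighbor_stat": noise})
        subset = pd.DataFrame(
            {"focal_score": x[:80], "neighbor_stat": x[:80] + 0.3 * noise[:80]}
        )
        pool = pd.concat([pairs, subset], ignore_index=True)
        mc, obs = subset_mc(pool, subset, n_draws=400, seed=1)
        assert obs > 0.5
        assert mc.empirical_p < 0.01

    def test_oversized_subset_rejected(self):
        pairs = pd.DataFrame({"focal_score": [1.0, 2, 3], "neighbor_stat": [1.0, 2, 3]})
        big = pd.concat([pairs, pairs], ignore_index=True)
        with pytest.raises(ValueError):
            subset_mc(pairs, big, n_draws=10)


class TestDistanceDecay:
    def test_grid_must_increase(self, clustered_study):
        _, gmap, _, _, z_table = clustered_study
        scores = z_series(z_table, "brain", "male")
        with pytest.raises(ValueError):
            distance_decay(scores, gmap, [10, 10], n_rand=5)

    def test_oversized_min_gap_undefined(self, clustered_study):
        _, gmap, _, _, z_table = clustered_study
        scores = z_series(z_table, "brain", "male")
        profile = distance_decay(scores, gmap, [10**10], n_rand=5, seed=0)
        assert not profile.table["defined"].iloc[0]

    def test_blocked_data_exits_then_reenters_envelope(self, clustered_study):
        _, gmap, _, _, z_table = clustered_study
        scores = z_series(z_table, "brain", "male")
        profile = distance_decay(
            scores, gmap, [10_000, 5_000_000], n_rand=200, seed=0
        )
        short, far = profile.table.iloc[0], profile.table.iloc[1]
        assert short["rho"] > short["upper"]
        assert far["lower"] <= far["rho"] <= far["upper"]
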