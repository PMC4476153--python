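"""Cross-tissue concertedness, TSU genes, and chromatin-mark comparisons.

Works on a "wide" sign or Z table: genes x tissues for one sex (by default
the male tissues, which carry replicated samples).  A gene is *concerted*
when its Z sign agrees across all tissues (|Z sum| equals the tissue count);
*tissue-specific upregulated* (TSU) when Z > 1 in exactly one tissue and
below threshold elsewhere (strict: <= 0; relaxed: < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneMap, IntervalSet
from .neighborstats import CorrelationResult, empirical_p, spearman

__all__ = [
    "z_sum",
    "concerted_expectation",
    "zsum_distribution_test",
    "concerted_cluster_scan",
    "tsu_classify",
    "tsu_neighbor_test",
    "TwoCellCounts",
    "two_cell_chisq",
    "cluster_peak_enrichment",
    "scalar_track_correlation",
]


def z_sum(signs: pd.DataFrame) -> pd.Series:
    """Sum of per-tissue signs (+1/-1/0) per gene; zeros contribute 0."""
    arr = signs.to_numpy()
    if not np.isin(arr, (-1, 0, 1)).all():
        raise ValueError("signs must be in {-1, 0, +1}")
    return pd.Series(arr.sum(axis=1), index=signs.index, name="z_sum")


def concerted_expectation(
    proportions, n_genes: int
) -> tuple[float, float]:
    """Null expectation for fully concerted genes under tissue independence.

    ``proportions`` holds, per tissue, the proportion of genes with the sign
    of interest; the expected proportion of genes with that sign in *every*
    tissue is the product, and the expected count that proportion times the
    gene total.
    """
    p = np.asarray(list(proportions), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must be in [0, 1]")
    prop = float(np.prod(p))
    return prop, prop * n_genes


@dataclass
class ZSumTestResult:
    observed: pd.Series  # histogram over z_sum categories
    expected: pd.Series  # randomization-mean histogram (same categories)
    chi2: float
    df: int
    p_analytic: float
    p_empirical: float
    concerted_fold: float  # observed/expected at |z_sum| = n_tissues (summed)
    pooled: bool
    n_randomizations: int
    seed: int


def zsum_distribution_test(
    signs: pd.DataFrame, n_rand: int = 1_000, seed: int = 0
) -> ZSumTestResult:
    """Chi-square of the Z-sum histogram against a tissue-independence null.

    The null preserves the per-tissue totals of +, - and 0 by permuting each
    tissue's sign column independently.  The chi-square compares the observed
    histogram over the 2k+1 Z-sum categories with the randomization-mean
    expectation (cells with expectation < 5 are pooled into their neighbor
    toward zero); an empirical P compares the observed statistic against the
    same statistic of each randomization.
    """
    arr = signs.to_numpy()
    G, k = arr.shape
    cats = np.arange(-k, k + 1)
    obs_sum = arr.sum(axis=1)
    observed = np.bincount(obs_sum + k, minlength=2 * k + 1)

    rng = np.random.default_rng(seed)
    null_hist = np.zeros((n_rand, 2 * k + 1), dtype=np.int64)
    for r in range(n_rand):
        total = np.zeros(G, dtype=np.int64)
        for j in range(k):
            total += rng.permutation(arr[:, j])
        null_hist[r] = np.bincount(total + k, minlength=2 * k + 1)
    expected = null_hist.mean(axis=0)

    # pool sparse extreme cells toward the centre so expectations stay >= 5
    order = np.argsort(np.abs(cats), kind="stable")[::-1]  # extremes first
    pool_map = np.arange(cats.size)
    pooled = False
    exp_work = expected.copy()
    for idx in order:
        if exp_work[idx] < 5 and cats[idx] != 0:
            step = -1 if cats[idx] > 0 else 1
            target = idx + step
            exp_work[target] += exp_work[idx]
            exp_work[idx] = 0
            pool_map[pool_map == idx] = target
            pooled = True

    def pooled_hist(h):
        out = np.zeros(cats.size)
        np.add.at(out, pool_map, h)
        return out[exp_work > 0]

    exp_p = exp_work[exp_work > 0]
    obs_p = pooled_hist(observed)
    chi2 = float(((obs_p - exp_p) ** 2 / exp_p).sum())
    df = exp_p.size - 1
    p_analytic = float(stats.chi2.sf(chi2, df))
    null_chi2 = np.array(
        [((pooled_hist(h) - exp_p) ** 2 / exp_p).sum() for h in null_hist]
    )
    N = int(np.count_nonzero(null_chi2 >= chi2))
    p_emp = empirical_p(N, n_rand)

    extreme = np.abs(cats) == k
    fold = float(observed[extreme].sum() / max(expected[extreme].sum(), 1e-300))
    return ZSumTestResult(
        pd.Series(observed, index=cats),
        pd.Series(expected, index=cats),
        chi2,
        df,
        p_analytic,
        p_emp,
        fold,
        pooled,
        n_rand,
        seed,
    )


def concerted_cluster_scan(
    flags: pd.Series,
    chroms: pd.Series,
    n_rand: int = 10_000,
    seed: int = 0,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Clusters of adjacent same-sign concerted genes vs randomized order.

    ``flags`` is +1 (concerted positive), -1 (concerted negative) or 0
    (anything else) in map order; a cluster is a maximal run of >= 2 adjacent
    equal non-zero flags, broken by any intervening non-concerted gene and at
    chromosome boundaries.  Positions are permuted within chromosomes,
    preserving the number of concerted genes of each sign; per (sign, size)
    the empirical P counts randomizations with as many or more clusters of
    that size, P = (N+1)/(M+1).
    """
    flags_arr = flags.to_numpy()
    df = pd.DataFrame({"flag": flags_arr, "chrom": chroms.to_numpy()})
    groups = [sub["flag"].to_numpy() for _, sub in df.groupby("chrom", sort=False)]

    def count_clusters(arrs) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for arr in arrs:
            if arr.size == 0:
                continue
            change = np.ones(arr.size + 1, dtype=bool)
            change[1:-1] = arr[1:] != arr[:-1]
            bounds = np.nonzero(change)[0]
            for a, b in zip(bounds[:-1], bounds[1:]):
                if arr[a] != 0 and b - a >= 2:
                    key = (int(arr[a]), int(b - a))
                    counts[key] = counts.get(key, 0) + 1
        return counts

    observed = count_clusters(groups)
    rng = np.random.default_rng(seed)
    top = max_size or max((s for _, s in observed), default=2)
    keys = [(sign, size) for sign in (1, -1) for size in range(2, top + 1)]
    n_ge = {key: 0 for key in keys}
    null_sum = {key: 0.0 for key in keys}
    for _ in range(n_rand):
        perm_groups = [rng.permutation(arr) for arr in groups]
        counts = count_clusters(perm_groups)
        for key in keys:
            c = counts.get(key, 0)
            null_sum[key] += c
            if c >= observed.get(key, 0):
                n_ge[key] += 1
    rows = [
        {
            "sign": sign,
            "size": size,
            "observed": observed.get((sign, size), 0),
            "null_mean": null_sum[(sign, size)] / n_rand,
            "empirical_p": empirical_p(n_ge[(sign, size)], n_rand),
        }
        for sign, size in keys
    ]
    return pd.DataFrame(rows)


def tsu_classify(z_wide: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Strict and relaxed tissue-specific upregulation flags per gene.

    strict: Z > threshold in exactly one tissue and Z <= 0 in all others;
    relaxed: Z > threshold in exactly one tissue and Z < threshold elsewhere.
    Strict implies relaxed.  Columns: focal_tissue, strict, relaxed.
    """
    arr = z_wide.to_numpy()
    above = arr > threshold
    one_high = above.sum(axis=1) == 1
    focal_idx = above.argmax(axis=1)
    others_nonpos = np.array(
        [np.all(np.delete(row, i) <= 0) for row, i in zip(arr, focal_idx)]
    )
    relaxed = one_high
    strict = one_high & others_nonpos
    focal = np.where(one_high, np.asarray(z_wide.columns)[focal_idx], None)
    return pd.DataFrame(
        {"focal_tissue": focal, "strict": strict, "relaxed": relaxed},
        index=z_wide.index,
    )


@dataclass
class TSUNeighborResult:
    per_tissue: pd.DataFrame  # tissue, n, observed, expected, chi2, p
    chi2: float
    df: int
    p_value: float
    fisher_stat: float
    fisher_df: int
    fisher_p: float
    proximity: str  # "near" (<= max_gap) or "far" (> max_gap)


def _nearest_neighbor_table(gmap: GeneMap) -> pd.DataFrame:
    """Nearest gene (either side, by body distance) per focal gene."""
    rows = []
    for chrom, sub in gmap.loci.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        genes = sub["gene"].to_numpy()
        n = len(sub)
        for i in range(n):
            best = None
            for j in (i - 1, i + 1):
                if 0 <= j < n:
                    if starts[max(i, j)] > ends[min(i, j)]:
                        d = int(starts[max(i, j)] - ends[min(i, j)] - 1)
                    else:
                        d = 0
                    if best is None or d < best[1]:
                        best = (genes[j], d)
            if best is not None:
                rows.append((genes[i], best[0], best[1]))
    return pd.DataFrame(rows, columns=["gene", "neighbor", "distance"])


def tsu_neighbor_test(
    z_wide: pd.DataFrame,
    gmap: GeneMap,
    max_gap: int = 100_000,
    relaxed: bool = True,
    proximity: str = "near",
    threshold: float = 1.0,
) -> TSUNeighborResult:
    """Do TSU genes sit next to genes upregulated in the same tissue?

    For each tissue, the observed count of TSU genes whose nearest neighbor
    (closer flank by body distance, restricted to the <=/& > ``max_gap``
    proximity class) has Z > 0 in the focal tissue is compared with the
    expectation from that tissue's genome-wide proportion of Z > 0 genes
    (genes with sign 0 excluded from the proportion).  Per-tissue two-cell
    chi-square contributions are summed (df = tissues - 1) and the
    per-tissue P values combined by Fisher's method (df = 2k).
    """
    tsu = tsu_classify(z_wide, threshold=threshold)
    flag_col = "relaxed" if relaxed else "strict"
    nn = _nearest_neighbor_table(gmap).set_index("gene")
    rows = []
    chi2_total = 0.0
    fisher = 0.0
    used = 0
    for tissue in z_wide.columns:
        z_t = z_wide[tissue].dropna()
        z_t = z_t[np.isfinite(z_t)]
        nonzero = z_t[z_t != 0]
        if nonzero.empty:
            continue
        p_plus = float((nonzero > 0).mean())
        focal = tsu.index[(tsu[flag_col]) & (tsu["focal_tissue"] == tissue)]
        focal = [g for g in focal if g in nn.index]
        sel = []
        for g in focal:
            d = nn.loc[g, "distance"]
            near = d <= max_gap
            if (proximity == "near") == near and nn.loc[g, "neighbor"] in nonzero.index:
                sel.append(g)
        n_t = len(sel)
        if n_t == 0:
            continue  # excluded from df, logged in the output table
        obs = int(sum(nonzero[nn.loc[g, "neighbor"]] > 0 for g in sel))
        exp = n_t * p_plus
        exp_neg = n_t - exp
        contrib = 0.0
        if exp > 0:
            contrib += (obs - exp) ** 2 / exp
        if exp_neg > 0:
            contrib += ((n_t - obs) - exp_neg) ** 2 / exp_neg
        p_t = float(stats.chi2.sf(contrib, 1))
        chi2_total += contrib
        fisher += -2.0 * np.log(max(p_t, 1e-300))
        used += 1
        rows.append(
            {
                "tissue": tissue,
                "n": n_t,
                "observed": obs,
                "expected": exp,
                "chi2": contrib,
                "p_value": p_t,
            }
        )
    per_tissue = pd.DataFrame(rows)
    df_total = max(used - 1, 1)
    return TSUNeighborResult(
        per_tissue=per_tissue,
        chi2=chi2_total,
        df=df_total,
        p_value=float(stats.chi2.sf(chi2_total, df_total)),
        fisher_stat=fisher,
        fisher_df=2 * used,
        fisher_p=float(stats.chi2.sf(fisher, 2 * used)) if used else float("nan"),
        proximity=proximity,
    )


@dataclass(frozen=True)
class TwoCellCounts:
    N_plus: float
    N_minus: float
    O_plus: float
    O_minus: float
    E_plus: float
    E_minus: float
    chi2: float
    df: int
    p_value: float


def two_cell_chisq(
    n_plus: float, n_minus: float, o_plus: float, o_minus: float
) -> TwoCellCounts:
    """Two-cell chi-square of peak overlap between Z+ and Z- genes.

    ``o_plus``/``o_minus`` are the (possibly replicate-averaged, hence
    fractional) counts of Z+/Z- genes overlapping >= 1 peak.  Expectations
    split the overlap total by the Z+/Z- margin:
    ``E+ = N+ * (O+ + O-) / (N+ + N-)``; the statistic sums (O-E)^2/E over
    the two overlap cells only, df = 1.
    """
    if min(n_plus, n_minus, o_plus, o_minus) < 0:
        raise ValueError("counts must be non-negative")
    if o_plus > n_plus or o_minus > n_minus:
        raise ValueError("overlap counts cannot exceed gene counts")
    total_overlap = o_plus + o_minus
    total_genes = n_plus + n_minus
    if total_genes == 0:
        raise ValueError("no genes")
    e_plus = n_plus * total_overlap / total_genes
    e_minus = n_minus * total_overlap / total_genes
    if e_plus == 0 or e_minus == 0:
        raise ValueError("zero expectation in a cell")
    chi2 = (o_plus - e_plus) ** 2 / e_plus + (o_minus - e_minus) ** 2 / e_minus
    return TwoCellCounts(
        n_plus, n_minus, o_plus, o_minus, e_plus, e_minus,
        float(chi2), 1, float(stats.chi2.sf(chi2, 1)),
    )


def cluster_peak_enrichment(
    clusters: pd.DataFrame, peaks: IntervalSet
) -> dict:
    """2x2 chi-square of cluster sign x >=1 overlapping peak.

    ``clusters`` needs chrom/start/end/sign columns (spans of same-sign Z
    runs, 1-based inclusive); the flag per cluster marks overlap with at
    least one peak interval.
    """
    if clusters.empty:
        return {"defined": False}
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s) + 1, int(e) + 1) for s, e in zip(sub["start"], sub["end"])
        )
    flags = []
    for _, row in clusters.iterrows():
        tree = trees.get(row["chrom"])
        flags.append(
            bool(tree is not None and tree.overlap(int(row["start"]), int(row["end"]) + 1))
        )
    flags = np.asarray(flags)
    sign = clusters["sign"].to_numpy()
    table = np.array(
        [
            [np.sum((sign > 0) & flags), np.sum((sign > 0) & ~flags)],
            [np.sum((sign < 0) & flags), np.sum((sign < 0) & ~flags)],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return {"defined": False, "table": table}
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {
        "defined": True,
        "table": table,
        "chi2": float(chi2),
        "df": int(dof),
        "p_value": float(p),
        "plus_with_peak": int(table[0, 0]),
        "minus_with_peak": int(table[1, 0]),
    }


def scalar_track_correlation(
    scores: pd.Series, track: pd.Series
) -> CorrelationResult:
    """Spearman of per-gene scores vs a scalar annotation track."""
    joined = pd.concat([scores.rename("z"), track.rename("track")], axis=1).dropna()
    joined = joined[np.isfinite(joined["z"]) & np.isfinite(joined["track"])]
    if len(joined) < 3:
        return CorrelationResult(float("nan"), float("nan"), len(joined), defined=False)
    return spearman(joined["z"].to_numpy(), joined["track"].to_numpy())
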