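"""Spatial statistics of per-gene scores along the genome.

The per-gene score is usually the median-corrected divergence Z, but every
routine here is agnostic: it takes a gene-indexed Series of scores and a
:class:`~zripple.genome.GeneMap`.  Core facilities:

* neighbor correlations in three modes (nearest downstream, the mean of the
  two flanks, the mean of all neighbors within a radius), with the
  non-overlap filters applied per mode;
* sign-run ("edge") statistics along each chromosome with a within-chromosome
  permutation null that preserves the per-chromosome +/- counts;
* cluster-size spectra versus randomized sets;
* distance-decay correlograms (rho of focal vs nearest downstream gene at a
  minimum distance x, over a grid of x) with 1.96 SD randomization envelopes;
* Monte Carlo subset comparisons and the unbiased empirical P = (N+1)/(M+1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneMap

__all__ = [
    "CorrelationResult",
    "RunSpectrum",
    "NullEnvelope",
    "MonteCarloResult",
    "spearman",
    "neighbor_pairs",
    "neighbor_correlation",
    "bin_means",
    "run_edges",
    "run_randomization_test",
    "cluster_spectrum_test",
    "distance_decay",
    "subset_mc",
    "empirical_p",
    "mann_whitney",
    "bonferroni",
]

EXACT_PERMUTATION_MAX_N = 10  # exact Spearman P up to here, t approximation above


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True
    bonferroni_adjusted: bool = False


@dataclass(frozen=True)
class NullEnvelope:
    n_randomizations: int
    mean: float
    sd: float
    seed: int | None = None

    @property
    def lower(self) -> float:
        return self.mean - 1.96 * self.sd

    @property
    def upper(self) -> float:
        return self.mean + 1.96 * self.sd


@dataclass(frozen=True)
class MonteCarloResult:
    """N as-or-more-extreme null statistics out of M; P = (N+1)/(M+1)."""

    N: int
    M: int
    direction: str = "greater"
    seed: int | None = None

    @property
    def empirical_p(self) -> float:
        return empirical_p(self.N, self.M)


@dataclass
class RunSpectrum:
    """Sign-run structure of per-chromosome +/-1 sequences (zeros removed)."""

    edge_count: int
    clusters: pd.DataFrame  # chrom, sign, size, span_bp
    n_signed: int
    n_chromosomes: int


def empirical_p(N: int, M: int) -> float:
    """Unbiased Monte Carlo type-I error estimate (N + 1) / (M + 1)."""
    if M < 1 or not 0 <= N <= M:
        raise ValueError("need 0 <= N <= M and M >= 1")
    return (N + 1) / (M + 1)


def bonferroni(p: float, m: int) -> float:
    """Family-wise adjusted P = min(1, m * p)."""
    return min(1.0, m * p)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float((xc @ yc) / denom)


def spearman(x, y) -> CorrelationResult:
    """Spearman rho with average ranks; exact permutation P for n <= 10,
    two-sided t approximation above.  Constant input flags the result
    undefined rather than raising."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    if np.isnan(rho):
        return CorrelationResult(float("nan"), float("nan"), n, defined=False)
    if n <= EXACT_PERMUTATION_MAX_N:
        rxc = rx - rx.mean()
        denom_x = rxc @ rxc
        hits = total = 0
        perm_iter = itertools.permutations(ry)
        while True:
            chunk = np.array(list(itertools.islice(perm_iter, 100_000)), dtype=float)
            if chunk.size == 0:
                break
            pc = chunk - ry.mean()
            rho_null = (pc @ rxc) / np.sqrt(denom_x * (pc * pc).sum(axis=1))
            hits += int(np.count_nonzero(np.abs(rho_null) >= abs(rho) - 1e-12))
            total += chunk.shape[0]
        p = hits / total
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n)


def mann_whitney(a, b) -> tuple[float, float]:
    """Rank-sum U with normal approximation and tie correction, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# -- neighbor correlations ----------------------------------------------------


def neighbor_pairs(
    scores: pd.Series,
    gmap: GeneMap,
    mode: str = "downstream",
    max_gap: int = 100_000,
    convention: str = "body_gap",
    overlapping: bool = False,
) -> pd.DataFrame:
    """(focal score, neighbor statistic) pairs for one analysis mode.

    ``scores`` holds the per-gene values to correlate; genes absent from it
    (e.g. excluded zero-Z genes) can be neither focal genes nor neighbors.

    downstream: nearest downstream neighbor; only non-overlapping pairs by
    default (``overlapping=True`` selects exactly the overlapping ones, the
    comparison set used for the overlapping-gene analyses).
    flank_pair: mean score of the two nearest non-overlapping flanks, both
    within ``max_gap``.
    window: mean score of all neighbors within ``max_gap``; focal genes that
    overlap an adjacent gene are removed, overlapping non-focal neighbors
    are retained.

    Columns: focal, focal_score, neighbor_stat, n_neighbors, and for
    downstream mode also orientation, gap_bp, start_to_start_bp.
    """
    scored = scores.dropna()
    scored = scored[np.isfinite(scored)]
    have = set(scored.index)
    if mode == "downstream":
        table = gmap.nearest_downstream_table(max_gap=max_gap, convention=convention)
        table = table[table["overlapping"] == overlapping]
        table = table[table["focal"].isin(have) & table["neighbor"].isin(have)]
        return pd.DataFrame(
            {
                "focal": table["focal"].to_numpy(),
                "focal_score": scored[table["focal"]].to_numpy(),
                "neighbor_stat": scored[table["neighbor"]].to_numpy(),
                "n_neighbors": 1,
                "orientation": table["orientation"].to_numpy(),
                "gap_bp": table["gap_bp"].to_numpy(),
                "start_to_start_bp": table["start_to_start_bp"].to_numpy(),
            }
        )
    if mode == "flank_pair":
        rows = []
        for gene in scored.index:
            flanks = gmap.flanking_pair(gene, max_gap=max_gap, convention=convention)
            if flanks is None:
                continue
            up, down = flanks
            if up.overlapping or down.overlapping:
                if not overlapping:
                    continue
            elif overlapping:
                continue
            names = [up.focal, down.neighbor]
            if not all(n in have for n in names):
                continue
            rows.append(
                (gene, scored[gene], float(np.mean([scored[n] for n in names])), 2)
            )
        return pd.DataFrame(
            rows, columns=["focal", "focal_score", "neighbor_stat", "n_neighbors"]
        )
    if mode == "window":
        overlaps_adj = gmap.overlaps_adjacent()
        sets = gmap.neighbor_sets_within(max_gap)
        rows = []
        for gene in scored.index:
            if overlaps_adj.get(gene, False):
                continue
            neigh = [n for n in sets.get(gene, []) if n in have]
            if not neigh:
                continue
            rows.append(
                (gene, scored[gene], float(scored[neigh].mean()), len(neigh))
            )
        return pd.DataFrame(
            rows, columns=["focal", "focal_score", "neighbor_stat", "n_neighbors"]
        )
    raise ValueError(f"unknown mode {mode!r}")


def neighbor_correlation(
    scores: pd.Series,
    gmap: GeneMap,
    mode: str = "downstream",
    max_gap: int = 100_000,
    convention: str = "body_gap",
    overlapping: bool = False,
) -> CorrelationResult:
    """Spearman correlation of focal score vs neighbor statistic for a mode."""
    pairs = neighbor_pairs(
        scores, gmap, mode=mode, max_gap=max_gap, convention=convention,
        overlapping=overlapping,
    )
    if len(pairs) < 3:
        return CorrelationResult(float("nan"), float("nan"), len(pairs), defined=False)
    return spearman(pairs["focal_score"].to_numpy(), pairs["neighbor_stat"].to_numpy())


def bin_means(
    focal: np.ndarray, neighbor: np.ndarray, bin_size: int = 500
) -> pd.DataFrame:
    """Equal-size bins by focal-score rank; last partial bin kept and flagged.

    Returns per-bin mean focal score, mean and SEM of the neighbor statistic.
    """
    focal = np.asarray(focal, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    order = np.argsort(focal, kind="stable")
    rows = []
    for start in range(0, focal.size, bin_size):
        idx = order[start : start + bin_size]
        nb = neighbor[idx]
        sem = float(nb.std(ddof=1) / np.sqrt(idx.size)) if idx.size > 1 else 0.0
        rows.append(
            {
                "bin": start // bin_size,
                "n": idx.size,
                "focal_mean": float(focal[idx].mean()),
                "neighbor_mean": float(nb.mean()),
                "neighbor_sem": sem,
                "partial": idx.size < bin_size,
            }
        )
    return pd.DataFrame(rows)


# -- sign runs ----------------------------------------------------------------


def _chrom_sign_arrays(signs: pd.Series, chroms: pd.Series) -> dict[str, np.ndarray]:
    """Per-chromosome +/-1 arrays in map order, zeros removed."""
    df = pd.DataFrame({"sign": signs.to_numpy(), "chrom": chroms.to_numpy()})
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = sub["sign"].to_numpy()
        arr = arr[arr != 0]
        if arr.size:
            out[chrom] = arr.astype(np.int8)
    return out


def _edges(arr: np.ndarray) -> int:
    return int(np.count_nonzero(arr[1:] != arr[:-1]))


def run_edges(
    signs: pd.Series,
    chroms: pd.Series,
    starts: pd.Series | None = None,
    ends: pd.Series | None = None,
) -> RunSpectrum:
    """Edge count and cluster sizes/spans of the per-chromosome sign runs.

    ``signs`` are +1/-1/0 in map order; zeros ("too indecisive") are removed
    before runs are formed.  An edge is an adjacent unequal pair; a cluster
    is a maximal same-sign run.  Genomic spans (first start to last end of
    the run) are attached when coordinates are provided.
    """
    pos = None
    if starts is not None and ends is not None:
        pos = pd.DataFrame(
            {
                "chrom": chroms.to_numpy(),
                "sign": signs.to_numpy(),
                "start": starts.to_numpy(),
                "end": ends.to_numpy(),
            }
        )
    arrays = _chrom_sign_arrays(signs, chroms)
    total_edges = 0
    rows = []
    for chrom, arr in arrays.items():
        total_edges += _edges(arr)
        breaks = np.nonzero(arr[1:] != arr[:-1])[0] + 1
        bounds = np.concatenate([[0], breaks, [arr.size]])
        spans = None
        if pos is not None:
            sub = pos[pos["chrom"] == chrom]
            sub = sub[sub["sign"] != 0]
            spans = (sub["start"].to_numpy(), sub["end"].to_numpy())
        for a, b in zip(bounds[:-1], bounds[1:]):
            span_bp = (
                int(spans[1][b - 1] - spans[0][a] + 1) if spans is not None else -1
            )
            rows.append((chrom, int(arr[a]), int(b - a), span_bp))
    clusters = pd.DataFrame(rows, columns=["chrom", "sign", "size", "span_bp"])
    n_signed = int(sum(arr.size for arr in arrays.values()))
    return RunSpectrum(total_edges, clusters, n_signed, len(arrays))


def _permuted_edge_counts(
    arrays: dict[str, np.ndarray], n_rand: int, rng
) -> np.ndarray:
    """Total edge count for n_rand within-chromosome sign permutations."""
    totals = np.zeros(n_rand, dtype=np.int64)
    for arr in arrays.values():
        tiled = np.tile(arr, (n_rand, 1))
        perm = rng.permuted(tiled, axis=1)
        totals += np.count_nonzero(perm[:, 1:] != perm[:, :-1], axis=1)
    return totals


def run_randomization_test(
    signs: pd.Series,
    chroms: pd.Series,
    n_rand: int = 10_000,
    seed: int = 0,
) -> tuple[MonteCarloResult, NullEnvelope, RunSpectrum]:
    """Permutation test for fewer run edges than expected (clustering).

    Signs are permuted within each chromosome, preserving the per-chromosome
    +/- counts exactly; the statistic is the genome-wide total edge count and
    the test is one-tailed for a deficit of edges.
    """
    spectrum = run_edges(signs, chroms)
    arrays = _chrom_sign_arrays(signs, chroms)
    rng = np.random.default_rng(seed)
    totals = _permuted_edge_counts(arrays, n_rand, rng)
    N = int(np.count_nonzero(totals <= spectrum.edge_count))
    mc = MonteCarloResult(N, n_rand, direction="fewer_edges", seed=seed)
    env = NullEnvelope(n_rand, float(totals.mean()), float(totals.std(ddof=0)), seed)
    return mc, env, spectrum


def cluster_spectrum_test(
    signs: pd.Series,
    chroms: pd.Series,
    n_rand: int = 1_000,
    seed: int = 0,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Observed cluster-size counts vs within-chromosome randomization nulls.

    For each cluster size the empirical P counts randomizations with as many
    or more clusters of that size, P = (N+1)/(M+1).  Null quartiles support
    boxplot-style summaries.
    """
    spectrum = run_edges(signs, chroms)
    observed = spectrum.clusters.groupby("size").size()
    arrays = _chrom_sign_arrays(signs, chroms)
    rng = np.random.default_rng(seed)
    top = max_size or (int(observed.index.max()) if len(observed) else 1)
    sizes = np.arange(1, top + 1)
    null_counts = np.zeros((n_rand, sizes.size), dtype=np.int64)
    for arr in arrays.values():
        tiled = np.tile(arr, (n_rand, 1))
        perm = rng.permuted(tiled, axis=1)
        change = np.ones((n_rand, arr.size + 1), dtype=bool)
        change[:, 1:-1] = perm[:, 1:] != perm[:, :-1]
        for r in range(n_rand):
            bounds = np.nonzero(change[r])[0]
            lens = np.diff(bounds)
            lens = lens[lens <= top]
            if lens.size:
                null_counts[r] += np.bincount(lens, minlength=top + 1)[1:]
    obs = np.array([observed.get(s, 0) for s in sizes])
    N = (null_counts >= obs).sum(axis=0)
    rows = pd.DataFrame(
        {
            "size": sizes,
            "observed": obs,
            "null_mean": null_counts.mean(axis=0),
            "null_q025": np.quantile(null_counts, 0.025, axis=0),
            "null_q975": np.quantile(null_counts, 0.975, axis=0),
            "empirical_p": (N + 1) / (n_rand + 1),
        }
    )
    return rows


def large_cluster_excess(
    signs: pd.Series,
    chroms: pd.Series,
    min_size: int = 5,
    n_rand: int = 1_000,
    seed: int = 0,
) -> dict:
    """Observed count of sign clusters of size >= min_size vs the null tail.

    Uses the same within-chromosome permutation null as the spectrum test;
    reports the null 97.5th percentile of the tail count and the one-tailed
    empirical P for an excess.
    """
    spectrum = run_edges(signs, chroms)
    observed = int((spectrum.clusters["size"] >= min_size).sum())
    arrays = _chrom_sign_arrays(signs, chroms)
    rng = np.random.default_rng(seed)
    tail = np.zeros(n_rand, dtype=np.int64)
    for arr in arrays.values():
        tiled = np.tile(arr, (n_rand, 1))
        perm = rng.permuted(tiled, axis=1)
        change = np.ones((n_rand, arr.size + 1), dtype=bool)
        change[:, 1:-1] = perm[:, 1:] != perm[:, :-1]
        for r in range(n_rand):
            lens = np.diff(np.nonzero(change[r])[0])
            tail[r] += int((lens >= min_size).sum())
    N = int(np.count_nonzero(tail >= observed))
    return {
        "observed": observed,
        "null_q975": float(np.quantile(tail, 0.975)),
        "null_mean": float(tail.mean()),
        "empirical_p": empirical_p(N, n_rand),
    }


# -- distance decay -----------------------------------------------------------


@dataclass
class DecayProfile:
    table: pd.DataFrame  # min_gap, rho, p_value, n, null_mean, lower, upper
    n_randomizations: int
    seed: int
    shuffle: str = "genome"


def _decay_pairs(
    scored: pd.Series, gmap: GeneMap, min_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (focal, nearest downstream scored gene >= min_gap away)."""
    loci = gmap.loci[gmap.loci["gene"].isin(scored.index)]
    out_i, out_j = [], []
    offset = 0
    for chrom, sub in loci.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # nearest downstream body >= min_gap away: smallest start >= end + gap + 1
        targets = np.searchsorted(starts, ends + min_gap + 1, side="left")
        ok = targets < starts.size
        out_i.append(np.nonzero(ok)[0] + offset)
        out_j.append(targets[ok] + offset)
        offset += starts.size
    return np.concatenate(out_i), np.concatenate(out_j)


def distance_decay(
    scores: pd.Series,
    gmap: GeneMap,
    min_gaps,
    n_rand: int = 1_000,
    seed: int = 0,
    shuffle: str = "genome",
) -> DecayProfile:
    """Correlation of focal vs nearest downstream gene at minimum distance x.

    For each grid value x the nearest downstream scored gene at body distance
    >= x pairs with each focal gene; the Spearman rho over those pairs is
    compared with a mean +/- 1.96 SD envelope from ``n_rand`` shufflings of
    the scores over loci (genome-wide by default, within chromosomes with
    ``shuffle="chromosome"``).
    """
    min_gaps = list(min_gaps)
    if any(b <= a for a, b in zip(min_gaps, min_gaps[1:])):
        raise ValueError("min_gaps grid must be strictly increasing")
    scored = scores.dropna()
    scored = scored[np.isfinite(scored)]
    loci = gmap.loci[gmap.loci["gene"].isin(scored.index)]
    values = scored[loci["gene"]].to_numpy()
    chrom_codes = pd.factorize(loci["chrom"].to_numpy())[0]
    rng = np.random.default_rng(seed)

    pair_idx = {x: _decay_pairs(scored, gmap, x) for x in min_gaps}
    rows = []
    null_rhos = {x: [] for x in min_gaps}
    perms = []
    for _ in range(n_rand):
        if shuffle == "genome":
            perm = rng.permutation(values.size)
        elif shuffle == "chromosome":
            perm = np.arange(values.size)
            for c in np.unique(chrom_codes):
                idx = np.nonzero(chrom_codes == c)[0]
                perm[idx] = idx[rng.permutation(idx.size)]
        else:
            raise ValueError(f"unknown shuffle mode {shuffle!r}")
        perms.append(perm)

    for x in min_gaps:
        i, j = pair_idx[x]
        if i.size < 3:
            rows.append(
                {
                    "min_gap": x,
                    "rho": float("nan"),
                    "p_value": float("nan"),
                    "n": int(i.size),
                    "null_mean": float("nan"),
                    "lower": float("nan"),
                    "upper": float("nan"),
                    "defined": False,
                }
            )
            continue
        res = spearman(values[i], values[j])
        for perm in perms:
            pv = values[perm]
            rx, ry = _rank(pv[i]), _rank(pv[j])
            null_rhos[x].append(_pearson(rx, ry))
        null = np.asarray(null_rhos[x])
        rows.append(
            {
                "min_gap": x,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "null_mean": float(null.mean()),
                "lower": float(null.mean() - 1.96 * null.std(ddof=0)),
                "upper": float(null.mean() + 1.96 * null.std(ddof=0)),
                "defined": True,
            }
        )
    return DecayProfile(pd.DataFrame(rows), n_rand, seed, shuffle)


# -- Monte Carlo subset comparison -------------------------------------------


def subset_mc(
    pairs: pd.DataFrame,
    subset: pd.DataFrame,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[MonteCarloResult, float]:
    """Is the subset's rho higher than random equal-size subsets of the pool?

    ``pairs`` is the pool of (focal_score, neighbor_stat) rows and ``subset``
    a frame of the same columns whose rho is the observed statistic.
    One-tailed "greater": N counts draws with rho >= observed.
    """
    pool_f = pairs["focal_score"].to_numpy(dtype=float)
    pool_n = pairs["neighbor_stat"].to_numpy(dtype=float)
    k = len(subset)
    if k > len(pairs):
        raise ValueError("subset larger than pool")
    obs = spearman(
        subset["focal_score"].to_numpy(dtype=float),
        subset["neighbor_stat"].to_numpy(dtype=float),
    ).rho
    rng = np.random.default_rng(seed)
    N = 0
    for _ in range(n_draws):
        idx = rng.choice(len(pairs), size=k, replace=False)
        rx, ry = _rank(pool_f[idx]), _rank(pool_n[idx])
        if _pearson(rx, ry) >= obs - 1e-12:
            N += 1
    return MonteCarloResult(N, n_draws, direction="greater", seed=seed), obs
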