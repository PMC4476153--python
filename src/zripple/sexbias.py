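"""Change in sex bias of expression evolution via SMA residuals.

Male and female divergence scores for the same tissue are strongly
correlated; the standard-major-axis (SMA, "orthogonal") line between them is
the no-change-in-sex-bias expectation, and a gene's standardized residual
from that line measures how much its expression change differs between the
sexes.  The residual plays the same role Z does in the spatial statistics:
neighbor correlations, run tests, decay profiles and X-vs-autosome
comparisons all accept it unchanged.

The emitted residual is the vertical deviation standardized to unit SD; the
signed orthogonal distance is the same quantity divided by sqrt(1 + slope^2),
so the two are identical after standardization and for every rank-based
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneMap
from .neighborstats import (
    CorrelationResult,
    neighbor_correlation,
    run_randomization_test,
    mann_whitney,
)

__all__ = [
    "SMAFit",
    "sma_fit",
    "standardized_residuals",
    "residual_clustering",
    "x_chromosome_tests",
]


@dataclass(frozen=True)
class SMAFit:
    slope: float
    intercept: float
    r: float  # Pearson correlation, carries the slope sign
    n: int


def sma_fit(x, y) -> SMAFit:
    """Standard major axis line: slope = sign(r) * SD(y)/SD(x), through the
    centroid.  Symmetric: swapping x and y inverts the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("constant input: SMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    return SMAFit(float(slope), intercept, r, int(x.size))


def standardized_residuals(
    fit: SMAFit, x, y, orthogonal: bool = False
) -> pd.DataFrame:
    """Signed deviations from the SMA line, standardized to unit SD.

    Columns: residual (vertical, or orthogonal distance with the flag),
    standardized, modulus.  The standardized values are identical under
    either flag (the orthogonal distance is the vertical one scaled by a
    constant).
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    resid = y - (fit.intercept + fit.slope * x)
    if orthogonal:
        resid = resid / math.sqrt(1.0 + fit.slope**2)
    sd = resid.std(ddof=1)
    standardized = resid / sd if sd > 0 else resid * 0.0
    return pd.DataFrame(
        {
            "residual": resid,
            "standardized": standardized,
            "modulus": standardized.abs(),
        }
    )


def residual_clustering(
    residuals: pd.Series,
    gmap: GeneMap,
    max_gap: int = 100_000,
    n_rand: int = 1_000,
    seed: int = 0,
) -> dict:
    """Neighbor correlations (all three modes) and the sign-run test, with
    standardized residuals in place of Z."""
    out: dict[str, object] = {}
    for mode in ("downstream", "flank_pair", "window"):
        out[mode] = neighbor_correlation(residuals, gmap, mode=mode, max_gap=max_gap)
    scored = residuals.dropna()
    scored = scored[np.isfinite(scored)]
    loci = gmap.loci[gmap.loci["gene"].isin(scored.index)]
    signs = pd.Series(np.sign(scored[loci["gene"]].to_numpy()).astype(int))
    mc, env, spectrum = run_randomization_test(
        signs, loci["chrom"].reset_index(drop=True), n_rand=n_rand, seed=seed
    )
    out["run_test"] = mc
    out["run_envelope"] = env
    out["run_spectrum"] = spectrum
    return out


@dataclass
class XChromosomeResult:
    mw_u: float
    mw_p: float
    n_x: int
    n_auto: int
    top_table: np.ndarray  # 2x2 X-membership x top-5% membership
    top_chi2: float
    top_p: float
    top_k: int
    median_tests: pd.DataFrame | None = None


def x_chromosome_tests(
    residuals: pd.Series,
    gmap: GeneMap,
    z_by_tissue: dict[str, pd.Series] | None = None,
    x_chromosome: str = "chrX",
    top_fraction: float = 0.05,
) -> XChromosomeResult:
    """Is the X a hotspot for change in sex bias?

    (a) Mann-Whitney on |standardized residual| of X-linked vs autosomal
    genes; (b) 2x2 chi-square of X membership x membership of the top
    ``ceil(top_fraction * n)`` genes by modulus; (c) optionally, per-tissue
    Mann-Whitney of Z for X vs autosomes with the medians reported.
    """
    loci = gmap.loci.set_index("gene")
    scored = residuals.dropna()
    scored = scored[np.isfinite(scored)]
    chrom = loci.loc[scored.index, "chrom"]
    on_x = (chrom == x_chromosome).to_numpy()
    if not on_x.any():
        raise ValueError(f"no genes on {x_chromosome!r}")
    modulus = scored.abs().to_numpy()
    u, p = mann_whitney(modulus[on_x], modulus[~on_x])

    n = modulus.size
    k = math.ceil(top_fraction * n)
    top_idx = np.argsort(modulus, kind="stable")[::-1][:k]
    in_top = np.zeros(n, dtype=bool)
    in_top[top_idx] = True
    table = np.array(
        [
            [np.sum(on_x & in_top), np.sum(on_x & ~in_top)],
            [np.sum(~on_x & in_top), np.sum(~on_x & ~in_top)],
        ]
    )
    chi2, chi_p, _, _ = stats.chi2_contingency(table, correction=False)

    median_tests = None
    if z_by_tissue:
        rows = []
        for tissue, z in z_by_tissue.items():
            z = z.dropna()
            z = z[np.isfinite(z)]
            zx = z[loci.loc[z.index, "chrom"] == x_chromosome]
            za = z[loci.loc[z.index, "chrom"] != x_chromosome]
            if zx.empty or za.empty:
                continue
            u_t, p_t = mann_whitney(zx.to_numpy(), za.to_numpy())
            rows.append(
                {
                    "tissue": tissue,
                    "median_x": float(zx.median()),
                    "median_autosome": float(za.median()),
                    "U": u_t,
                    "p_value": p_t,
                }
            )
        median_tests = pd.DataFrame(rows)
    return XChromosomeResult(
        u, p, int(on_x.sum()), int((~on_x).sum()), table,
        float(chi2), float(chi_p), k, median_tests,
    )
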