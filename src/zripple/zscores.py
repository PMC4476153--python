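"""Expression-divergence Z scores and expression-profile summaries.

The central statistic is

    Z = (E_c - E_a) / sqrt(V_c + V_a)

where ``E_c``/``V_c`` are the mean and sample variance of current human
expression across replicates and ``E_a``/``V_a`` the posterior mean and
variance of the human--chimp ancestral state.  Positive Z means expression
rose on the human lineage, in combined-uncertainty standard-deviation units.

Within each tissue x sex the Z distribution is recentred to median zero
(``Z_mod = Z - median(Z)``), encoding the assumption of no net transcriptome
growth or shrinkage; rank-based downstream statistics are unaffected.

Degenerate cases follow fixed rules: a zero denominator with ``E_c == E_a``
gives Z = 0; with ``E_c != E_a`` it gives a signed-infinity sentinel that is
excluded from all rank statistics.  ``E_c = 0`` with ``E_a <= 0`` marks the
gene ``zero_flag`` ("no expression" in this tissue), excluded by default with
a retain switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSummary",
    "ExpressionProfile",
    "summarize_current",
    "z_score",
    "median_correct",
    "change_metrics",
    "expression_profile",
    "EXPRESSION_FLOOR",
]

#: genes below this mean RPKM in a tissue count as unexpressed there
EXPRESSION_FLOOR = 2.0


@dataclass(frozen=True)
class ExpressionSummary:
    E_c: float
    V_c: float
    single_replicate: bool = False


@dataclass(frozen=True)
class ExpressionProfile:
    breadth: float
    mean_rate: float
    peak_rate: float
    tau: float  # NaN when undefined (no expressed tissue)
    n_tissues: int


def summarize_current(replicates: Sequence[float]) -> ExpressionSummary:
    """Mean and unbiased sample variance across replicates.

    A single replicate yields ``V_c = 0`` with the ``single_replicate`` flag
    (the variance is not estimable from one sample).
    """
    values = np.asarray(list(replicates), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    if values.size == 1:
        return ExpressionSummary(float(values[0]), 0.0, single_replicate=True)
    return ExpressionSummary(float(values.mean()), float(values.var(ddof=1)))


def z_score(e_c: float, v_c: float, e_a: float, v_a: float) -> float:
    """Z = (E_c - E_a) / sqrt(V_c + V_a).

    Zero total variance gives 0 when the means agree, else a signed-infinity
    sentinel (to be excluded from rank statistics downstream).
    """
    if v_c < 0 or v_a < 0:
        raise ValueError("variances must be non-negative")
    denom = v_c + v_a
    diff = e_c - e_a
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(denom)


def median_correct(z_raw: pd.Series | np.ndarray) -> tuple[pd.Series, float]:
    """``Z_mod = Z - median(Z)`` over the finite entries; returns (Z_mod, M).

    Rank order is preserved exactly; the median of the returned finite values
    is zero by construction.  Infinite sentinels pass through unchanged.
    """
    z = pd.Series(z_raw, dtype=float)
    finite = z[np.isfinite(z)]
    if finite.empty:
        raise ValueError("need at least one finite Z value")
    m = float(finite.median())
    return z - m, m


def change_metrics(e_c: float, e_a: float, z_mod: float) -> tuple[float, int]:
    """(fold_change, sign): E_c/E_a when E_a > 0 (else NaN), sign of Z_mod."""
    fold = e_c / e_a if e_a > 0 else float("nan")
    sign = 0 if z_mod == 0 else (1 if z_mod > 0 else -1)
    return fold, sign


def expression_profile(
    per_tissue: Sequence[float], floor: float = EXPRESSION_FLOOR
) -> ExpressionProfile:
    """Breadth, mean/peak rate, and the specificity index tau for one gene.

    Tissues with mean expression below ``floor`` are set to zero first.
    ``tau = sum_j (1 - log e_j / log e_max) / (n - 1)`` over the n tissues; a
    zero-expression tissue contributes its limiting term 1 (it is maximally
    "off").  Uniform expression gives tau = 0, single-tissue expression
    tau = 1.  With no expressed tissue, breadth is 0 and tau is NaN.
    """
    e = np.asarray(list(per_tissue), dtype=float)
    n = e.size
    if n < 2:
        raise ValueError("tau needs >= 2 tissues")
    e = np.where(e < floor, 0.0, e)
    expressed = e > 0
    breadth = expressed.mean()
    if not expressed.any():
        return ExpressionProfile(0.0, 0.0, 0.0, float("nan"), n)
    e_max = float(e.max())
    mean_rate = float(e[expressed].mean())
    log_emax = math.log(e_max)
    terms = np.ones(n)  # zero-expression tissues take the limit value 1
    if log_emax > 0:
        nz = expressed
        terms[nz] = 1.0 - np.log(e[nz]) / log_emax
    else:  # e_max == 1 exactly: every expressed tissue is at the maximum
        terms[expressed] = 0.0
    tau = float(terms.sum() / (n - 1))
    return ExpressionProfile(float(breadth), mean_rate, e_max, tau, n)
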