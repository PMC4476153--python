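"""End-to-end drivers: dataset -> ancestral states -> Z table -> reports.

The Z table is the pipeline's central tidy frame, one row per gene x tissue
x sex with columns gene, tissue, sex, E_c, V_c, E_a, V_a, Z_raw, Z_mod,
sign, fold_change, zero_flag, single_replicate, excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ancestral import ANCESTOR_NODE, SPECIES, AncestralModel, Tree
from .genome import GeneMap
from .io import ExpressionDataset
from .neighborstats import bonferroni, neighbor_correlation
from .zscores import median_correct

__all__ = [
    "ancestral_table",
    "compute_z_table",
    "z_series",
    "z_wide",
    "sign_wide",
    "neighbor_report",
]

Z_COLUMNS = [
    "gene", "tissue", "sex", "E_c", "V_c", "E_a", "V_a",
    "Z_raw", "Z_mod", "sign", "fold_change", "zero_flag",
    "single_replicate", "excluded",
]


def ancestral_table(
    dataset: ExpressionDataset,
    tree: Tree,
    node: str = ANCESTOR_NODE,
    uncertainty: str = "marginal",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Ancestral mean/variance per gene x tissue x sex (analytic, vectorized).

    ``log_scale=True`` runs the Brownian model on the natural log of the
    species means (adding a tiny offset guard is the caller's concern; zero
    means raise).
    """
    model = AncestralModel(tree, list(SPECIES), node)
    frames = []
    for tissue, sex in dataset.combos():
        means = dataset.species_means(tissue, sex, SPECIES)
        X = means.to_numpy()
        if log_scale:
            if (X <= 0).any():
                raise ValueError("log-scale ancestral fit requires positive means")
            X = np.log(X)
        est = model.estimate(X, uncertainty=uncertainty)
        frames.append(
            pd.DataFrame(
                {
                    "gene": means.index,
                    "tissue": tissue,
                    "sex": sex,
                    "E_a": est["E_a"],
                    "V_a": est["V_a"],
                    "mu": est["mu"],
                    "sigma2": est["sigma2"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compute_z_table(
    dataset: ExpressionDataset,
    tree: Tree,
    node: str = ANCESTOR_NODE,
    uncertainty: str = "marginal",
    retain_zero_flag: bool = False,
) -> pd.DataFrame:
    """Full Z table for every available tissue x sex.

    E_c/V_c come from the human replicates (unbiased variance; a single
    replicate gives V_c = 0 and a flag).  E_a/V_a come from the analytic
    ancestral estimator on the five species means.  Z_raw is median-corrected
    per tissue x sex over the non-excluded genes; genes with the zero flag
    (E_c = 0 and E_a <= 0) or an infinite Z are excluded from the median and
    marked ``excluded`` (the zero-flag exclusion is reversible via
    ``retain_zero_flag``).
    """
    model = AncestralModel(tree, list(SPECIES), node)
    frames = []
    for tissue, sex in dataset.combos():
        human = dataset.select(tissue, sex, "human")
        e_c = human.mean(axis=1)
        single = human.shape[1] == 1
        v_c = (
            pd.Series(0.0, index=human.index)
            if single
            else human.var(axis=1, ddof=1)
        )
        means = dataset.species_means(tissue, sex, SPECIES)
        est = model.estimate(means.to_numpy(), uncertainty=uncertainty)
        e_a = pd.Series(est["E_a"], index=means.index)
        v_a = pd.Series(est["V_a"], index=means.index)

        denom = v_c + v_a
        diff = e_c - e_a
        with np.errstate(divide="ignore", invalid="ignore"):
            z_raw = diff / np.sqrt(denom)
        z_raw = z_raw.where(denom > 0, np.sign(diff) * np.inf)
        z_raw = z_raw.where(~((denom == 0) & (diff == 0)), 0.0)

        zero_flag = (e_c == 0) & (e_a <= 0)
        excluded = ~np.isfinite(z_raw)
        if not retain_zero_flag:
            excluded |= zero_flag

        z_for_median = z_raw[~excluded]
        if z_for_median.empty:
            raise ValueError(f"no usable genes for tissue={tissue} sex={sex}")
        _, m = median_correct(z_for_median)
        z_mod = z_raw - m
        sign = pd.Series(np.sign(z_mod).astype(int), index=z_mod.index)
        sign[excluded] = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = (e_c / e_a).where(e_a > 0, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene": e_c.index,
                    "tissue": tissue,
                    "sex": sex,
                    "E_c": e_c.to_numpy(),
                    "V_c": v_c.to_numpy(),
                    "E_a": e_a.to_numpy(),
                    "V_a": v_a.to_numpy(),
                    "Z_raw": z_raw.to_numpy(),
                    "Z_mod": z_mod.to_numpy(),
                    "sign": sign.to_numpy(),
                    "fold_change": fold.to_numpy(),
                    "zero_flag": zero_flag.to_numpy(),
                    "single_replicate": single,
                    "excluded": excluded.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[Z_COLUMNS]


def z_series(
    z_table: pd.DataFrame,
    tissue: str,
    sex: str,
    column: str = "Z_mod",
    include_excluded: bool = False,
) -> pd.Series:
    """Per-gene score Series for one tissue x sex (excluded genes dropped)."""
    sub = z_table[(z_table["tissue"] == tissue) & (z_table["sex"] == sex)]
    if not include_excluded:
        sub = sub[~sub["excluded"]]
    return sub.set_index("gene")[column]


def z_wide(
    z_table: pd.DataFrame, sex: str = "male", column: str = "Z_mod",
    tissues=None, drop_excluded: bool = True,
) -> pd.DataFrame:
    """Genes x tissues wide frame of one sex's scores.

    With ``drop_excluded`` the excluded entries become NaN and genes missing
    any tissue are dropped (the cross-tissue statistics need complete rows).
    """
    sub = z_table[z_table["sex"] == sex]
    if tissues is not None:
        sub = sub[sub["tissue"].isin(tissues)]
    if drop_excluded:
        sub = sub[~sub["excluded"]]
    wide = sub.pivot(index="gene", columns="tissue", values=column)
    return wide.dropna()


def sign_wide(z_table: pd.DataFrame, sex: str = "male", tissues=None) -> pd.DataFrame:
    """Genes x tissues sign matrix (+1/-1/0); excluded entries count as 0."""
    sub = z_table[z_table["sex"] == sex]
    if tissues is not None:
        sub = sub[sub["tissue"].isin(tissues)]
    wide = sub.pivot(index="gene", columns="tissue", values="sign")
    return wide.dropna().astype(int)


def neighbor_report(
    z_table: pd.DataFrame,
    gmap: GeneMap,
    mode: str = "downstream",
    max_gap: int = 100_000,
    convention: str = "body_gap",
    overlapping: bool = False,
) -> pd.DataFrame:
    """Per tissue x sex neighbor-correlation table (rho, P, Bonferroni P).

    The Bonferroni family is the set of tests in this table, matching a
    per-table correction.
    """
    rows = []
    combos = z_table[["tissue", "sex"]].drop_duplicates().itertuples(index=False)
    for tissue, sex in combos:
        scores = z_series(z_table, tissue, sex)
        res = neighbor_correlation(
            scores, gmap, mode=mode, max_gap=max_gap,
            convention=convention, overlapping=overlapping,
        )
        rows.append(
            {
                "tissue": tissue,
                "sex": sex,
                "mode": mode,
                "n": res.n,
                "rho": res.rho,
                "p_value": res.p_value,
                "defined": res.defined,
            }
        )
    out = pd.DataFrame(rows)
    m = int(out["defined"].sum())
    out["p_bonferroni"] = [
        bonferroni(p, m) if d else np.nan
        for p, d in zip(out["p_value"], out["defined"])
    ]
    return out
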