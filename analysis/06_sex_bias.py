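#!/usr/bin/env python
"""Is change in sex bias itself clustered, and is the X a hotspot?

Fits the male/female SMA per tissue, checks the male-female Z correlation,
runs the residual clustering battery (neighbor modes, run test, decay), and
the X-vs-autosome modulus, top-5% and per-tissue median-Z contrasts.
"""

import pandas as pd

from study_config import RESULTS, build_study
from zripple.neighborstats import distance_decay, spearman
from zripple.pipeline import z_series
from zripple.sexbias import (
    residual_clustering,
    sma_fit,
    standardized_residuals,
    x_chromosome_tests,
)


def main():
    gmap, dataset, truth, _, _, z_table = build_study()
    tissues = sorted(set(z_table.loc[z_table["sex"] == "female", "tissue"]))

    rows, resid_by_tissue = [], {}
    for tissue in tissues:
        zm = z_series(z_table, tissue, "male")
        zf = z_series(z_table, tissue, "female")
        common = zm.index.intersection(zf.index)
        corr = spearman(zm[common].to_numpy(), zf[common].to_numpy())
        fit = sma_fit(zm[common], zf[common])
        resid = standardized_residuals(fit, zm[common], zf[common])
        resid.index = common
        resid_by_tissue[tissue] = resid["standardized"]
        clust = residual_clustering(resid["standardized"], gmap,
                                    n_rand=1_000, seed=31)
        rows.append({
            "tissue": tissue, "n": fit.n, "male_female_rho": corr.rho,
            "male_female_p": corr.p_value, "sma_slope": fit.slope,
            "rho_downstream": clust["downstream"].rho,
            "p_downstream": clust["downstream"].p_value,
            "rho_window": clust["window"].rho,
            "p_window": clust["window"].p_value,
            "run_test_p": clust["run_test"].empirical_p,
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "06_sexbias_clustering.tsv", sep="\t", index=False)

    # decay of residual correlation (brain)
    profile = distance_decay(
        resid_by_tissue["brain"], gmap,
        [10_000, 100_000, 1_000_000, 5_000_000], n_rand=400, seed=32)
    profile.table.to_csv(RESULTS / "06_residual_decay.tsv", sep="\t", index=False)

    x_rows = []
    for tissue in tissues:
        res = x_chromosome_tests(
            resid_by_tissue[tissue], gmap,
            z_by_tissue={tissue: z_series(z_table, tissue, "male")},
        )
        med = res.median_tests.iloc[0]
        x_rows.append({
            "tissue": tissue, "modulus_mw_p": res.mw_p,
            "top5_chi2": res.top_chi2, "top5_p": res.top_p,
            "median_z_x": med["median_x"],
            "median_z_autosome": med["median_autosome"],
            "median_z_p": med["p_value"],
        })
    x_table = pd.DataFrame(x_rows)
    x_table.to_csv(RESULTS / "06_x_tests.tsv", sep="\t", index=False)

    print(table.to_string(index=False))
    print()
    print(x_table.to_string(index=False))
    print(
        "\nmale and female Z correlate strongly within tissues, and residual "
        "clustering reflects the planted sex-specific block shifts; note "
        "that those blocks also make the chromosome-level X contrasts "
        "noisy -- no X effect is planted, but whole blocks of correlated "
        "residuals land on single chromosomes, so the X tests should be "
        "read against that block noise"
    )


if __name__ == "__main__":
    main()
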