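#!/usr/bin/env python
"""Generate the synthetic study and summarize its planted structure.

Writes the full data files under scratch/study/ (they are inputs for ad-hoc
exploration; every later driver regenerates the study in memory instead of
reading them) and a small truth summary under results/.
"""

from pathlib import Path

import pandas as pd

from study_config import COUPLING, RESULTS, STUDY, build_study
from zripple.io import write_expression, write_scalar_track

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main():
    gmap, dataset, truth, intervals, tracks, z_table = build_study()
    SCRATCH.mkdir(parents=True, exist_ok=True)
    gmap.to_tsv(SCRATCH / "gene_map.tsv")
    write_expression(dataset, SCRATCH / "expression.tsv", SCRATCH / "samples.tsv")
    z_table.to_csv(SCRATCH / "ztable.tsv", sep="\t", index=False)
    truth.per_gene_tissue.to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)
    for name, ivs in intervals.items():
        ivs.to_bed(SCRATCH / f"{name}.bed")
    for name, track in tracks.items():
        write_scalar_track(track, SCRATCH / f"track_{name}.tsv")

    shifted = truth.per_gene_tissue.groupby("gene")["true_shift"].apply(
        lambda s: (s != 0).any()
    )
    blocks = truth.per_gene.groupby("block_id").size()
    summary = pd.DataFrame(
        [
            ("genes", len(gmap)),
            ("chromosomes", len(gmap.chromosomes)),
            ("samples", dataset.values.shape[1]),
            ("tissue_sex_combinations", len(dataset.combos())),
            ("blocks", len(blocks)),
            ("shifted_genes", int(shifted.sum())),
            ("overlapping_adjacent_pairs",
             int(gmap.detect_overlaps()["overlapping"].sum())),
            ("annotation_coupling", COUPLING),
            ("seed", STUDY.seed),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "01_study_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nfull data written to {SCRATCH}")


if __name__ == "__main__":
    main()
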