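"""Shared study conditions for the numbered analysis drivers.

One synthetic study is used throughout: 4,000 genes on 8 chromosomes (the
last one X-labelled), six tissues with the female liver/testis gap, 10-gene
shift blocks of which 15% receive a human-branch shift, 30% of shifted
blocks concerted across tissues, and annotations coupled to the truth with
strength 0.6.  Every driver regenerates the study deterministically from
this config, so the scripts can run independently and in any order.
"""

from pathlib import Path

from zripple.ancestral import DEFAULT_TREE_NEWICK, Tree
from zripple.pipeline import compute_z_table
from zripple.simulate import SimConfig, simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimConfig(
    n_genes=4_000,
    n_chromosomes=8,
    seed=2024,
    shift_prob=0.15,
    shift_sd=0.8,
    concerted_fraction=0.3,
    sex_shift_fraction=0.15,
)

COUPLING = 0.6


def build_study():
    """(gmap, dataset, truth, intervals, tracks, z_table) for the study."""
    gmap, dataset, truth, intervals, tracks = simulate_study(STUDY, COUPLING)
    tree = Tree.from_newick(DEFAULT_TREE_NEWICK)
    z_table = compute_z_table(dataset, tree)
    RESULTS.mkdir(exist_ok=True)
    return gmap, dataset, truth, intervals, tracks, z_table
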