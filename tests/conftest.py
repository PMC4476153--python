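import numpy as np
import pandas as pd
import pytest

from zripple.ancestral import DEFAULT_TREE_NEWICK, Tree
from zripple.genome import GeneMap, GENE_COLUMNS
from zripple.pipeline import compute_z_table
from zripple.simulate import SimConfig, generate_gene_map, simulate_expression


@pytest.fixture(scope="session")
def tree() -> Tree:
    return Tree.from_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture
def tiny_map() -> GeneMap:
    """Hand-laid map: chr1 has a close pair, an overlap, and an isolated gene."""
    records = [
        ("A", "chr1", 1_000, 2_000, "+"),
        ("B", "chr1", 2_500, 3_000, "-"),
        ("C", "chr1", 2_900, 4_000, "+"),
        ("D", "chr1", 500_000, 510_000, "-"),
        ("E", "chr2", 100, 900, "+"),
        ("F", "chr2", 50_000, 60_000, "+"),
    ]
    return GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))


def random_map(rng: np.random.Generator, n: int = 60, chroms: int = 3) -> GeneMap:
    records = []
    for g in range(n):
        chrom = f"chr{rng.integers(1, chroms + 1)}"
        start = int(rng.integers(1, 200_000))
        end = start + int(rng.integers(100, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((f"g{g}", chrom, start, end, strand))
    return GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))


@pytest.fixture(scope="session")
def clustered_study(tree):
    """One blocked-shift study shared by the spatial-statistics tests."""
    cfg = SimConfig(
        n_genes=1_200, n_chromosomes=4, seed=7, shift_prob=0.3, shift_sd=1.0
    )
    gmap = generate_gene_map(cfg)
    dataset, truth = simulate_expression(gmap, cfg)
    z_table = compute_z_table(dataset, tree)
    return cfg, gmap, dataset, truth, z_table


@pytest.fixture(scope="session")
def null_study(tree):
    """A shift-free study: the global null every clustering test assumes."""
    cfg = SimConfig(n_genes=800, n_chromosomes=4, seed=19, shift_prob=0.0)
    gmap = generate_gene_map(cfg)
    dataset, truth = simulate_expression(gmap, cfg)
    z_table = compute_z_table(dataset, tree)
    return cfg, gmap, dataset, truth, z_table
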