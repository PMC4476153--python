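"""Synthetic gene maps, multi-species expression, and coupled annotations.

The generator emulates the statistical structure the analysis assumes:

* a chromosome-ordered gene map with strands, configurable overlap between
  adjacent genes, and contiguous same-chromosome gene blocks;
* per-gene, per-tissue Brownian-motion evolution of a latent log-expression
  value along a fixed five-primate tree, with an extra human-branch shift
  shared by all genes of a block (spatial clustering of expression change),
  optionally concerted in sign across tissues and optionally sex-specific;
* replicate measurement noise on the latent scale, then exponentiation, so
  the emitted RPKM-like values are non-negative while the evolutionary model
  stays Gaussian;
* annotation tracks (LAD-like and peak-like intervals, hmC/mC-like scalars)
  statistically coupled to the true shifts with a signed strength.

Ground truth (ancestral values, shifts, block ids, annotation memberships) is
returned alongside the data so downstream statistics can be calibrated
against a known answer.  Identical configurations (including the seed) give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .ancestral import DEFAULT_TREE_NEWICK, SPECIES, ANCESTOR_NODE, Tree
from .genome import GeneMap, IntervalSet, GENE_COLUMNS
from .io import ExpressionDataset

__all__ = ["SimConfig", "SimTruth", "generate_gene_map", "simulate_expression",
           "generate_annotations", "simulate_study"]

TISSUES = ("brain", "cerebellum", "heart", "kidney", "liver", "testis")
#: tissues with female samples (no female liver or testis, as in the study data)
FEMALE_TISSUES = ("brain", "cerebellum", "heart", "kidney")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions.

    Expression operates on a latent natural-log scale: ``bm_rate`` is latent
    variance per million years of branch, ``shift_sd``/``noise_sd`` are latent
    standard deviations (0.5 latent units ~ a 65% expression change).
    """

    n_genes: int = 13_027
    n_chromosomes: int = 23
    gene_length_mean: float = 30_000.0
    intergap_mean: float = 60_000.0
    overlap_fraction: float = 0.05
    strand_prob: float = 0.5
    tissues: tuple[str, ...] = TISSUES
    sexes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            t: (("male", "female") if t in FEMALE_TISSUES else ("male",))
            for t in TISSUES
        }
    )
    n_replicates: Mapping[str, int] = field(
        default_factory=lambda: {"male": 3, "female": 1}
    )
    tree_spec: str = DEFAULT_TREE_NEWICK
    bm_rate: float = 0.01
    shift_block_len: int = 10
    shift_prob: float = 0.15
    shift_sd: float = 0.5
    noise_sd: float = 0.2
    concerted_fraction: float = 0.3
    sex_shift_fraction: float = 0.0
    sex_shift_sd: float = 0.5
    base_log_mean: float = 3.0
    base_log_sd: float = 1.5
    tissue_sd: float = 1.0
    x_chromosome: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_chromosomes", "shift_block_len"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        for name in (
            "overlap_fraction",
            "strand_prob",
            "shift_prob",
            "concerted_fraction",
            "sex_shift_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise SimConfigError(f"{name} must be in [0, 1]")
        for name in ("bm_rate", "shift_sd", "noise_sd", "sex_shift_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.gene_length_mean <= 0:
            raise SimConfigError("gene_length_mean must be > 0")
        if self.intergap_mean <= 0 and self.overlap_fraction == 0:
            raise SimConfigError(
                "impossible geometry: non-positive intergap_mean with "
                "overlap_fraction 0"
            )
        for sex, n in self.n_replicates.items():
            if n < 1:
                raise SimConfigError(f"n_replicates[{sex!r}] must be >= 1")
        for t in self.sexes:
            if t not in self.tissues:
                raise SimConfigError(f"sex availability for unknown tissue {t!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["sexes"] = {t: list(s) for t, s in self.sexes.items()}
        d["n_replicates"] = dict(self.n_replicates)
        return d


@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    ``per_gene``: gene, chrom, block_id (blocks are contiguous on one
    chromosome; every gene belongs to exactly one).
    ``per_gene_tissue``: latent ancestor, true ancestor (expression scale,
    shared across sexes), human-branch shift (latent scale, sex-shared part)
    and the male-minus-female differential shift per gene x tissue.
    ``lad_truth``/``peak_truth`` are filled by :func:`generate_annotations`.
    """

    per_gene: pd.DataFrame
    per_gene_tissue: pd.DataFrame
    lad_truth: pd.Series | None = None
    peak_truth: pd.Series | None = None

    def ancestor_matrix(self, tissue: str, latent: bool = False) -> pd.Series:
        sub = self.per_gene_tissue[self.per_gene_tissue["tissue"] == tissue]
        col = "latent_ancestor" if latent else "true_ancestor"
        return sub.set_index("gene")[col]

    def shift_matrix(self, tissue: str, sex: str = "male") -> pd.Series:
        sub = self.per_gene_tissue[self.per_gene_tissue["tissue"] == tissue]
        shift = sub.set_index("gene")["true_shift"]
        delta = sub.set_index("gene")["sex_shift"]
        return shift + (delta / 2 if sex == "male" else -delta / 2)


def _chromosome_sizes(n_genes: int, n_chromosomes: int, rng) -> np.ndarray:
    """Split genes over chromosomes, roughly even, every chromosome >= 1."""
    base = np.full(n_chromosomes, n_genes // n_chromosomes)
    extra = n_genes - base.sum()
    if extra:
        base[rng.choice(n_chromosomes, size=extra, replace=False)] += 1
    if (base == 0).any():
        raise SimConfigError("more chromosomes than genes")
    return base


def chromosome_names(config: SimConfig) -> list[str]:
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.x_chromosome:
        names[-1] = "chrX"
    return names


def generate_gene_map(config: SimConfig) -> GeneMap:
    """Lay genes per chromosome in increasing coordinates, 1-based inclusive.

    Gene lengths and intergenic gaps are exponential with the configured
    means; a configured fraction of adjacent pairs is forced to overlap in
    transcript span.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sizes = _chromosome_sizes(config.n_genes, config.n_chromosomes, rng)
    names = chromosome_names(config)
    records = []
    gid = 0
    for chrom, size in zip(names, sizes):
        pos = 1
        prev_start = prev_end = None
        for _ in range(size):
            length = max(200, int(rng.exponential(config.gene_length_mean)))
            if prev_end is not None and rng.random() < config.overlap_fraction:
                # force transcript-span overlap, keeping starts increasing
                lo = prev_start + 1
                start = int(rng.integers(max(lo, prev_end - length + 1), prev_end + 1))
            else:
                gap = int(rng.exponential(max(config.intergap_mean, 1.0)))
                start = (prev_end if prev_end is not None else 0) + gap + 1
            end = start + length - 1
            strand = "+" if rng.random() < config.strand_prob else "-"
            records.append((f"g{gid:05d}", chrom, start, end, strand))
            gid += 1
            prev_start, prev_end = start, end
    return GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))


def assign_blocks(gmap: GeneMap, block_len: int) -> pd.Series:
    """Contiguous blocks of ``block_len`` genes per chromosome (never spanning
    chromosomes); returns gene -> integer block id."""
    ids = np.empty(len(gmap), dtype=int)
    next_block = 0
    offset = 0
    for chrom, sub in gmap.loci.groupby("chrom", sort=False):
        n = len(sub)
        local = np.arange(n) // block_len
        ids[offset : offset + n] = local + next_block
        next_block += local[-1] + 1
        offset += n
    return pd.Series(ids, index=gmap.loci["gene"], name="block_id")


def _bm_tip_and_ancestor(tree: Tree, tip_names, node: str, rng, rate: float,
                         shape: tuple[int, ...]):
    """Simulate zero-mean BM increments along the tree for ``shape`` many
    independent realizations; return ({tip: value}, ancestor value)."""
    # preorder walk accumulating increments
    values: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    anc = None
    dtree = tree._dtree
    for nodeobj in dtree.preorder_node_iter():
        if nodeobj.parent_node is None:
            values[id(nodeobj)] = np.zeros(shape)
        else:
            incr = rng.standard_normal(shape) * np.sqrt(rate * nodeobj.edge.length)
            values[id(nodeobj)] = values[id(nodeobj.parent_node)] + incr
        name = None
        if nodeobj.taxon is not None and nodeobj.taxon.label:
            name = nodeobj.taxon.label
        elif nodeobj.label:
            name = nodeobj.label
        if name in tip_names:
            tips[name] = values[id(nodeobj)]
        if name == node:
            anc = values[id(nodeobj)]
    if anc is None:
        raise SimConfigError(f"tree has no node named {node!r}")
    missing = set(tip_names) - set(tips)
    if missing:
        raise SimConfigError(f"tree tips do not match species: missing {missing}")
    return tips, anc


def simulate_expression(
    gmap: GeneMap, config: SimConfig
) -> tuple[ExpressionDataset, SimTruth]:
    """Replicated expression for every species/tissue/sex in the config.

    The latent log value of gene g in tissue t at the root is
    ``base_g + tissue_offset_gt``; BM with rate ``bm_rate`` runs along the
    tree; the human tip additionally receives the block shift for (block(g),
    t) plus half the sex differential (+ for males, - for females).
    Replicates add Gaussian latent noise and are exponentiated.
    """
    tree = Tree.from_newick(config.tree_spec)
    missing = set(SPECIES) - set(tree.tip_names)
    if missing:
        raise SimConfigError(f"tree tips do not match species: missing {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = gmap.loci["gene"].to_numpy()
    G, T = len(genes), len(config.tissues)

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=G)
    tissue_off = rng.normal(0.0, config.tissue_sd, size=(G, T))
    root = base[:, None] + tissue_off  # latent root value per gene x tissue

    tips, anc = _bm_tip_and_ancestor(
        tree, SPECIES, ANCESTOR_NODE, rng, config.bm_rate, (G, T)
    )

    block_id = assign_blocks(gmap, config.shift_block_len)
    blocks = block_id.to_numpy()
    n_blocks = blocks.max() + 1
    shifted = rng.random(n_blocks) < config.shift_prob
    concerted = rng.random(n_blocks) < config.concerted_fraction
    conc_sign = rng.choice([-1.0, 1.0], size=n_blocks)
    mag = np.abs(rng.normal(0.0, config.shift_sd, size=(n_blocks, T)))
    free_sign = rng.choice([-1.0, 1.0], size=(n_blocks, T))
    block_shift = np.where(
        shifted[:, None],
        mag * np.where(concerted[:, None], conc_sign[:, None], free_sign),
        0.0,
    )
    sexed = rng.random(n_blocks) < config.sex_shift_fraction
    sex_delta_block = np.where(
        sexed[:, None], rng.normal(0.0, config.sex_shift_sd, size=(n_blocks, T)), 0.0
    )
    shift = block_shift[blocks]  # gene x tissue, sex-shared part
    sex_delta = sex_delta_block[blocks]  # male gets +delta/2, female -delta/2

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for ti, tissue in enumerate(config.tissues):
        for sex in config.sexes.get(tissue, ("male",)):
            sgn = 0.5 if sex == "male" else -0.5
            n_rep = config.n_replicates.get(sex, 1)
            for sp in SPECIES:
                latent = tips[sp][:, ti].copy()
                if sp == "human":
                    latent = latent + shift[:, ti] + sgn * sex_delta[:, ti]
                for rep in range(1, n_rep + 1):
                    noisy = latent + rng.normal(0.0, config.noise_sd, size=G)
                    sample = f"{sp}_{tissue}_{sex}_{rep}"
                    columns[sample] = np.maximum(np.exp(root[:, ti] + noisy), 0.0)
                    sheet_rows.append((sample, sp, tissue, sex, rep))

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(
        sheet_rows, columns=["sample", "species", "tissue", "sex", "replicate"]
    )
    dataset = ExpressionDataset(values=values, samples=samples)

    latent_anc = root + anc
    pgt = pd.DataFrame(
        {
            "gene": np.repeat(genes, T),
            "tissue": np.tile(list(config.tissues), G),
            "latent_ancestor": latent_anc.ravel(),
            "true_ancestor": np.exp(latent_anc).ravel(),
            "true_shift": shift.ravel(),
            "sex_shift": sex_delta.ravel(),
        }
    )
    per_gene = pd.DataFrame(
        {
            "gene": genes,
            "chrom": gmap.loci["chrom"].to_numpy(),
            "block_id": blocks,
        }
    )
    return dataset, SimTruth(per_gene=per_gene, per_gene_tissue=pgt)


def generate_annotations(
    gmap: GeneMap,
    truth: SimTruth,
    coupling: float,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[dict[str, IntervalSet], dict[str, pd.Series]]:
    """Interval sets and scalar tracks statistically coupled to the shifts.

    With positive ``coupling``: LAD-like intervals preferentially cover
    negatively shifted blocks, peak-like (and gained-peak) intervals cover
    positively shifted genes, depleted-peak intervals cover negatively
    shifted genes; the hmC-like scalar correlates positively and the mC-like
    scalar negatively with the true shift.  ``coupling = 0`` makes every
    membership independent of the truth.  Also records the LAD/peak truth
    memberships on ``truth``.
    """
    if not -1 <= coupling <= 1:
        raise SimConfigError("coupling must be in [-1, 1]")
    if seed is None:
        seed = config.seed if config is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    loci = gmap.loci.set_index("gene")
    per_gene = truth.per_gene.set_index("gene")
    # sex-shared shift averaged over tissues, per gene, standardized
    shift_g = (
        truth.per_gene_tissue.groupby("gene", sort=False)["true_shift"].mean()
    ).reindex(loci.index)
    scale = float(shift_g.std(ddof=0))
    signal = np.tanh(shift_g.to_numpy() / scale) if scale > 0 else np.zeros(len(loci))

    # LAD-like intervals: per block, coverage probability decreasing in shift
    blocks = per_gene["block_id"].reindex(loci.index)
    block_sig = pd.Series(signal, index=loci.index).groupby(blocks).mean()
    p_lad = np.clip(0.3 - 0.28 * coupling * block_sig, 0.02, 0.98)
    covered_blocks = set(block_sig.index[rng.random(len(block_sig)) < p_lad])
    lad_rows = []
    margin = 5_000
    frame = loci.assign(block=blocks)
    for b, sub in frame.groupby("block"):
        if b in covered_blocks:
            lad_rows.append(
                (
                    sub["chrom"].iloc[0],
                    max(0, int(sub["start"].min()) - 1 - margin),
                    int(sub["end"].max()) + margin,
                )
            )
    lads = IntervalSet(
        "lads", pd.DataFrame(lad_rows, columns=["chrom", "start", "end"])
    )

    def _gene_intervals(p: np.ndarray, name: str) -> tuple[IntervalSet, pd.Series]:
        hit = rng.random(len(loci)) < p
        rows = [
            (c, int(s) - 1, int(e))
            for c, s, e in zip(
                loci["chrom"][hit], loci["start"][hit], loci["end"][hit]
            )
        ]
        return (
            IntervalSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"])),
            pd.Series(hit, index=loci.index, name=name),
        )

    peaks, peak_truth = _gene_intervals(
        np.clip(0.4 + 0.3 * coupling * signal, 0.02, 0.98), "peaks"
    )
    gained, _ = _gene_intervals(
        np.clip(0.15 + 0.14 * coupling * signal, 0.01, 0.98), "gained_peaks"
    )
    depleted, _ = _gene_intervals(
        np.clip(0.15 - 0.14 * coupling * signal, 0.01, 0.98), "depleted_peaks"
    )

    noise = rng.standard_normal((2, len(loci)))
    std_shift = (
        (shift_g - shift_g.mean()) / scale if scale > 0 else shift_g * 0.0
    ).to_numpy()
    tracks = {
        "hmc": pd.Series(
            coupling * std_shift + noise[0] * np.sqrt(max(1 - coupling**2, 1e-12)),
            index=loci.index,
            name="hmc",
        ),
        "mc": pd.Series(
            -coupling * std_shift + noise[1] * np.sqrt(max(1 - coupling**2, 1e-12)),
            index=loci.index,
            name="mc",
        ),
    }
    truth.lad_truth = gmap.gene_interval_overlap(lads)
    truth.peak_truth = peak_truth
    intervals = {"lads": lads, "peaks": peaks, "gained_peaks": gained,
                 "depleted_peaks": depleted}
    return intervals, tracks


def simulate_study(config: SimConfig, coupling: float = 0.0):
    """Convenience wrapper: gene map + expression + truth (+ annotations)."""
    gmap = generate_gene_map(config)
    dataset, truth = simulate_expression(gmap, config)
    intervals, tracks = generate_annotations(gmap, truth, coupling, config=config)
    return gmap, dataset, truth, intervals, tracks
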