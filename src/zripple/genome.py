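"""Chromosome-ordered gene model and interval queries.

Coordinate conventions (centralized here and tested):

* gene tables are 1-based inclusive ``[start, end]`` spans;
* BED interval sets are 0-based half-open ``[start, end)`` and are converted
  on read;
* "downstream" means increasing published-strand coordinate, regardless of
  the orientation of either gene;
* the body gap between non-overlapping genes ``A[s1,e1]``, ``B[s2,e2]`` with
  ``s2 > e1`` is ``s2 - e1 - 1`` (touching genes have gap 0 and do not
  overlap); two genes overlap iff their inclusive spans intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneMap",
    "NeighborPair",
    "IntervalSet",
    "classify_orientation",
    "body_distance",
]

GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand"]


class GeneMapError(ValueError):
    pass


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class of an adjacent pair; the left gene has the lower start.

    (-, +) -> divergent  <- ->;  (+, -) -> convergent  -> <-;
    equal strands -> cooriented.
    """
    for s in (left_strand, right_strand):
        if s not in ("+", "-"):
            raise GeneMapError(f"missing or invalid strand {s!r}")
    if left_strand == right_strand:
        return "cooriented"
    return "divergent" if left_strand == "-" else "convergent"


def body_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """Minimum body-to-body distance; 0 if the spans overlap or touch."""
    if s2 > e1:
        return s2 - e1 - 1
    if s1 > e2:
        return s1 - e2 - 1
    return 0


@dataclass(frozen=True)
class NeighborPair:
    focal: str
    neighbor: str
    gap_bp: int  # body gap; negative when overlapping
    start_to_start_bp: int
    orientation: str
    overlapping: bool


@dataclass(frozen=True)
class IntervalSet:
    """Named set of genomic intervals in BED (0-based half-open) convention."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self):
        df = self.intervals
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise GeneMapError("interval set needs chrom/start/end columns")
        if (df["start"] >= df["end"]).any():
            raise GeneMapError("BED intervals require start < end")

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise GeneMapError(f"{path}:{lineno}: malformed BED line")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError:
                    raise GeneMapError(
                        f"{path}:{lineno}: non-integer BED coordinates"
                    ) from None
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(name or str(path), df)

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


class GeneMap:
    """Validated, chromosome-sorted table of gene loci.

    The underlying frame is sorted by (chrom, start, end, gene) -- the same
    deterministic tie-break used by every neighbor query.
    """

    def __init__(self, loci: pd.DataFrame):
        df = loci[GENE_COLUMNS].copy()
        if df["gene"].duplicated().any():
            dupes = df.loc[df["gene"].duplicated(), "gene"].head(3).tolist()
            raise GeneMapError(f"duplicate gene ids: {dupes}")
        if (df["start"] < 1).any():
            raise GeneMapError("gene starts must be >= 1 (1-based inclusive)")
        if (df["start"] > df["end"]).any():
            raise GeneMapError("gene start > end")
        if not df["strand"].isin(["+", "-"]).all():
            raise GeneMapError("strand must be '+' or '-'")
        df = df.sort_values(["chrom", "start", "end", "gene"], kind="mergesort")
        self.loci = df.reset_index(drop=True)
        self._by_gene = self.loci.set_index("gene")
        self._chrom_groups = {
            chrom: sub.reset_index()  # keeps position in self.loci as 'index'
            for chrom, sub in self.loci.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_groups)

    def locus(self, gene: str) -> pd.Series:
        try:
            row = self._by_gene.loc[gene].copy()
        except KeyError:
            raise GeneMapError(f"unknown gene {gene!r}") from None
        row["gene"] = gene
        return row

    # -- adjacency ---------------------------------------------------------

    def _pair(self, frow: pd.Series, nrow: pd.Series) -> NeighborPair:
        gap = int(nrow["start"]) - int(frow["end"]) - 1
        overlapping = int(nrow["start"]) <= int(frow["end"])
        return NeighborPair(
            focal=str(frow["gene"]),
            neighbor=str(nrow["gene"]),
            gap_bp=gap,
            start_to_start_bp=int(nrow["start"]) - int(frow["start"]),
            orientation=classify_orientation(frow["strand"], nrow["strand"]),
            overlapping=overlapping,
        )

    def nearest_downstream(
        self,
        focal: str,
        max_gap: int = 100_000,
        convention: str = "body_gap",
    ) -> NeighborPair | None:
        """Neighbor with smallest start strictly greater than the focal start.

        Returns None when no such gene exists on the chromosome or the
        distance under ``convention`` ("body_gap" or "start_to_start")
        exceeds ``max_gap``.  Overlapping neighbors always qualify.
        """
        if convention not in ("body_gap", "start_to_start"):
            raise GeneMapError(f"unknown distance convention {convention!r}")
        frow = self.locus(focal)
        sub = self._chrom_groups[frow["chrom"]]
        starts = sub["start"].to_numpy()
        j = int(np.searchsorted(starts, frow["start"], side="right"))
        if j >= len(sub):
            return None
        pair = self._pair(frow, sub.iloc[j])
        if pair.overlapping:
            return pair
        dist = pair.gap_bp if convention == "body_gap" else pair.start_to_start_bp
        return pair if dist <= max_gap else None

    def nearest_downstream_table(
        self, max_gap: int = 100_000, convention: str = "body_gap"
    ) -> pd.DataFrame:
        """Vectorized nearest-downstream pairs for every focal gene.

        Columns: focal, neighbor, gap_bp, start_to_start_bp, orientation,
        overlapping.  Focal genes without a qualifying neighbor are absent.
        """
        if convention not in ("body_gap", "start_to_start"):
            raise GeneMapError(f"unknown distance convention {convention!r}")
        frames = []
        for chrom, sub in self._chrom_groups.items():
            n = len(sub)
            if n < 2:
                continue
            starts = sub["start"].to_numpy()
            # first index j > i with starts[j] > starts[i]
            nxt = np.searchsorted(starts, starts, side="right")
            valid = nxt < n
            i = np.nonzero(valid)[0]
            j = nxt[valid]
            f, nb = sub.iloc[i], sub.iloc[j]
            gap = nb["start"].to_numpy() - f["end"].to_numpy() - 1
            sts = nb["start"].to_numpy() - f["start"].to_numpy()
            overl = gap < 0
            ori = np.where(
                f["strand"].to_numpy() == nb["strand"].to_numpy(),
                "cooriented",
                np.where(f["strand"].to_numpy() == "-", "divergent", "convergent"),
            )
            frame = pd.DataFrame(
                {
                    "focal": f["gene"].to_numpy(),
                    "neighbor": nb["gene"].to_numpy(),
                    "gap_bp": gap,
                    "start_to_start_bp": sts,
                    "orientation": ori,
                    "overlapping": overl,
                }
            )
            dist = frame["gap_bp"] if convention == "body_gap" else frame["start_to_start_bp"]
            frame = frame[(frame["overlapping"]) | (dist <= max_gap)]
            frames.append(frame)
        if not frames:
            return pd.DataFrame(
                columns=[
                    "focal",
                    "neighbor",
                    "gap_bp",
                    "start_to_start_bp",
                    "orientation",
                    "overlapping",
                ]
            )
        return pd.concat(frames, ignore_index=True)

    def flanking_pair(
        self, focal: str, max_gap: int = 100_000, convention: str = "body_gap"
    ) -> tuple[NeighborPair, NeighborPair] | None:
        """Nearest upstream and downstream neighbors, both within ``max_gap``.

        The upstream neighbor is the gene of which the focal is the nearest
        downstream gene under the same start-ordering rule.  Returns None if
        either flank is missing or too far.
        """
        frow = self.locus(focal)
        sub = self._chrom_groups[frow["chrom"]]
        starts = sub["start"].to_numpy()
        lo = int(np.searchsorted(starts, frow["start"], side="left"))
        hi = int(np.searchsorted(starts, frow["start"], side="right"))
        if lo == 0 or hi >= len(sub):
            return None
        up_row = sub.iloc[lo - 1]
        up_pair = self._pair(up_row, frow)
        down = self.nearest_downstream(focal, max_gap=max_gap, convention=convention)
        if down is None:
            return None
        if not up_pair.overlapping:
            dist = (
                up_pair.gap_bp
                if convention == "body_gap"
                else up_pair.start_to_start_bp
            )
            if dist > max_gap:
                return None
        return (up_pair, down)

    def neighbors_within(self, focal: str, radius: int) -> list[str]:
        """All other genes whose body lies within ``radius`` bp of the focal body.

        Uses the minimum body-to-body distance with a ``<= radius`` rule;
        overlapping non-focal genes count as distance 0 and are included.
        """
        if radius <= 0:
            raise GeneMapError("radius must be > 0")
        frow = self.locus(focal)
        sub = self._chrom_groups[frow["chrom"]]
        s, e = int(frow["start"]), int(frow["end"])
        qualify = (sub["start"] <= e + radius + 1) & (sub["end"] >= s - radius - 1)
        out = sub.loc[qualify, "gene"].tolist()
        return [g for g in out if g != focal]

    def neighbor_sets_within(self, radius: int) -> dict[str, list[str]]:
        """Vectorized :meth:`neighbors_within` for all genes (per-chromosome)."""
        if radius <= 0:
            raise GeneMapError("radius must be > 0")
        result: dict[str, list[str]] = {}
        for chrom, sub in self._chrom_groups.items():
            s = sub["start"].to_numpy()[:, None]
            e = sub["end"].to_numpy()[:, None]
            near = (s.T <= e + radius + 1) & (e.T >= s - radius - 1)
            np.fill_diagonal(near, False)
            genes = sub["gene"].to_numpy()
            for i, g in enumerate(genes):
                result[g] = genes[near[i]].tolist()
        return result

    def detect_overlaps(self) -> pd.DataFrame:
        """Overlap flags for consecutive (by sorted start) gene pairs.

        A pair overlaps iff the 1-based inclusive spans intersect; a running
        maximum of upstream ends catches overlaps across nested/contained
        genes, not just the immediately preceding one.
        """
        frames = []
        for chrom, sub in self._chrom_groups.items():
            n = len(sub)
            if n < 2:
                continue
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            max_prev_end = np.maximum.accumulate(ends)[:-1]
            overl = starts[1:] <= max_prev_end
            frames.append(
                pd.DataFrame(
                    {
                        "left": sub["gene"].to_numpy()[:-1],
                        "right": sub["gene"].to_numpy()[1:],
                        "overlapping": overl,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["left", "right", "overlapping"])
        return pd.concat(frames, ignore_index=True)

    def overlaps_adjacent(self) -> pd.Series:
        """Per-gene flag: does the gene overlap any adjacent (prev/next) gene?"""
        flag = pd.Series(False, index=self.loci["gene"])
        adj = self.detect_overlaps()
        for _, row in adj[adj["overlapping"]].iterrows():
            flag[row["left"]] = True
            flag[row["right"]] = True
        return flag

    def gene_interval_overlap(self, intervals: IntervalSet) -> pd.Series:
        """True per gene iff >= 1 bp of the body intersects >= 1 interval.

        BED's 0-based half-open intervals are converted to the gene table's
        1-based inclusive coordinates before intersection.
        """
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in intervals.intervals.groupby("chrom"):
            # BED [start, end) == 1-based inclusive [start+1, end]
            trees[chrom] = IntervalTree.from_tuples(
                (int(s) + 1, int(e) + 1) for s, e in zip(sub["start"], sub["end"])
            )
        out = np.zeros(len(self.loci), dtype=bool)
        for i, (chrom, s, e) in enumerate(
            zip(self.loci["chrom"], self.loci["start"], self.loci["end"])
        ):
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(int(s), int(e) + 1):
                out[i] = True
        return pd.Series(out, index=self.loci["gene"], name=intervals.name)

    def window_query(self, chrom: str, position: int, window: int) -> list[str]:
        """Genes whose body intersects [position - window, position + window]."""
        if chrom not in self._chrom_groups:
            raise GeneMapError(f"unknown chromosome {chrom!r}")
        sub = self._chrom_groups[chrom]
        lo, hi = position - window, position + window
        hit = (sub["start"] <= hi) & (sub["end"] >= lo)
        return sub.loc[hit, "gene"].tolist()

    # -- IO ------------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "GeneMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(GENE_COLUMNS) - set(df.columns)
        if missing:
            raise GeneMapError(f"gene map missing columns {sorted(missing)}")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.loci.to_csv(path, sep="\t", index=False)


def make_gene_map(records: Iterable[Sequence]) -> GeneMap:
    """GeneMap from (gene, chrom, start, end, strand) tuples."""
    return GeneMap(pd.DataFrame(records, columns=GENE_COLUMNS))
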