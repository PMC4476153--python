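"""File formats: expression matrix + sample sheet, gene map, tracks, manifest.

All tabular formats are TSV with a header row and '.' decimals; BED files are
0-based half-open; trees are newick.  Readers validate rather than coerce:
duplicate gene ids, unknown sample columns, negative or missing expression
values raise errors naming the offender.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "read_scalar_track",
    "write_scalar_track",
    "write_manifest",
]

SAMPLE_COLUMNS = ["sample", "species", "tissue", "sex", "replicate"]
KNOWN_SPECIES = {"human", "chimp", "gorilla", "orangutan", "macaque"}


class ExpressionIOError(ValueError):
    pass


@dataclass
class ExpressionDataset:
    """Normalized (RPKM-like) expression matrix plus its sample sheet.

    ``values``: genes x samples frame (index = gene ids, columns = sample ids).
    ``samples``: one row per sample (sample, species, tissue, sex, replicate).
    Missing sex/tissue combinations are simply absent columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ExpressionIOError(f"sample sheet missing columns {sorted(missing)}")
        if self.samples["sample"].duplicated().any():
            raise ExpressionIOError("duplicate sample ids in sample sheet")
        sheet = set(self.samples["sample"])
        cols = set(self.values.columns)
        if sheet != cols:
            odd = sorted((sheet ^ cols))[:5]
            raise ExpressionIOError(
                f"sample sheet and matrix columns disagree (e.g. {odd})"
            )
        unknown = set(self.samples["species"]) - KNOWN_SPECIES
        if unknown:
            raise ExpressionIOError(f"unknown species {sorted(unknown)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def combos(self) -> list[tuple[str, str]]:
        """Available (tissue, sex) combinations, in sheet order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.samples.iterrows():
            key = (row["tissue"], row["sex"])
            if key not in seen:
                seen.append(key)
        return seen

    def select(self, tissue: str, sex: str, species: str | None = None) -> pd.DataFrame:
        """Sub-matrix of samples for one tissue/sex (optionally one species)."""
        mask = (self.samples["tissue"] == tissue) & (self.samples["sex"] == sex)
        if species is not None:
            mask &= self.samples["species"] == species
        cols = self.samples.loc[mask, "sample"]
        return self.values[list(cols)]

    def species_means(self, tissue: str, sex: str, species_order) -> pd.DataFrame:
        """Per-species mean expression (genes x species) for one tissue/sex."""
        out = {}
        for sp in species_order:
            sub = self.select(tissue, sex, sp)
            if sub.shape[1] == 0:
                raise ExpressionIOError(
                    f"no samples for species={sp} tissue={tissue} sex={sex}"
                )
            out[sp] = sub.mean(axis=1)
        return pd.DataFrame(out)


def read_expression(matrix_path, sample_sheet_path) -> ExpressionDataset:
    """Read a gene x sample expression TSV with its sample sheet, validating."""
    samples = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ExpressionIOError(
            f"{sample_sheet_path}: missing columns {sorted(missing)}"
        )
    samples["replicate"] = samples["replicate"].astype(int)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dupes = values.index[values.index.duplicated()][:3].tolist()
        raise ExpressionIOError(f"{matrix_path}: duplicate gene ids {dupes}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ExpressionIOError(f"{matrix_path}: non-numeric expression values")
    if np.isnan(arr).any():
        gene = values.index[np.isnan(arr).any(axis=1)][0]
        raise ExpressionIOError(f"{matrix_path}: NaN expression for gene {gene!r}")
    if (arr < 0).any():
        gene = values.index[(arr < 0).any(axis=1)][0]
        raise ExpressionIOError(
            f"{matrix_path}: negative expression for gene {gene!r}"
        )
    return ExpressionDataset(values=values, samples=samples)


def write_expression(dataset: ExpressionDataset, matrix_path, sample_sheet_path):
    dataset.values.to_csv(matrix_path, sep="\t", index_label="gene")
    dataset.samples.to_csv(sample_sheet_path, sep="\t", index=False)


def read_scalar_track(path) -> pd.Series:
    """Per-gene scalar track TSV (columns: gene, value)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "value"}.issubset(df.columns):
        raise ExpressionIOError(f"{path}: scalar track needs gene/value columns")
    if df["gene"].duplicated().any():
        raise ExpressionIOError(f"{path}: duplicate gene ids in scalar track")
    return df.set_index("gene")["value"].astype(float)


def write_scalar_track(track: pd.Series, path) -> None:
    track.rename("value").rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs=(), outputs=(), seed=None) -> dict:
    """JSON run manifest: config echo, seed, versions, input checksums."""
    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "zripple": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
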