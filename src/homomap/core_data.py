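"""Data model and I/O for gene x cell UMI count matrices.

The central container is :class:`ExpressionDataset`: a sparse genes x cells
matrix of non-negative integer UMI counts plus per-cell annotations
(cell-type, optionally region and spot grid coordinates).  Matrices are
exchanged as Matrix Market coordinate files with one-entry-per-line TSV
label files, the convention of filtered feature-barcode matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "GeneClassTable",
    "FormatError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "qc_filter",
    "cap_dataset_size",
]

GENE_CLASSES = (
    "transcription_factor",
    "neuromodulatory_ligand",
    "neuromodulatory_receptor",
    "other",
)


class FormatError(ValueError):
    """Raised when an on-disk file does not match its expected layout."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a dataset invariant."""


@dataclass
class ExpressionDataset:
    """One species' (or one slide's) UMI counts with per-cell annotations.

    Attributes
    ----------
    species_tag:
        Short identifier for the species/dataset, used to tag cells when two
        datasets are combined.
    gene_ids, cell_ids:
        Ordered, duplicate-free identifiers for matrix rows and columns.
    counts:
        Sparse ``genes x cells`` matrix of non-negative integer UMI counts.
    cell_type:
        Per-cell categorical label (one label per cell, required).
    region:
        Optional per-cell/per-spot anatomical region label.
    spot_coords:
        Optional integer ``(row, col)`` grid coordinates, one per cell; only
        meaningful for spatial spot datasets.
    true_abundance:
        Optional spots x cell-types matrix of simulated ground-truth cell
        counts (set by the spatial-grid generator, never read from disk).
    """

    species_tag: str
    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    cell_type: np.ndarray
    region: np.ndarray | None = None
    spot_coords: np.ndarray | None = None
    true_abundance: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        self.counts = sp.csr_matrix(self.counts)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
        if self.spot_coords is not None:
            self.spot_coords = np.asarray(self.spot_coords, dtype=int)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise FormatError(
                f"label/matrix dimension mismatch: matrix {self.counts.shape}, "
                f"{len(self.gene_ids)} gene ids, {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entries")
        if len(self.cell_type) != n_cells:
            raise ValidationError("cell_type must have one label per cell")
        if any(pd.isna(t) for t in self.cell_type):
            raise ValidationError("every cell needs a cell_type label")
        if self.region is not None and len(self.region) != n_cells:
            raise ValidationError("region must have one label per cell")
        if self.spot_coords is not None and self.spot_coords.shape != (n_cells, 2):
            raise ValidationError("spot_coords must be (n_cells, 2) integers")

    # -- conveniences ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one UMI, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to the cells at integer positions ``index``."""
        index = np.asarray(index)
        return replace(
            self,
            cell_ids=[self.cell_ids[i] for i in index],
            counts=self.counts[:, index],
            cell_type=self.cell_type[index],
            region=None if self.region is None else self.region[index],
            spot_coords=None if self.spot_coords is None else self.spot_coords[index],
            true_abundance=None
            if self.true_abundance is None
            else self.true_abundance.iloc[index],
        )


@dataclass
class GeneClassTable:
    """Maps gene symbols to one of four functional classes.

    Unlisted symbols default to ``"other"``.
    """

    classes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in GENE_CLASSES}
        if bad:
            raise ValidationError(f"unknown gene classes: {sorted(bad)}")

    def lookup(self, symbol: str) -> str:
        return self.classes.get(symbol, "other")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneClassTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_symbol", "gene_class"} <= set(df.columns):
            raise FormatError("gene class table needs gene_symbol and gene_class columns")
        if df["gene_symbol"].duplicated().any():
            raise ValidationError("each symbol maps to exactly one class")
        return cls(dict(zip(df["gene_symbol"], df["gene_class"])))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_labels(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_dataset(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    annotations_path: str | Path | None = None,
    species_tag: str = "species",
) -> ExpressionDataset:
    """Read a Matrix Market counts matrix with TSV label and annotation files.

    The annotation TSV must be keyed by a ``cell_id`` column and provide
    ``cell_type``; optional ``region`` and ``row``/``col`` columns populate
    region labels and spot coordinates.  Without an annotation file every
    cell is labeled ``"unassigned"``.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"could not parse Matrix Market file: {exc}") from exc
    counts = sp.csr_matrix(mat)
    genes = _read_labels(genes_path)
    cells = _read_labels(cells_path)
    if counts.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {counts.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )

    region = None
    coords = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype={"cell_id": str})
        if "cell_id" not in ann.columns or "cell_type" not in ann.columns:
            raise FormatError("annotations need cell_id and cell_type columns")
        ann = ann.set_index("cell_id")
        missing = [c for c in cells if c not in ann.index]
        if missing:
            raise ValidationError(f"annotations missing cell ids: {missing[:5]}")
        ann = ann.loc[cells]
        cell_type = ann["cell_type"].to_numpy(dtype=object)
        if "region" in ann.columns:
            region = ann["region"].to_numpy(dtype=object)
        if {"row", "col"} <= set(ann.columns):
            coords = ann[["row", "col"]].to_numpy(dtype=int)
    else:
        cell_type = np.array(["unassigned"] * len(cells), dtype=object)

    return ExpressionDataset(
        species_tag=species_tag,
        gene_ids=genes,
        cell_ids=cells,
        counts=counts,
        cell_type=cell_type,
        region=region,
        spot_coords=coords,
    )


def write_dataset(ds: ExpressionDataset, out_dir: str | Path, prefix: str = "matrix") -> None:
    """Write a dataset as ``<prefix>.mtx`` + gene/cell label TSVs + annotations."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / f"{prefix}.mtx"), sp.coo_matrix(ds.counts))
    (out / f"{prefix}.genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    (out / f"{prefix}.cells.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    ann = pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.cell_type})
    if ds.region is not None:
        ann["region"] = ds.region
    if ds.spot_coords is not None:
        ann["row"] = ds.spot_coords[:, 0]
        ann["col"] = ds.spot_coords[:, 1]
    ann.to_csv(out / f"{prefix}.annotations.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filtering and size capping
# ---------------------------------------------------------------------------

def qc_filter(
    ds: ExpressionDataset,
    min_umi: int = 500,
    min_genes: int = 500,
    max_umi: int = 5000,
    max_genes: int = 2500,
) -> ExpressionDataset:
    """Keep cells with min_umi < total UMI < max_umi and min_genes < detected < max_genes.

    All four inequalities are strict ("greater than 500 UMIs, ... less than
    5000 UMIs").  An empty result is returned with a warning, not an error.
    """
    if min_umi <= 0 or min_genes <= 0:
        raise ValueError("thresholds must be positive")
    if min_umi >= max_umi or min_genes >= max_genes:
        raise ValueError("min thresholds must be below max thresholds")
    totals = ds.cell_totals()
    ngene = ds.genes_detected()
    keep = (totals > min_umi) & (totals < max_umi) & (ngene > min_genes) & (ngene < max_genes)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return ds.subset_cells(np.flatnonzero(keep))


def cap_dataset_size(ds: ExpressionDataset, target_n: int, seed: int) -> ExpressionDataset:
    """Randomly and evenly remove cells from the largest cell-type groups.

    One cell at a time is removed from a currently-largest group (ties between
    groups broken by label sort order) until exactly ``target_n`` cells
    remain.  Deterministic given ``seed``; the maximum group size never
    increases during removal.
    """
    if target_n > ds.n_cells:
        raise ValueError(f"target_n={target_n} exceeds {ds.n_cells} cells")
    if target_n == ds.n_cells:
        return ds
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(ds.cell_type):
        groups.setdefault(str(t), []).append(i)
    n_remove = ds.n_cells - target_n
    for _ in range(n_remove):
        max_size = max(len(v) for v in groups.values())
        label = min(g for g, v in groups.items() if len(v) == max_size)
        members = groups[label]
        j = int(rng.integers(len(members)))
        members[j] = members[-1]
        members.pop()
        if not members:
            del groups[label]
    keep = np.sort(np.concatenate([np.array(v, dtype=int) for v in groups.values()]))
    return ds.subset_cells(keep)
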