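"""Data model and file I/O shared by all analysis stages.

The central container is :class:`CellTable`, a sparse cells x genes UMI
count matrix with per-cell metadata (mouse sample, time after injury in
days, optional cell-type label) and optional extra count layers of the
same shape (e.g. ``"spliced"`` / ``"unspliced"``).  Bulk-level profiles
(tissue RNA-seq, in silico bulk, proteomics intensities) live in
:class:`BulkProfile`.

On disk a CellTable is a MatrixMarket MTX file (cell-major, 1-based, as
per the MatrixMarket convention) plus row/column id TSVs and a metadata
TSV keyed by cell id.  ``write_counts`` / ``read_counts`` round-trip
counts, layers and metadata bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellTable",
    "BulkProfile",
    "ValidationError",
    "FormatError",
    "read_counts",
    "write_counts",
]

#: metadata columns every cell must carry
REQUIRED_META = ("sample", "time_days")


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk file cannot be interpreted."""


def _as_int_csr(mat) -> sp.csr_matrix:
    """Coerce to CSR with integer dtype, rejecting negatives / non-integers."""
    m = sp.csr_matrix(mat)
    if m.nnz:
        data = m.data
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data), atol=0, rtol=0):
                raise ValidationError("count entries must be integers")
            data = data.astype(np.int64)
        if data.min() < 0:
            raise ValidationError("count entries must be nonnegative")
        m = sp.csr_matrix((data.astype(np.int64), m.indices, m.indptr), shape=m.shape)
    else:
        m = sp.csr_matrix(m.shape, dtype=np.int64)
    return m


@dataclass
class CellTable:
    """Sparse cells x genes UMI counts plus per-cell metadata.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, cells as rows and genes as columns.
    gene_ids, cell_ids
        Unique string identifiers for columns and rows.
    obs
        Per-cell metadata indexed like ``cell_ids``; must contain columns
        ``sample`` and ``time_days`` (days after injury; uninjured PBS
        controls enter at time 0), may contain ``label`` (cell type) and
        ``is_control``.
    layers
        Optional named count matrices of identical shape.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    obs: pd.DataFrame
    layers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.counts = _as_int_csr(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if not isinstance(self.obs, pd.DataFrame):
            raise ValidationError("obs must be a DataFrame")
        self.obs = self.obs.copy()
        self.obs.index = pd.Index(self.cell_ids)
        for col in REQUIRED_META:
            if col not in self.obs.columns:
                raise ValidationError(f"metadata column '{col}' is required")
            if self.obs[col].isna().any():
                bad = self.obs.index[self.obs[col].isna()][0]
                raise ValidationError(f"cell '{bad}' has missing '{col}'")
        t = pd.to_numeric(self.obs["time_days"], errors="coerce")
        if t.isna().any() or (t < 0).any():
            raise ValidationError("time_days must be nonnegative numbers")
        self.obs["time_days"] = t.astype(float)
        self.layers = {k: _as_int_csr(v) for k, v in self.layers.items()}
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValidationError(
                    f"layer '{name}' shape {layer.shape} != counts shape {self.counts.shape}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def sample(self) -> pd.Series:
        return self.obs["sample"]

    @property
    def time_days(self) -> pd.Series:
        return self.obs["time_days"]

    @property
    def label(self) -> pd.Series | None:
        return self.obs["label"] if "label" in self.obs.columns else None

    def total_counts(self) -> np.ndarray:
        """Total UMI per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with nonzero count per cell."""
        return np.diff(self.counts.indptr)

    def subset_cells(self, mask) -> "CellTable":
        """New table restricted to the cells selected by a boolean mask or index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellTable(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            obs=self.obs.iloc[idx],
            layers={k: v.tocsr()[idx] for k, v in self.layers.items()},
        )

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if len(hits) == 0:
            raise KeyError(f"gene '{gene}' not in table")
        return int(hits[0])

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
            layers={k: v.copy() for k, v in self.layers.items()},
        )


@dataclass
class BulkProfile:
    """Bulk-level profiles: samples x genes values with per-sample annotation.

    ``values`` rows are samples, columns genes.  ``sample_meta`` is indexed
    by sample id and carries at least ``condition`` and ``modality``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample ids in bulk profile")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate gene ids in bulk profile")
        self.sample_meta = self.sample_meta.reindex(self.values.index)
        if self.sample_meta.isna().all(axis=1).any():
            missing = self.sample_meta.index[self.sample_meta.isna().all(axis=1)][0]
            raise ValidationError(f"sample '{missing}' has no metadata")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


# -- I/O -------------------------------------------------------------------

def _read_ids(path: str) -> np.ndarray:
    with open(path) as fh:
        ids = [line.rstrip("\n") for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def read_counts(matrix_path, genes_path, cells_path, meta_path) -> CellTable:
    """Read a CellTable from MTX + id TSVs + metadata TSV.

    The MTX is cell-major (rows = cells, columns = genes).  The metadata
    TSV must have a ``cell_id`` column covering every cell; cells without
    metadata are rejected.  Layer files named ``layer_<name>.mtx`` next to
    the matrix are picked up automatically.
    """
    try:
        counts = scipy.io.mmread(matrix_path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    if counts.shape != (len(cells), len(genes)):
        raise FormatError(
            f"MTX dimensions {counts.shape} do not match "
            f"{len(cells)} cell ids x {len(genes)} gene ids"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str, "sample": str})
    if "cell_id" not in meta.columns:
        raise FormatError("metadata TSV must have a 'cell_id' column")
    meta = meta.set_index("cell_id")
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise ValidationError(f"metadata missing for cell '{missing[0]}'")
    obs = meta.loc[list(cells)]

    layers = {}
    base = os.path.dirname(os.path.abspath(matrix_path))
    for fname in sorted(os.listdir(base)):
        if fname.startswith("layer_") and fname.endswith(".mtx"):
            name = fname[len("layer_"):-len(".mtx")]
            layers[name] = scipy.io.mmread(os.path.join(base, fname))
    return CellTable(counts=counts, gene_ids=genes, cell_ids=cells, obs=obs, layers=layers)


def write_counts(table: CellTable, out_dir) -> dict:
    """Write a CellTable as MTX + TSVs; returns the mapping of written paths.

    ``read_counts`` inverts this bit-exactly on counts, layers and metadata.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "counts.mtx"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "cells": os.path.join(out_dir, "cells.tsv"),
        "meta": os.path.join(out_dir, "metadata.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], table.counts.tocoo(), field="integer")
    for name, layer in table.layers.items():
        p = os.path.join(out_dir, f"layer_{name}.mtx")
        scipy.io.mmwrite(p, layer.tocoo(), field="integer")
        paths[f"layer_{name}"] = p
    with open(paths["genes"], "w") as fh:
        fh.writelines(f"{g}\n" for g in table.gene_ids)
    with open(paths["cells"], "w") as fh:
        fh.writelines(f"{c}\n" for c in table.cell_ids)
    meta = table.obs.copy()
    meta.insert(0, "cell_id", table.cell_ids)
    meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_rl_catalog(path) -> pd.DataFrame:
    """Read a receptor-ligand catalog CSV with columns ``ligand``, ``receptor``."""
    cat = pd.read_csv(path)
    for col in ("ligand", "receptor"):
        if col not in cat.columns:
            raise FormatError("receptor-ligand catalog needs 'ligand' and 'receptor' columns")
    return cat[["ligand", "receptor"]].astype(str)
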