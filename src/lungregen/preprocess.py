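"""QC filtering, normalization, marker discovery, cell-type frequencies
and in silico bulk construction.

Filtering follows the droplet-workflow rules of the emulated study: a
per-sample barcode rank cut (the expected-cell count plus headroom), a
minimum detected-genes threshold, a mitochondrial-fraction cap and an
upper total-UMI cut to exclude likely doublets.  Marker discovery is a
one-vs-rest Wilcoxon rank-sum on log-normalized expression restricted to
genes detected in more than 10% of a cluster's cells with an absolute
average natural-log fold change of at least 0.25, Benjamini-Hochberg
adjusted within each cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import BulkProfile, CellTable, ValidationError

__all__ = [
    "filter_barcodes",
    "filter_cells_qc",
    "normalize_log",
    "find_markers",
    "cell_type_frequencies",
    "scale_minmax",
    "in_silico_bulk",
]


def filter_barcodes(
    table: CellTable, min_genes: int = 200, max_barcodes_per_sample: int = 1200
) -> CellTable:
    """Per sample keep the top ``max_barcodes_per_sample`` barcodes by total
    UMI, then drop barcodes with fewer than ``min_genes`` detected genes.

    The rank cut is applied before the detected-genes filter, matching the
    stated order of the workflow being reproduced.  Idempotent.
    """
    totals = table.total_counts()
    detected = table.genes_detected()
    keep = np.zeros(table.n_cells, dtype=bool)
    for _, idx in table.obs.groupby("sample", sort=False).indices.items():
        idx = np.asarray(idx)
        # stable rank: ties broken by original order so the cut is deterministic
        order = idx[np.argsort(-totals[idx], kind="stable")]
        top = order[:max_barcodes_per_sample]
        keep[top] = detected[top] >= min_genes
    return table.subset_cells(keep)


def filter_cells_qc(
    table: CellTable,
    max_mito_frac: float = 0.10,
    max_umi: float = 5000,
    mito_prefix: str = "mt-",
) -> CellTable:
    """Remove cells with mitochondrial count fraction above ``max_mito_frac``
    or total UMI count of ``max_umi`` or more (strict "less than" rule).

    ``max_umi`` is 5000 for whole-lung-style data and 3000 for the
    higher-resolution sorted-cell design.  Mitochondrial genes are found by
    prefix (mouse default ``mt-``); if none are present the mito rule is
    skipped with a warning.
    """
    totals = table.total_counts()
    keep = totals < max_umi
    is_mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in table.gene_ids]
    )
    if is_mito.any():
        mito = np.asarray(table.counts[:, np.flatnonzero(is_mito)].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        keep &= frac <= max_mito_frac
    else:
        warnings.warn(
            f"no genes with prefix '{mito_prefix}' found; mitochondrial filter skipped"
        )
    return table.subset_cells(keep)


def normalize_log(table: CellTable, scale_factor: float = 1e4) -> sp.csr_matrix:
    """Log-normalize: ``ln(1 + count / cell_total * scale_factor)``.

    Zero counts map to zero, so the result stays sparse.  Cells with zero
    total counts are rejected by name.
    """
    totals = table.total_counts()
    if (totals == 0).any():
        bad = table.cell_ids[np.argmax(totals == 0)]
        raise ValidationError(f"cell '{bad}' has zero total counts; filter first")
    x = table.counts.tocoo()
    data = np.log1p(x.data / totals[x.row] * scale_factor)
    return sp.csr_matrix((data, (x.row, x.col)), shape=x.shape)


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both groups are small
    (n <= 25) and the pooled values are tie-free, otherwise the normal
    approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 25 and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _rank_sum_pvalues(in_block: np.ndarray, out_block: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (columns)."""
    n_in, n_out = in_block.shape[0], out_block.shape[0]
    if min(n_in, n_out) > 25:
        res = mannwhitneyu(in_block, out_block, alternative="two-sided",
                           method="asymptotic", axis=0)
        return np.asarray(res.pvalue)
    return np.array(
        [rank_sum_p(in_block[:, j], out_block[:, j]) for j in range(in_block.shape[1])]
    )


def find_markers(
    normalized: sp.spmatrix,
    labels,
    gene_ids=None,
    min_pct: float = 0.10,
    min_logfc: float = 0.25,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker discovery on a log-normalized matrix.

    For every label and gene detected in more than ``min_pct`` of the
    label's cells, tests the label's cells against all other cells with a
    two-sided Wilcoxon rank-sum; ``avg_logFC`` is the difference of mean
    normalized (natural-log) expression, in minus rest.  Genes with
    ``|avg_logFC| < min_logfc`` are excluded; BH adjustment is applied
    within each label.  Labels with fewer than ``min_cells`` cells are
    skipped with a warning.

    Returns
    -------
    MarkerTable: DataFrame with columns cell_type, gene, avg_logFC,
    pct_in, pct_out, p_value, p_adj and a 'gene' per (cell_type, gene).
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    X = sp.csr_matrix(normalized)
    n_cells, n_genes = X.shape
    if len(labels) != n_cells:
        raise ValidationError("labels length must match matrix rows")
    uniq = [l for l in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValidationError("need at least two labels")
    if gene_ids is None:
        gene_pos = np.arange(n_genes)
    else:
        gene_pos = np.asarray(gene_ids, dtype=object)
        if len(gene_pos) != n_genes:
            raise ValidationError("gene_ids length must match matrix columns")
    dense = np.asarray(X.todense())
    detected = dense > 0
    rows = []
    for ct in uniq:
        mask = (labels == ct).to_numpy()
        n_in = int(mask.sum())
        if n_in < min_cells:
            warnings.warn(f"label '{ct}' has fewer than {min_cells} cells; skipped")
            continue
        in_block = dense[mask]
        out_block = dense[~mask]
        pct_in = detected[mask].mean(axis=0)
        pct_out = detected[~mask].mean(axis=0)
        logfc = in_block.mean(axis=0) - out_block.mean(axis=0)
        test = (pct_in > min_pct) & (np.abs(logfc) >= min_logfc)
        if not test.any():
            continue
        pvals = _rank_sum_pvalues(in_block[:, test], out_block[:, test])
        padj = multipletests(pvals, method="fdr_bh")[1]
        for j, gi in enumerate(np.flatnonzero(test)):
            rows.append(
                (ct, gene_pos[gi], logfc[gi], pct_in[gi], pct_out[gi], pvals[j], padj[j])
            )
    out = pd.DataFrame(
        rows,
        columns=["cell_type", "gene", "avg_logFC", "pct_in", "pct_out", "p_value", "p_adj"],
    )
    return out


def cell_type_frequencies(table: CellTable, drop_unlabeled: bool = False) -> pd.DataFrame:
    """Per-sample relative cell-type frequencies.

    Every (sample, cell type) combination is reported; absent types get
    frequency 0.  Unlabeled cells raise unless ``drop_unlabeled``.

    Returns
    -------
    FrequencyTable: DataFrame with columns sample, time_days, cell_type,
    n_cells, frequency; frequencies per sample sum to 1.
    """
    if table.label is None:
        raise ValidationError("cell-type labels are required")
    obs = table.obs
    if obs["label"].isna().any():
        if drop_unlabeled:
            obs = obs[obs["label"].notna()]
        else:
            raise ValidationError("unlabeled cells present; pass drop_unlabeled=True")
    celltypes = sorted(pd.unique(obs["label"]))
    rows = []
    for sample, grp in obs.groupby("sample", sort=False):
        total = len(grp)
        counts = grp["label"].value_counts()
        t = float(grp["time_days"].iloc[0])
        for ct in celltypes:
            n = int(counts.get(ct, 0))
            rows.append((sample, t, ct, n, n / total))
    return pd.DataFrame(
        rows, columns=["sample", "time_days", "cell_type", "n_cells", "frequency"]
    )


def scale_minmax(series) -> np.ndarray:
    """Affine rescale so min -> 0 and max -> 1 (used for per-type frequency
    trajectories).  A constant series maps to all zeros with a warning."""
    x = np.asarray(series, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        warnings.warn("constant series; min-max scaling returns zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def in_silico_bulk(table: CellTable, group_by: str = "sample") -> BulkProfile:
    """Sum raw counts over a grouping variable (default: per mouse sample),
    emulating bulk RNA-seq from single cells."""
    if group_by not in table.obs.columns:
        raise ValidationError(f"grouping column '{group_by}' not in metadata")
    groups = table.obs[group_by]
    uniq = list(pd.unique(groups))
    mat = np.zeros((len(uniq), table.n_genes))
    meta_rows = []
    for i, g in enumerate(uniq):
        idx = np.flatnonzero((groups == g).to_numpy())
        mat[i] = np.asarray(table.counts[idx].sum(axis=0)).ravel()
        sub = table.obs.iloc[idx]
        cond = "control"
        if "is_control" in sub.columns:
            cond = "control" if bool(sub["is_control"].iloc[0]) else "injured"
        elif (sub["time_days"] > 0).any():
            cond = "injured"
        meta_rows.append((cond, "insilico", float(sub["time_days"].iloc[0])))
    values = pd.DataFrame(mat, index=[str(g) for g in uniq], columns=table.gene_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["condition", "modality", "time_days"],
        index=values.index,
    )
    return BulkProfile(values=values, sample_meta=meta)
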