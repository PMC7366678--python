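"""Signature scoring of single cells.

Two schemes are provided:

* Correlation scoring against bulk-derived differential-expression
  signatures (e.g. sorted macrophage populations): per cell, the Pearson
  correlation between the signature's log fold changes over its top
  differential genes and the cell's gene-standardized (z-scaled)
  expression over the same genes.  Cells are assigned to the
  best-scoring signature only when it beats the runner-up by a strict
  margin (default 0.05); otherwise they are "unassigned".

* Gene-set (module) scores: mean expression of the set's genes minus the
  mean of control genes sampled matched on expression bin, so that
  sets of highly expressed genes are not trivially high-scoring.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import ValidationError

__all__ = [
    "scale_expression",
    "score_signature",
    "score_signatures",
    "assign_by_margin",
    "gene_set_score",
]


def scale_expression(normalized) -> np.ndarray:
    """Per-gene z-scaling across cells (mean 0, SD 1; population SD).
    Zero-variance genes map to all zeros.  Idempotent."""
    X = np.asarray(
        normalized.todense() if sp.issparse(normalized) else normalized, dtype=float
    )
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def _top_signature_genes(signature: pd.DataFrame, universe, top_n: int):
    """Select the signature's top_n most differential genes present in the
    gene universe; ranking by p-value, ties broken by |logFC|."""
    sig = signature.copy()
    if "gene" not in sig.columns or "logfc" not in sig.columns:
        raise ValidationError("signature needs 'gene' and 'logfc' columns")
    if "p_value" in sig.columns:
        sig = sig.assign(_abs=sig["logfc"].abs()).sort_values(
            ["p_value", "_abs"], ascending=[True, False]
        )
    else:
        sig = sig.assign(_abs=sig["logfc"].abs()).sort_values("_abs", ascending=False)
    sig = sig.head(top_n)
    universe = {str(g) for g in universe}
    sig = sig[sig["gene"].astype(str).isin(universe)]
    return sig


def score_signature(
    z_matrix: np.ndarray,
    gene_ids,
    signature: pd.DataFrame,
    top_n: int = 500,
    min_overlap_warn: int = 50,
) -> np.ndarray:
    """Per-cell Pearson correlation between the signature's log fold
    changes (top ``top_n`` genes, intersected with the gene universe) and
    the cell's z-scaled expression over those genes.

    ``signature`` is a DataFrame with columns gene, logfc and optionally
    p_value (used for the top-N ranking).  Fewer than 3 overlapping genes
    is an error; fewer than ``min_overlap_warn`` warns.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    sig = _top_signature_genes(signature, gene_ids, top_n)
    if len(sig) < 3:
        raise ValidationError("fewer than 3 signature genes overlap the gene universe")
    if len(sig) < min_overlap_warn:
        warnings.warn(f"only {len(sig)} signature genes overlap the gene universe")
    pos = {str(g): i for i, g in enumerate(gene_ids)}
    idx = np.array([pos[str(g)] for g in sig["gene"]])
    v = sig["logfc"].to_numpy(dtype=float)
    Z = np.asarray(z_matrix, dtype=float)[:, idx]

    vc = v - v.mean()
    zc = Z - Z.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(zc, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, zc @ vc / np.where(denom > 0, denom, 1.0), 0.0)
    return scores


def score_signatures(
    z_matrix: np.ndarray, gene_ids, signatures: dict, top_n: int = 500
) -> pd.DataFrame:
    """Score several named signatures; returns a cells x signatures frame."""
    if len(signatures) < 2:
        raise ValidationError("need at least two signatures for assignment")
    return pd.DataFrame(
        {
            name: score_signature(z_matrix, gene_ids, sig, top_n=top_n)
            for name, sig in signatures.items()
        }
    )


def assign_by_margin(scores: pd.DataFrame, margin: float = 0.05) -> pd.Series:
    """Assign each cell to its best-scoring signature when the best score
    exceeds the second best by strictly more than ``margin``; otherwise
    "unassigned".  Ties are therefore unassigned."""
    if scores.shape[1] < 2:
        raise ValidationError("need at least two signature scores")
    arr = scores.to_numpy(dtype=float)
    order = np.argsort(-arr, axis=1)
    best = order[:, 0]
    top = arr[np.arange(len(arr)), best]
    second = arr[np.arange(len(arr)), order[:, 1]]
    labels = np.where(
        top - second > margin, scores.columns.to_numpy(dtype=object)[best], "unassigned"
    )
    return pd.Series(labels, index=scores.index, name="assigned")


def gene_set_score(
    normalized,
    gene_ids,
    gene_set,
    n_bins: int = 25,
    n_control: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched gene-set (module) score per cell.

    Genes are binned by mean expression into ``n_bins`` equal-size bins;
    for every set gene, ``n_control`` control genes are sampled from its
    bin (set genes excluded).  Score = mean expression over the set minus
    mean over the control pool.  Deterministic under a fixed seed.
    """
    X = np.asarray(
        normalized.todense() if sp.issparse(normalized) else normalized, dtype=float
    )
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {str(g): i for i, g in enumerate(gene_ids)}
    set_idx = np.array(sorted(pos[str(g)] for g in gene_set if str(g) in pos))
    if len(set_idx) < 2:
        raise ValidationError("gene set has fewer than 2 genes in the universe")
    rng = np.random.default_rng(seed)
    means = X.mean(axis=0)
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(gene_ids), dtype=int)
    bins[order] = np.floor(
        np.arange(len(gene_ids)) * n_bins / len(gene_ids)
    ).astype(int)
    set_mask = np.zeros(len(gene_ids), dtype=bool)
    set_mask[set_idx] = True
    controls = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~set_mask)
        if len(pool) == 0:
            continue
        take = min(n_control, len(pool))
        controls.append(rng.choice(pool, size=take, replace=False))
    if not controls:
        raise ValidationError("no control genes available; reduce n_bins")
    ctrl_idx = np.unique(np.concatenate(controls))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
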