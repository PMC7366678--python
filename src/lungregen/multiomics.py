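"""Cross-modality integration of bulk profiles.

In silico bulk and tissue bulk RNA counts are put on a log2
counts-per-million scale (voom-style pseudocount: log2((count + 0.5) /
(total + 1) * 1e6)); proteomics-like profiles enter as already-log
intensities.  Profiles are merged on the shared gene set, quantile
normalized (every sample forced onto the mean order-statistic
distribution), and summarized by column-centered PCA and pairwise
Pearson correlation.  Fold changes measured with error on both axes are
compared by Deming (errors-in-variables) regression with error-variance
ratio lambda.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import BulkProfile, ValidationError

__all__ = [
    "logcpm",
    "quantile_normalize",
    "pca",
    "merge_modalities",
    "crossmodal_correlation",
    "deming_fit",
]


def logcpm(bulk: BulkProfile) -> BulkProfile:
    """log2 counts-per-million with the voom pseudocount convention:
    ``log2((count + 0.5) / (total + 1) * 1e6)``."""
    values = bulk.values
    if (values < 0).to_numpy().any():
        raise ValidationError("counts must be nonnegative")
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"sample '{bad}' has zero total counts")
    out = np.log2((values + 0.5).div(totals + 1.0, axis=0) * 1e6)
    return BulkProfile(values=out, sample_meta=bulk.sample_meta.copy())


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (rows = samples).

    Each sample's values are replaced by the mean of the order statistics
    across samples at the same rank; ties receive the average of the
    values they span.  After normalization every sample's sorted value
    vector is identical; within-sample ranks are preserved.
    """
    df = pd.DataFrame(matrix)
    if df.isna().to_numpy().any():
        raise ValidationError("missing values; restrict to the shared gene set first")
    if df.shape[0] == 1:
        warnings.warn("single sample; quantile normalization is the identity")
        return df.copy()
    X = df.to_numpy(dtype=float)
    n_samp, n_genes = X.shape
    mean_sorted = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n_samp):
        ranks = rankdata(X[i], method="average")  # 1..n, ties averaged
        out[i] = np.interp(ranks, np.arange(1, n_genes + 1), mean_sorted)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def pca(matrix, n_components: int | None = None):
    """Column-centered PCA by SVD.

    Returns (scores, loadings, variance_fractions); scores have zero
    column means and components carry a deterministic sign (the
    largest-magnitude loading element is positive).  ``n_components``
    beyond the matrix rank is truncated with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least 2 samples for PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    rank = int((s > tol).sum())
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncated")
        n_components = rank
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| entry positive per component
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    total_var = (Xc**2).sum()
    varfrac = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return scores, Vt.T, varfrac


def merge_modalities(profiles, quantile: bool = True) -> BulkProfile:
    """Merge bulk profiles on their shared gene set (exact identifier
    match), optionally quantile normalizing the combined matrix."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles to merge")
    shared = profiles[0].values.columns
    for p in profiles[1:]:
        shared = shared.intersection(p.values.columns)
    if len(shared) == 0:
        raise ValidationError("no shared genes across profiles")
    values = pd.concat([p.values[shared] for p in profiles], axis=0)
    meta = pd.concat([p.sample_meta for p in profiles], axis=0)
    if values.index.duplicated().any():
        raise ValidationError("duplicate sample ids across profiles")
    if quantile:
        values = quantile_normalize(values)
    return BulkProfile(values=values, sample_meta=meta)


def crossmodal_correlation(profiles) -> pd.DataFrame:
    """Pairwise Pearson correlation over all samples of all modalities on
    the shared gene set.  Constant samples give NaN rows, flagged."""
    merged = merge_modalities(profiles, quantile=False)
    X = merged.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = merged.values.index[sd == 0].tolist()
        warnings.warn(f"constant samples with undefined correlation: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    return pd.DataFrame(corr, index=merged.values.index, columns=merged.values.index)


def deming_fit(x, y, lam: float = 1.0):
    """Closed-form Deming (errors-in-variables) regression.

    ``lam`` is the ratio of error variances (y over x); lam = 1 is
    orthogonal / total least squares.  With sample (co)variances s_xx,
    s_yy, s_xy:

        slope = (s_yy - lam*s_xx + sqrt((s_yy - lam*s_xx)^2 + 4*lam*s_xy^2))
                / (2*s_xy)
        intercept = ybar - slope * xbar
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need >= 3 paired points")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        raise ValidationError("zero covariance: Deming slope orientation undefined")
    d = syy - lam * sxx
    slope = (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)
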