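"""Marker-set Kolmogorov-Smirnov deconvolution of bulk fold changes.

Cell types whose frequency shifts between two bulk conditions drag the
fold changes of their marker genes away from the background distribution.
Per cell type, the positively qualifying markers (positive log fold
change, adjusted p below 0.25) are tested for enrichment in the bulk
fold-change distribution against all other genes with a two-sided
two-sample KS test; the result is a volcano-style table of mean marker
fold change versus -log10 p, with p floored at 1e-50.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .core import BulkProfile, ValidationError

__all__ = [
    "select_deconv_markers",
    "ks_enrichment",
    "deconvolve",
    "bulk_log2_fold_changes",
    "P_FLOOR",
]

P_FLOOR = 1e-50


def select_deconv_markers(
    markers: pd.DataFrame, max_padj: float = 0.25
) -> dict:
    """Per cell type, marker genes with positive average log fold change and
    adjusted p-value below ``max_padj``.  Types with no qualifying marker
    are dropped with a warning."""
    out = {}
    for ct, grp in markers.groupby("cell_type"):
        sel = grp.loc[(grp["avg_logFC"] > 0) & (grp["p_adj"] < max_padj), "gene"]
        genes = sorted(map(str, sel.unique()))
        if genes:
            out[str(ct)] = genes
        else:
            warnings.warn(f"cell type '{ct}' has no qualifying deconvolution markers")
    return out


def bulk_log2_fold_changes(
    bulk: BulkProfile, cond_a: str = "injured", cond_b: str = "control"
) -> pd.Series:
    """Per-gene log2 fold change of (CPM+1) condition means, a vs b."""
    cond = bulk.sample_meta["condition"]
    a = bulk.values.loc[(cond == cond_a).to_numpy()]
    b = bulk.values.loc[(cond == cond_b).to_numpy()]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(f"conditions '{cond_a}'/'{cond_b}' not both present")

    def cpm(frame):
        totals = frame.sum(axis=1)
        return frame.div(totals, axis=0) * 1e6

    return np.log2(cpm(a).mean(axis=0) + 1.0) - np.log2(cpm(b).mean(axis=0) + 1.0)


def ks_enrichment(bulk_fold_changes: pd.Series, marker_set) -> tuple:
    """Two-sided two-sample KS of marker fold changes vs all other genes.

    Returns (D, p, mean_fc) with p floored at ``P_FLOOR``.  Requires at
    least 2 markers with fold changes and 10 background genes.
    """
    fc = pd.Series(bulk_fold_changes).dropna()
    marker_set = {str(g) for g in marker_set}
    in_mask = fc.index.astype(str).isin(marker_set)
    x = fc[in_mask].to_numpy(dtype=float)
    y = fc[~in_mask].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 marker genes with fold changes")
    if len(y) < 10:
        raise ValidationError("need at least 10 background genes")
    res = ks_2samp(x, y, alternative="two-sided")
    p = max(float(res.pvalue), P_FLOOR)
    return float(res.statistic), p, float(x.mean())


def deconvolve(bulk_fold_changes: pd.Series, marker_sets: dict) -> pd.DataFrame:
    """Volcano table of the KS deconvolution over all cell types.

    Returns
    -------
    DeconvResult: DataFrame indexed by cell type with columns mean_fc,
    ks_stat, p_value, neg_log10_p, n_markers.  Types whose marker sets
    yield fewer than 2 genes with fold changes are skipped with a warning.
    """
    rows = {}
    for ct, genes in marker_sets.items():
        try:
            d, p, mean_fc = ks_enrichment(bulk_fold_changes, genes)
        except ValidationError as exc:
            warnings.warn(f"cell type '{ct}' skipped: {exc}")
            continue
        n = int(pd.Series(bulk_fold_changes).index.astype(str).isin(set(genes)).sum())
        rows[ct] = {
            "mean_fc": mean_fc,
            "ks_stat": d,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "n_markers": n,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cell_type")
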