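"""Tests for transitional cell states.

Two questions about a candidate intermediate state are covered:

* Is it a linear expression mixture of two parent states?  Pseudo-bulk
  samples are built by summing counts of randomly drawn cells per
  cluster; artificial "doublet" samples aggregate equal numbers of cells
  from the two parents.  After joint log2-CPM normalization and PCA, the
  relative off-line distance rho of each sample — perpendicular distance
  to the segment joining the parent centroids, divided by the length of
  that segment, in top-k PC space — quantifies orthogonality: true
  mixtures sit near the segment (rho ~ 0), a genuinely distinct state
  maps off-axis (large rho).

* Is a gene transcriptionally induced?  The per-cell log2 ratio of
  unspliced over spliced counts (one added to both) is compared between
  two cell groups with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BulkProfile, CellTable, ValidationError
from .multiomics import pca

__all__ = [
    "make_insilico_bulks",
    "make_doublet_bulks",
    "orthogonality_test",
    "splice_ratio_test",
    "OrthogonalityResult",
]


def _sample_and_sum(table, idx_pool, n_cells, rng):
    """Sum counts of n_cells cells drawn from idx_pool (without replacement
    when possible).  Returns (vector, with_replacement flag)."""
    replace = len(idx_pool) < n_cells
    chosen = rng.choice(idx_pool, size=n_cells, replace=replace)
    vec = np.asarray(table.counts[chosen].sum(axis=0)).ravel()
    return vec, replace


def make_insilico_bulks(
    table: CellTable, clusters, n_cells: int = 600, reps: int = 5, seed: int = 0
) -> BulkProfile:
    """Pure pseudo-bulk samples: ``reps`` per cluster, each the count sum of
    ``n_cells`` randomly selected cells of that cluster.

    Sampling is without replacement when the cluster is large enough,
    otherwise with replacement (flagged in the sample metadata).
    """
    if table.label is None:
        raise ValidationError("cell-type labels are required")
    rng = np.random.default_rng(seed)
    labels = table.label.to_numpy()
    rows, meta = [], []
    for cl in clusters:
        pool = np.flatnonzero(labels == cl)
        if len(pool) == 0:
            raise ValidationError(f"unknown cluster '{cl}'")
        if len(pool) < n_cells:
            warnings.warn(f"cluster '{cl}' has {len(pool)} < {n_cells} cells; sampling with replacement")
        for r in range(reps):
            vec, replaced = _sample_and_sum(table, pool, n_cells, rng)
            rows.append(vec)
            meta.append((f"{cl}_rep{r}", str(cl), "pure", replaced))
    values = pd.DataFrame(
        rows, index=[m[0] for m in meta], columns=table.gene_ids
    )
    sample_meta = pd.DataFrame(
        {
            "cluster": [m[1] for m in meta],
            "kind": [m[2] for m in meta],
            "with_replacement": [m[3] for m in meta],
            "condition": [m[1] for m in meta],
            "modality": "insilico",
        },
        index=values.index,
    )
    return BulkProfile(values=values, sample_meta=sample_meta)


def make_doublet_bulks(
    table: CellTable,
    parent_a: str,
    parent_b: str,
    n_each: int = 300,
    reps: int = 5,
    seed: int = 0,
) -> BulkProfile:
    """Artificial linear-mixture samples: each sums ``n_each`` cells from
    each of the two parent clusters."""
    if table.label is None:
        raise ValidationError("cell-type labels are required")
    rng = np.random.default_rng(seed)
    labels = table.label.to_numpy()
    pools = {}
    for cl in (parent_a, parent_b):
        pool = np.flatnonzero(labels == cl)
        if len(pool) == 0:
            raise ValidationError(f"unknown cluster '{cl}'")
        pools[cl] = pool
    rows, meta = [], []
    for r in range(reps):
        va, ra = _sample_and_sum(table, pools[parent_a], n_each, rng)
        vb, rb = _sample_and_sum(table, pools[parent_b], n_each, rng)
        rows.append(va + vb)
        meta.append((f"doublet_{parent_a}+{parent_b}_rep{r}", ra or rb))
    values = pd.DataFrame(rows, index=[m[0] for m in meta], columns=table.gene_ids)
    sample_meta = pd.DataFrame(
        {
            "cluster": f"{parent_a}+{parent_b}",
            "kind": "doublet",
            "parent_a": str(parent_a),
            "parent_b": str(parent_b),
            "with_replacement": [m[1] for m in meta],
            "condition": "doublet",
            "modality": "insilico",
        },
        index=values.index,
    )
    return BulkProfile(values=values, sample_meta=sample_meta)


@dataclass
class OrthogonalityResult:
    """PC scores and relative off-line distances of pseudo-bulk samples."""

    scores: pd.DataFrame          # samples x PCs with group annotation
    rho: pd.Series                # per sample
    axis_coord: pd.Series         # projection coefficient along the parent axis
    median_rho_doublet: float
    median_rho_query: float
    variance_fractions: np.ndarray


def _normalize_bulks(values: pd.DataFrame, normalization: str) -> pd.DataFrame:
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("pseudo-bulk sample with zero total counts")
    cpm = values.div(totals, axis=0) * 1e6
    if normalization == "log2cpm":
        return np.log2(cpm + 1.0)
    if normalization == "cpm":
        return cpm
    raise ValidationError("normalization must be 'log2cpm' or 'cpm'")


def relative_offline_distance(X: np.ndarray, cent_a: np.ndarray, cent_b: np.ndarray):
    """Relative off-line distance rho of each row of X: perpendicular
    distance to the *segment* joining the two centroids, divided by the
    centroid distance (so points beyond either endpoint also register as
    off-axis).  Also returns the projection coefficient along the axis
    (0 at cent_a, 1 at cent_b)."""
    axis = np.asarray(cent_b, dtype=float) - np.asarray(cent_a, dtype=float)
    axis_len = np.linalg.norm(axis)
    if axis_len < 1e-12:
        raise ValidationError("parent centroids coincide; mixture axis is degenerate")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    tcoord = (X - cent_a) @ axis / axis_len**2
    proj = cent_a[None, :] + np.clip(tcoord, 0.0, 1.0)[:, None] * axis[None, :]
    rho = np.linalg.norm(X - proj, axis=1) / axis_len
    return rho, tcoord


def orthogonality_test(
    pure_bulks: BulkProfile,
    doublet_bulks: BulkProfile,
    query_bulks: BulkProfile,
    k_pcs: int = 2,
    normalization: str = "log2cpm",
) -> OrthogonalityResult:
    """Quantify whether query samples are linear mixtures of two parents.

    All pseudo-bulk samples are jointly normalized and subjected to PCA;
    in the top ``k_pcs`` PC space, each sample's rho is its perpendicular
    distance to the *segment* joining the two parent centroids divided by
    the distance between the centroids.  True mixtures yield small rho,
    an orthogonal expression program a large one.

    ``normalization="log2cpm"`` (default) matches the PCA view the figure
    claim is about; note that a count-space mixture is *not* an exact
    affine combination after a log transform (Jensen curvature bows
    mixtures slightly off the segment, while a dominant orthogonal
    program still separates cleanly).  Under ``normalization="cpm"`` a
    count mixture is an exact convex combination of the parent profiles,
    so noiseless doublets have rho = 0 to machine precision.
    """
    pa = doublet_bulks.sample_meta["parent_a"].iloc[0]
    pb = doublet_bulks.sample_meta["parent_b"].iloc[0]
    pure_clusters = set(pure_bulks.sample_meta["cluster"])
    if not {pa, pb} <= pure_clusters:
        raise ValidationError("pure bulks must include both parent clusters")

    frames = []
    for prof, kind in ((pure_bulks, "pure"), (doublet_bulks, "doublet"), (query_bulks, "query")):
        f = prof.values.copy()
        f.index = pd.MultiIndex.from_arrays(
            [[kind] * len(f), prof.sample_meta["cluster"].tolist(), f.index],
            names=("kind", "cluster", "sample"),
        )
        frames.append(f)
    merged = pd.concat(frames, axis=0)
    norm = _normalize_bulks(merged, normalization)

    scores, _, varfrac = pca(norm.to_numpy(), n_components=k_pcs)
    pcs = pd.DataFrame(
        scores, index=merged.index, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )
    kind = pcs.index.get_level_values("kind")
    cluster = pcs.index.get_level_values("cluster")
    cent_a = pcs[(kind == "pure") & (cluster == pa)].mean(axis=0).to_numpy()
    cent_b = pcs[(kind == "pure") & (cluster == pb)].mean(axis=0).to_numpy()
    rho_arr, tcoord = relative_offline_distance(pcs.to_numpy(), cent_a, cent_b)
    rho = pd.Series(rho_arr, index=pcs.index)
    axis_coord = pd.Series(tcoord, index=pcs.index)

    out = pcs.reset_index()
    return OrthogonalityResult(
        scores=out,
        rho=rho,
        axis_coord=axis_coord,
        median_rho_doublet=float(rho[kind == "doublet"].median()),
        median_rho_query=float(rho[kind == "query"].median()),
        variance_fractions=varfrac,
    )


def splice_ratio_test(table: CellTable, gene: str, group_a_cells, group_b_cells):
    """Per-cell log2((unspliced+1)/(spliced+1)) ratios for one gene and a
    two-sided Wilcoxon rank-sum test between two cell groups.

    Returns (ratios_a, ratios_b, p_value).  ``group_*_cells`` are boolean
    masks or integer indices over the table's cells.
    """
    for layer in ("spliced", "unspliced"):
        if layer not in table.layers:
            raise ValidationError(f"layer '{layer}' is required")
    gi = table.gene_index(gene)
    s = np.asarray(table.layers["spliced"][:, gi].todense()).ravel()
    u = np.asarray(table.layers["unspliced"][:, gi].todense()).ravel()
    r = np.log2((u + 1.0) / (s + 1.0))

    def pick(sel):
        sel = np.asarray(sel)
        return r[np.flatnonzero(sel)] if sel.dtype == bool else r[sel]

    ra, rb = pick(group_a_cells), pick(group_b_cells)
    if len(ra) == 0 or len(rb) == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([ra, rb])
    if np.all(pooled == pooled[0]):
        p = 1.0  # all ratios identical: no evidence either way
    else:
        from .preprocess import rank_sum_p

        p = rank_sum_p(ra, rb)
    return ra, rb, p
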