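"""Time-course differential detection analysis.

Within each cell type, a gene's expression is modeled as a binomial
response at the *sample* level: the number of cells with nonzero UMI
count (k) out of all cells of that type in the sample (n).  The unit of
analysis is the mouse sample, not the cell.  Significance of temporal
change is a likelihood-ratio test between

* full model:  logit E[k/n] = intercept + offset + natural spline of time
  (df columns), and
* null model:  logit E[k/n] = intercept + offset,

where the offset is the log of the sample's mean total UMI per cell,
entering the linear predictor with fixed coefficient 1 (standard GLM
offset semantics).  The LRT statistic is referred to a chi-square with
df equal to the number of spline columns.  Candidate ambient-RNA genes
have their p-values forced to 1 in cell types where they are not
simultaneously a positive marker (adjusted p < 0.1, positive log fold
change); Benjamini-Hochberg correction is applied within each cell
type's test family after masking.

The binomial fits are a batched iteratively-reweighted-least-squares
(Newton) solver sharing the design matrix across genes, so that
thousands of genes per cell type are fitted in a few matrix operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import qr
from scipy.special import expit, xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core import CellTable, ValidationError

__all__ = [
    "natural_spline_basis",
    "fit_detection_model",
    "lrt_temporal",
    "mask_ambient",
    "run_temporal_de",
    "build_detection_summary",
    "FitResult",
]


# -- natural spline basis ----------------------------------------------------

def natural_spline_basis(times, df: int = 2, knots=None, boundary_knots=None) -> np.ndarray:
    """Natural cubic spline basis of the time variable with ``df`` columns.

    Construction follows the R ``splines::ns`` convention: cubic B-splines
    with boundary knots at the observed extremes (linear extrapolation
    beyond them), ``df - 1`` interior knots at quantiles of the supplied
    times, and the two second-derivative-at-boundary constraints absorbed
    by a null-space projection.  The returned columns exclude the constant
    (an intercept is fitted separately) and are linearly independent on
    any set of at least ``df + 1`` distinct times.
    """
    t = np.asarray(times, dtype=float)
    distinct = np.unique(t)
    if df < 1:
        raise ValidationError("df must be >= 1")
    if len(distinct) < df + 1:
        raise ValidationError(
            f"need at least {df + 1} distinct time values for df={df}, got {len(distinct)}"
        )
    if boundary_knots is None:
        lo, hi = distinct[0], distinct[-1]
    else:
        lo, hi = boundary_knots
    if knots is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        knots = np.quantile(t, probs) if len(probs) else np.array([])
    knots = np.asarray(knots, dtype=float)

    full_knots = np.concatenate([[lo] * 4, knots, [hi] * 4])
    n_basis = len(knots) + 4

    # evaluate B-splines with linear extrapolation beyond the boundary:
    # f(x) = f(b) + f'(b) (x - b) outside [lo, hi]
    def design(x):
        x = np.asarray(x, dtype=float)
        inside = np.clip(x, lo, hi)
        D = BSpline.design_matrix(inside, full_knots, 3).toarray()
        below, above = x < lo, x > hi
        if below.any() or above.any():
            for bound, mask in ((lo, below), (hi, above)):
                if mask.any():
                    base = BSpline.design_matrix(np.array([bound]), full_knots, 3).toarray()[0]
                    deriv = _bspline_deriv_row(full_knots, bound)
                    D[mask] = base + np.outer(x[mask] - bound, deriv)
        return D

    def _bspline_deriv_row(kn, x0):
        row = np.empty(n_basis)
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            row[j] = BSpline(kn, c, 3, extrapolate=True).derivative(1)(x0)
        return row

    # second-derivative constraint rows at the boundary knots
    C = np.empty((2, n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        spl = BSpline(full_knots, c, 3, extrapolate=True).derivative(2)
        C[0, j] = spl(lo)
        C[1, j] = spl(hi)
    Q, _ = qr(C.T, mode="full")
    null_basis = Q[:, 2:]  # (n_basis, n_basis - 2): natural-spline coefficient space

    H = design(t) @ null_basis  # spans natural splines incl. constants
    # remove the constant direction (intercept handled by the model) and
    # return an orthogonal basis of the remainder.  The rotation comes from
    # the Gram matrix, which depends only on the multiset of times, so the
    # basis is permutation-equivariant in the time vector.
    Hc = H - H.mean(axis=0, keepdims=True)
    gram = Hc.T @ Hc
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12))
    if rank < df:
        raise ValidationError("time values do not support the requested df")
    for j in range(df):  # deterministic sign
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1.0
    return Hc @ evecs[:, :df]


# -- detection summaries -----------------------------------------------------

def build_detection_summary(table: CellTable, cell_type: str) -> dict:
    """Per-sample detection summary for one cell type.

    Returns a dict with ``k`` (genes x samples detected-cell counts),
    ``n`` (cells of the type per sample), ``times`` (days), ``offsets``
    (log mean total UMI per cell of that type in the sample) and
    ``samples``.
    """
    if table.label is None:
        raise ValidationError("cell-type labels are required")
    mask = (table.label == cell_type).to_numpy()
    if not mask.any():
        raise ValidationError(f"no cells labeled '{cell_type}'")
    sub = table.subset_cells(mask)
    detected = sub.counts.copy()
    detected.data = np.ones_like(detected.data)
    totals = sub.total_counts()
    samples = list(pd.unique(sub.obs["sample"]))
    S = len(samples)
    k = np.zeros((table.n_genes, S), dtype=np.int64)
    n = np.zeros(S, dtype=np.int64)
    times = np.zeros(S)
    offsets = np.zeros(S)
    for j, s in enumerate(samples):
        idx = np.flatnonzero((sub.obs["sample"] == s).to_numpy())
        n[j] = len(idx)
        k[:, j] = np.asarray(detected[idx].sum(axis=0)).ravel()
        times[j] = float(sub.obs["time_days"].iloc[idx[0]])
        offsets[j] = np.log(totals[idx].mean())
    return {"k": k, "n": n, "times": times, "offsets": offsets, "samples": samples}


# -- batched binomial IRLS ---------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of the sample-level binomial detection model."""

    coef: np.ndarray        # (genes, p)
    loglik: np.ndarray      # (genes,) maximized binomial log-likelihood (no constant)
    converged: np.ndarray   # (genes,) bool
    flagged: np.ndarray     # (genes,) bool: penalized fallback used
    design: np.ndarray      # (samples, p)
    offsets: np.ndarray     # (samples,)

    @property
    def n_params(self) -> int:
        return self.design.shape[1]


_MAX_ETA = 30.0  # linear-predictor clip; beyond this mu under/overflows


def _binom_loglik(k, n, eta):
    mu = expit(np.clip(eta, -_MAX_ETA, _MAX_ETA))
    return (xlogy(k, mu) + xlogy(n - k, 1.0 - mu)).sum(axis=-1)


def fit_detection_model(
    k: np.ndarray,
    n: np.ndarray,
    offsets: np.ndarray,
    basis: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 1e-6,
) -> FitResult:
    """Fit binomial logit regressions of k/n on [intercept (+ spline basis)]
    with the offset entering at fixed coefficient 1, batched over genes.

    ``k`` may be (genes, samples) or a single (samples,) vector.  Fitting is
    iteratively reweighted least squares (Newton) to gradient max-norm
    below ``tol`` or ``max_iter`` iterations.  Genes whose Hessian becomes
    singular or that fail to converge (complete separation, boundary fits)
    are refitted with a weak ridge penalty on the non-intercept columns and
    flagged; their log-likelihoods are retained.
    """
    k = np.atleast_2d(np.asarray(k, dtype=float))
    n = np.asarray(n, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValidationError("offsets must be finite")
    if (k < 0).any() or (k > n[None, :]).any():
        raise ValidationError("need 0 <= k <= n")
    S = len(n)
    if basis is None:
        X = np.ones((S, 1))
    else:
        basis = np.atleast_2d(np.asarray(basis, dtype=float))
        if basis.shape[0] != S:
            raise ValidationError("basis rows must match number of samples")
        X = np.column_stack([np.ones(S), basis])
    G, P = k.shape[0], X.shape[1]

    pen = np.zeros(P)
    pen[1:] = ridge

    def solve(beta, penalized):
        active = np.ones(G, dtype=bool)
        singular = np.zeros(G, dtype=bool)
        for _ in range(max_iter):
            if not active.any():
                break
            eta = beta @ X.T + offsets[None, :]
            eta = np.clip(eta, -_MAX_ETA, _MAX_ETA)
            mu = expit(eta)
            w = n[None, :] * mu * (1.0 - mu)
            grad = (k - n[None, :] * mu) @ X
            if penalized:
                grad = grad - beta * pen[None, :]
            done = np.abs(grad).max(axis=1) < tol
            active = active & ~done
            idx = np.flatnonzero(active)
            if len(idx) == 0:
                break
            A = np.einsum("sp,gs,sq->gpq", X, w[idx], X)
            if penalized:
                A = A + np.diag(pen)[None, :, :]
            else:
                A = A + np.eye(P)[None, :, :] * 1e-12
            try:
                step = np.linalg.solve(A, grad[idx][:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = np.zeros((len(idx), P))
                for i, gi in enumerate(idx):
                    try:
                        step[i] = np.linalg.solve(A[i], grad[gi])
                    except np.linalg.LinAlgError:
                        singular[gi] = True
            step = np.clip(step, -10.0, 10.0)  # damp huge separation steps
            beta[idx] += step
        eta = np.clip(beta @ X.T + offsets[None, :], -_MAX_ETA, _MAX_ETA)
        mu = expit(eta)
        grad = (k - n[None, :] * mu) @ X
        if penalized:
            grad = grad - beta * pen[None, :]
        converged = np.abs(grad).max(axis=1) < max(tol, 1e-6)
        return beta, converged, singular

    # moment start: pooled detection rate per gene
    with np.errstate(divide="ignore"):
        p0 = np.clip(k.sum(axis=1) / max(n.sum(), 1), 1e-4, 1 - 1e-4)
    beta = np.zeros((G, P))
    beta[:, 0] = np.log(p0 / (1 - p0)) - offsets.mean()

    beta, converged, singular = solve(beta.copy(), penalized=False)
    flagged = ~converged | singular
    if flagged.any():
        beta[flagged] = solve_subset(k[flagged], n, offsets, X, pen, tol, max_iter)
    eta = beta @ X.T + offsets[None, :]
    ll = _binom_loglik(k, n, eta)
    return FitResult(
        coef=beta, loglik=ll, converged=converged | flagged, flagged=flagged,
        design=X, offsets=offsets,
    )


def solve_subset(k, n, offsets, X, pen, tol, max_iter):
    """Ridge-penalized Newton refit for flagged genes (separation fallback)."""
    G, P = k.shape[0], X.shape[1]
    beta = np.zeros((G, P))
    with np.errstate(divide="ignore"):
        p0 = np.clip(k.sum(axis=1) / max(n.sum(), 1), 1e-4, 1 - 1e-4)
    beta[:, 0] = np.log(p0 / (1 - p0)) - offsets.mean()
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offsets[None, :], -_MAX_ETA, _MAX_ETA)
        mu = expit(eta)
        w = n[None, :] * mu * (1.0 - mu) + 1e-10
        grad = (k - n[None, :] * mu) @ X - beta * pen[None, :]
        if np.abs(grad).max() < tol:
            break
        A = np.einsum("sp,gs,sq->gpq", X, w, X) + np.diag(pen + 1e-10)[None, :, :]
        step = np.linalg.solve(A, grad[:, :, None])[:, :, 0]
        beta += np.clip(step, -10.0, 10.0)
    return beta


# -- likelihood-ratio test ---------------------------------------------------

def lrt_temporal(full_fit: FitResult, null_fit: FitResult, df: int | None = None):
    """Likelihood-ratio test of the spline model against the offset-only null.

    Lambda = 2 (ll_full - ll_null), clipped at zero; p from chi-square with
    df = number of spline columns.  The fits must share offsets (nesting).
    """
    if full_fit.offsets.shape != null_fit.offsets.shape or not np.allclose(
        full_fit.offsets, null_fit.offsets
    ):
        raise ValidationError("fits are not nested: offsets differ")
    if full_fit.n_params <= null_fit.n_params:
        raise ValidationError("full model must have more parameters than the null")
    if df is None:
        df = full_fit.n_params - null_fit.n_params
    lam = np.clip(2.0 * (full_fit.loglik - null_fit.loglik), 0.0, None)
    p = chi2.sf(lam, df)
    return lam, p


# -- ambient masking ---------------------------------------------------------

def mask_ambient(
    results: pd.DataFrame,
    ambient_genes,
    markers: pd.DataFrame,
    marker_fdr: float = 0.1,
) -> pd.DataFrame:
    """Force p = 1 for candidate ambient genes in cell types where the gene
    is not simultaneously a positive marker (p_adj < ``marker_fdr`` and
    avg_logFC > 0).  Idempotent; adds/updates the ``masked`` flag."""
    ambient = {str(g) for g in ambient_genes}
    known = set(map(str, results["gene"].unique()))
    for g in sorted(ambient - known):
        warnings.warn(f"ambient gene '{g}' absent from the tested gene universe")
    qualifying = set(
        zip(
            markers.loc[
                (markers["p_adj"] < marker_fdr) & (markers["avg_logFC"] > 0), "cell_type"
            ].astype(str),
            markers.loc[
                (markers["p_adj"] < marker_fdr) & (markers["avg_logFC"] > 0), "gene"
            ].astype(str),
        )
    )
    out = results.copy()
    if "masked" not in out.columns:
        out["masked"] = False
    is_amb = out["gene"].astype(str).isin(ambient)
    is_marker = [
        (str(ct), str(g)) in qualifying
        for ct, g in zip(out["cell_type"], out["gene"])
    ]
    to_mask = is_amb & ~pd.Series(is_marker, index=out.index)
    out.loc[to_mask, "p_value"] = 1.0
    out.loc[to_mask, "masked"] = True
    return out


# -- full pipeline per cell type --------------------------------------------

def run_temporal_de(
    table: CellTable,
    ambient_genes=(),
    markers: pd.DataFrame | None = None,
    fdr_threshold: float = 0.1,
    df: int = 2,
    family: str = "celltype",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Temporal differential-detection analysis over all cell types.

    Per cell type: build the detection summary, fit offset-only and spline
    models per gene, likelihood-ratio test, ambient masking, then BH
    correction within the cell type (or globally with
    ``family="global"``).  Cell types present in fewer than ``min_samples``
    samples are skipped with a warning.

    Returns
    -------
    TemporalDEResult: DataFrame with one row per (cell_type, gene):
    lrt_stat, df, p_value, fdr, masked, flagged, n_samples.
    """
    if family not in ("celltype", "global"):
        raise ValidationError("family must be 'celltype' or 'global'")
    if table.label is None:
        raise ValidationError("cell-type labels are required")
    frames = []
    for ct in sorted(pd.unique(table.label.dropna())):
        summ = build_detection_summary(table, ct)
        if len(summ["samples"]) < min_samples:
            warnings.warn(f"cell type '{ct}' present in <{min_samples} samples; skipped")
            continue
        if len(np.unique(summ["times"])) < df + 1:
            warnings.warn(f"cell type '{ct}' has too few distinct times; skipped")
            continue
        basis = natural_spline_basis(summ["times"], df=df)
        null_fit = fit_detection_model(summ["k"], summ["n"], summ["offsets"])
        full_fit = fit_detection_model(summ["k"], summ["n"], summ["offsets"], basis=basis)
        lam, p = lrt_temporal(full_fit, null_fit)
        frames.append(
            pd.DataFrame(
                {
                    "cell_type": ct,
                    "gene": table.gene_ids,
                    "lrt_stat": lam,
                    "df": basis.shape[1],
                    "p_value": p,
                    "masked": False,
                    "flagged": full_fit.flagged | null_fit.flagged,
                    "n_samples": len(summ["samples"]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "cell_type", "gene", "lrt_stat", "df", "p_value", "fdr",
                "masked", "flagged", "n_samples",
            ]
        )
    res = pd.concat(frames, ignore_index=True)
    if markers is not None and len(ambient_genes):
        res = mask_ambient(res, ambient_genes, markers)
    if family == "celltype":
        res["fdr"] = np.nan
        for ct, idx in res.groupby("cell_type").indices.items():
            res.loc[res.index[idx], "fdr"] = multipletests(
                res["p_value"].iloc[idx], method="fdr_bh"
            )[1]
    else:
        res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res["significant"] = res["fdr"] < fdr_threshold
    return res


def injury_regulated_genes(results: pd.DataFrame, fdr_threshold: float = 0.1) -> list:
    """Genes significant (FDR below threshold) in at least one cell type."""
    sig = results.loc[results["fdr"] < fdr_threshold, "gene"]
    return sorted(map(str, sig.unique()))
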