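"""Binomial detection-rate spline model: basis construction, fitting,
likelihood-ratio testing, ambient masking and end-to-end recovery."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import chi2

from lungregen.core import ValidationError
from lungregen.synthetic import simulate_detection_summaries
from lungregen.temporal_de import (
    build_detection_summary,
    fit_detection_model,
    injury_regulated_genes,
    lrt_temporal,
    mask_ambient,
    natural_spline_basis,
    run_temporal_de,
)

TIMES = np.repeat([0.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0], 4)


# -- independent de Boor oracle ----------------------------------------------

def _deboor(knots, j, k, x):
    """Cox-de Boor recursion for B_{j,k}(x) (degree k)."""
    if k == 0:
        last = knots[j + 1] == knots[-1]
        if last:
            return 1.0 if knots[j] <= x <= knots[j + 1] else 0.0
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    out = 0.0
    d1 = knots[j + k] - knots[j]
    if d1 > 0:
        out += (x - knots[j]) / d1 * _deboor(knots, j, k - 1, x)
    d2 = knots[j + k + 1] - knots[j + 1]
    if d2 > 0:
        out += (knots[j + k + 1] - x) / d2 * _deboor(knots, j + 1, k - 1, x)
    return out


def _deboor_deriv(knots, j, k, x, order):
    if order == 0:
        return _deboor(knots, j, k, x)
    out = 0.0
    d1 = knots[j + k] - knots[j]
    if d1 > 0:
        out += k / d1 * _deboor_deriv(knots, j, k - 1, x, order - 1)
    d2 = knots[j + k + 1] - knots[j + 1]
    if d2 > 0:
        out -= k / d2 * _deboor_deriv(knots, j + 1, k - 1, x, order - 1)
    return out


class TestNaturalSplineBasis:
    def test_df1_is_affine_in_time(self):
        b = natural_spline_basis(TIMES, df=1)
        assert b.shape == (len(TIMES), 1)
        assert abs(np.corrcoef(b[:, 0], TIMES)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_columns_linearly_independent_with_intercept(self):
        for df in (1, 2, 3):
            b = natural_spline_basis(TIMES, df=df)
            X = np.column_stack([np.ones(len(TIMES)), b])
            assert np.linalg.matrix_rank(X) == df + 1

    def test_matches_de_boor_bspline_oracle(self):
        """The cubic B-spline design matrix underlying the basis matches an
        independent Cox-de Boor recursion, values and curvature rows."""
        from scipy.interpolate import BSpline

        t = np.unique(TIMES)
        lo, hi = t[0], t[-1]
        interior = np.quantile(TIMES, [0.5])
        full = np.concatenate([[lo] * 4, interior, [hi] * 4])
        nb = len(interior) + 4
        D_scipy = BSpline.design_matrix(t, full, 3).toarray()
        D_oracle = np.array([[_deboor(full, j, 3, x) for j in range(nb)] for x in t])
        assert np.abs(D_scipy - D_oracle).max() < 1e-10
        for bound in (lo, hi):
            for j in range(nb):
                c = np.zeros(nb)
                c[j] = 1.0
                impl = BSpline(full, c, 3, extrapolate=True).derivative(2)(bound)
                orc = _deboor_deriv(full, j, 3, bound - 1e-12 if bound == hi else bound, 2)
                assert impl == pytest.approx(orc, abs=1e-6, rel=1e-6)

    def test_span_matches_r_ns(self, tmp_path):
        """Column span (plus intercept) agrees with R's splines::ns."""
        script = tmp_path / "ns.R"
        out = tmp_path / "ns.tsv"
        script.write_text(
            "t <- c(%s)\n" % ",".join(map(str, TIMES))
            + "b <- splines::ns(t, df = 2)\n"
            + f"write.table(unclass(b), '{out}', sep='\\t', row.names=FALSE, col.names=FALSE)\n"
        )
        try:
            subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript not available")
        r_basis = np.loadtxt(out)
        mine = natural_spline_basis(TIMES, df=2)
        A = np.column_stack([np.ones(len(TIMES)), mine])
        B = np.column_stack([np.ones(len(TIMES)), r_basis])
        for X, Y in ((A, B), (B, A)):
            resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
            assert np.abs(resid).max() < 1e-8

    def test_permutation_equivariance_and_determinism(self):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(TIMES))
        b = natural_spline_basis(TIMES, df=2)
        bp = natural_spline_basis(TIMES[perm], df=2)
        assert np.allclose(b[perm], bp, atol=1e-12)
        assert np.array_equal(b, natural_spline_basis(TIMES, df=2))

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            natural_spline_basis(np.array([0.0, 0.0, 14.0]), df=2)


class TestFitDetectionModel:
    def test_intercept_only_closed_form(self):
        fit = fit_detection_model(np.array([2, 2]), np.array([4, 4]), np.zeros(2))
        assert fit.coef[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_detection_is_boundary_safe(self):
        fit = fit_detection_model(np.zeros(6), np.full(6, 10), np.zeros(6))
        assert np.isfinite(fit.loglik).all()
        assert fit.loglik[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_glm_oracle(self):
        rng = np.random.default_rng(3)
        times = np.array([0.0, 3.0, 7.0, 14.0, 28.0])
        k = np.array([3, 5, 9, 12, 7])
        n = np.full(5, 20)
        off = rng.normal(0, 0.3, 5)
        basis = natural_spline_basis(times, df=2)
        X = np.column_stack([np.ones(5), basis])
        oracle = sm.GLM(
            np.column_stack([k, n - k]), X, family=sm.families.Binomial(), offset=off
        ).fit()
        mine = fit_detection_model(k, n, off, basis=basis)
        assert np.abs(mine.coef[0] - oracle.params).max() < 1e-6

    def test_batched_equals_per_gene(self):
        d = simulate_detection_summaries(30, seed=5)
        basis = natural_spline_basis(d["times"], df=2)
        batched = fit_detection_model(d["k"], d["n"], d["offsets"], basis=basis)
        for g in (0, 7, 29):
            single = fit_detection_model(d["k"][g], d["n"], d["offsets"], basis=basis)
            assert np.abs(batched.coef[g] - single.coef[0]).max() < 1e-8

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            fit_detection_model(np.array([5]), np.array([4]), np.zeros(1))


class TestLRT:
    def test_identical_fits_give_zero_statistic(self):
        d = simulate_detection_summaries(5, seed=1)
        basis = natural_spline_basis(d["times"], df=2)
        null = fit_detection_model(d["k"], d["n"], d["offsets"])
        full = fit_detection_model(d["k"], d["n"], d["offsets"], basis=basis)
        lam, p = lrt_temporal(full, null)
        assert (lam >= 0).all()
        # spline model never fits worse than its nested null
        assert (full.loglik >= null.loglik - 1e-8).all()

    def test_chi_square_reference(self):
        # analytic check of the reference distribution at the 5% point
        assert chi2.sf(5.991, 2) == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_offsets_rejected(self):
        d = simulate_detection_summaries(3, seed=2)
        basis = natural_spline_basis(d["times"], df=2)
        null = fit_detection_model(d["k"], d["n"], d["offsets"] + 1.0)
        full = fit_detection_model(d["k"], d["n"], d["offsets"], basis=basis)
        with pytest.raises(ValidationError, match="nested"):
            lrt_temporal(full, null)

    def test_null_calibration(self):
        d = simulate_detection_summaries(2000, cells_per_sample=30, seed=0)
        basis = natural_spline_basis(d["times"], df=2)
        null = fit_detection_model(d["k"], d["n"], d["offsets"])
        full = fit_detection_model(d["k"], d["n"], d["offsets"], basis=basis)
        _, p = lrt_temporal(full, null)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_power_monotone_in_effect_size(self):
        from statsmodels.stats.multitest import multipletests

        powers = []
        for effect in (0.5, 1.0, 2.0):
            d = simulate_detection_summaries(
                400, n_shifted=400, effect=effect, cells_per_sample=30, seed=7
            )
            basis = natural_spline_basis(d["times"], df=2)
            null = fit_detection_model(d["k"], d["n"], d["offsets"])
            full = fit_detection_model(d["k"], d["n"], d["offsets"], basis=basis)
            _, p = lrt_temporal(full, null)
            fdr = multipletests(p, method="fdr_bh")[1]
            powers.append((fdr < 0.1).mean())
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] >= 0.8


def _bh_brute_force(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


class TestBHCorrection:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [1, 7, 100])
    def test_matches_brute_force(self, seed, n):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=n) ** 2
        assert np.allclose(multipletests(p, method="fdr_bh")[1], _bh_brute_force(p))


class TestMaskAmbient:
    @pytest.fixture()
    def results_and_markers(self):
        res = pd.DataFrame(
            {
                "cell_type": ["A", "A", "B", "B"],
                "gene": ["amb1", "g1", "amb1", "g1"],
                "p_value": [0.001, 0.02, 0.003, 0.5],
            }
        )
        markers = pd.DataFrame(
            {
                "cell_type": ["A"],
                "gene": ["amb1"],
                "avg_logFC": [1.0],
                "p_adj": [0.01],
            }
        )
        return res, markers

    def test_non_marker_ambient_masked_everywhere(self, results_and_markers):
        res, _ = results_and_markers
        empty_markers = pd.DataFrame(columns=["cell_type", "gene", "avg_logFC", "p_adj"])
        out = mask_ambient(res, ["amb1"], empty_markers)
        amb = out[out["gene"] == "amb1"]
        assert (amb["p_value"] == 1.0).all() and amb["masked"].all()
        assert (out.loc[out["gene"] == "g1", "p_value"] == res.loc[res["gene"] == "g1", "p_value"].to_numpy()).all()

    def test_qualifying_marker_type_unmasked(self, results_and_markers):
        res, markers = results_and_markers
        out = mask_ambient(res, ["amb1"], markers)
        assert out.loc[(out["gene"] == "amb1") & (out["cell_type"] == "A"), "p_value"].iloc[0] == 0.001
        assert out.loc[(out["gene"] == "amb1") & (out["cell_type"] == "B"), "p_value"].iloc[0] == 1.0

    def test_idempotence(self, results_and_markers):
        res, markers = results_and_markers
        once = mask_ambient(res, ["amb1"], markers)
        twice = mask_ambient(once, ["amb1"], markers)
        pd.testing.assert_frame_equal(once, twice)

    def test_unknown_ambient_gene_warns(self, results_and_markers):
        res, markers = results_and_markers
        with pytest.warns(UserWarning, match="absent"):
            mask_ambient(res, ["ghost"], markers)


class TestRunTemporalDE:
    def test_recovers_planted_temporal_genes(self, small_sim):
        from lungregen.preprocess import find_markers, normalize_log

        _, table, truth = small_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = normalize_log(table)
            markers = find_markers(norm, table.label, gene_ids=table.gene_ids)
            res = run_temporal_de(table, truth.ambient_genes, markers)
        hits = total = 0
        for ct, genes in truth.temporal_genes.items():
            for g in genes:
                row = res[(res["cell_type"] == ct) & (res["gene"] == g)]
                total += 1
                hits += int(row["fdr"].iloc[0] < 0.1)
        assert hits / total >= 0.8
        # unplanted, non-marker, non-ambient genes: almost none significant
        planted = {g for d in truth.temporal_genes.values() for g in d}
        nulls = [
            str(g)
            for g in table.gene_ids
            if str(g) not in planted
            and str(g) not in truth.marker_assignment
            and str(g) not in truth.ambient_genes
        ]
        nd = res[res["gene"].isin(nulls)]
        assert (nd["fdr"] < 0.1).mean() < 0.02
        assert nd["fdr"].median() > 0.5
        # the injury-regulated list is exactly the genes with fdr < 0.1 somewhere
        expected = set(map(str, res.loc[res["fdr"] < 0.1, "gene"].unique()))
        assert set(injury_regulated_genes(res)) == expected

    def test_detection_summary_consistency(self, small_sim):
        _, table, _ = small_sim
        ct = table.obs["label"].iloc[0]
        summ = build_detection_summary(table, ct)
        assert (summ["k"] <= summ["n"][None, :]).all()
        assert summ["n"].sum() == (table.obs["label"] == ct).sum()
        assert np.isfinite(summ["offsets"]).all()

    def test_rare_type_skipped_with_warning(self, tiny_table):
        with pytest.warns(UserWarning):
            res = run_temporal_de(tiny_table, min_samples=3)
        assert len(res) == 0
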