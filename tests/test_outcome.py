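import numpy as np
import pytest

from micromediate.dirichlet import DirichletRegression
from micromediate.inference import _Arrays
from micromediate.outcome import (
    LogContrastRegression,
    OutcomeParams,
    PenaltyConfig,
    design_matrix,
    fit_ols,
    fit_penalized,
    refit_unpenalized,
    sum_zero_basis,
)
from micromediate.synthetic import generate_study, preset


def _design(data):
    return np.hstack([data.r[:, None], data.x, data.m])


def _noiseless_study(n=200, j=5, k=2, seed=0):
    cfg = preset("mixed", n_per_group=n // 2, n_taxa=j, n_covariates=k, noise_sd=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    data, truth = generate_study(cfg)
    out = truth["config"].outcome
    logm = np.log(data.m)
    y = (
        out.alpha0
        + data.x @ out.alpha_x
        + out.alpha_r * data.r
        + logm @ out.alpha_m
        + (logm * data.r[:, None]) @ out.alpha_c
    )
    return data, y, out


class TestBasis:
    def test_two_taxa_contrast(self):
        u = sum_zero_basis(2)
        assert u.shape == (2, 1)
        np.testing.assert_allclose(u.sum(axis=0), 0.0, atol=1e-14)
        np.testing.assert_allclose(np.abs(u[:, 0]), 1 / np.sqrt(2))

    def test_projection_idempotent(self, rng):
        j = 7
        u = sum_zero_basis(j)
        v = rng.standard_normal(j)
        proj = u @ (u.T @ v)
        np.testing.assert_allclose(u @ (u.T @ proj), proj, atol=1e-12)
        np.testing.assert_allclose(proj.sum(), 0.0, atol=1e-12)

    def test_design_matrix_shape(self, mixed_small):
        data, _ = mixed_small
        z, colmap, u = design_matrix(data)
        j, k = data.n_taxa, data.x.shape[1]
        assert z.shape == (data.n_samples, 2 + k + 2 * (j - 1))
        assert len(colmap["log_composition"]) == j - 1


class TestOLS:
    def test_noiseless_exact_recovery(self):
        data, y, out = _noiseless_study()
        est = LogContrastRegression(n_covariates=data.x.shape[1])
        est.fit(_design(data), y)
        np.testing.assert_allclose(est.alpha_m_, out.alpha_m, atol=1e-8)
        np.testing.assert_allclose(est.alpha_c_, out.alpha_c, atol=1e-8)
        np.testing.assert_allclose(est.alpha_r_, out.alpha_r, atol=1e-8)
        np.testing.assert_allclose(est.alpha_x_, out.alpha_x, atol=1e-8)

    def test_location_equivariance(self, mixed_small):
        data, _ = mixed_small
        f1 = fit_ols(data)
        shifted = np.asarray(data.meta.frame["outcome"]) + 7.5
        data.meta.frame["outcome"] = shifted
        f2 = fit_ols(data)
        data.meta.frame["outcome"] = shifted - 7.5
        assert f2.alpha0 == pytest.approx(f1.alpha0 + 7.5)
        np.testing.assert_allclose(f2.alpha_m, f1.alpha_m, atol=1e-10)
        assert f2.alpha_r == pytest.approx(f1.alpha_r, abs=1e-10)

    def test_sigma_estimation(self):
        inside = 0
        for rep in range(30):
            cfg = preset("mixed", n_per_group=250, n_taxa=5, noise_sd=1.0, seed=200 + rep)
            data, _ = generate_study(cfg)
            params = fit_ols(data)
            inside += 0.9 <= params.sigma <= 1.1
        assert inside >= 27

    def test_constraints_exact(self, mixed_medium):
        data, _ = mixed_medium
        params = fit_ols(data)
        assert abs(params.alpha_m.sum()) < 1e-10
        assert abs(params.alpha_c.sum()) < 1e-10

    def test_insufficient_samples_error(self):
        data, y, _ = _noiseless_study(n=200)
        est = LogContrastRegression(n_covariates=2)
        with pytest.raises(ValueError, match="free parameters"):
            est.fit(_design(data)[:8], y[:8])

    def test_log_contrast_scale_invariance(self, mixed_small):
        # multiplying a sample's composition by a constant (pre-normalization)
        # must not change alpha_m / alpha_c: the defining log-contrast property
        data, _ = mixed_small
        est1 = LogContrastRegression(n_covariates=data.x.shape[1])
        est1.fit(_design(data), data.y)
        rng = np.random.default_rng(0)
        scale = np.exp(rng.standard_normal(data.n_samples))
        m2 = data.m * scale[:, None]
        X2 = np.hstack([data.r[:, None], data.x, m2])
        est2 = LogContrastRegression(n_covariates=data.x.shape[1])
        est2.fit(X2, data.y)
        np.testing.assert_allclose(est2.alpha_m_, est1.alpha_m_, atol=1e-8)
        np.testing.assert_allclose(est2.alpha_c_, est1.alpha_c_, atol=1e-8)


class TestPenalized:
    def test_full_shrinkage(self, mixed_small):
        data, _ = mixed_small
        params, selected = fit_penalized(data, PenaltyConfig(lambda1=50.0, lambda2=0.0))
        assert selected.size == 0
        np.testing.assert_array_equal(params.alpha_m, 0.0)

    def test_zero_penalty_matches_ols(self, mixed_small):
        data, _ = mixed_small
        est = LogContrastRegression(
            n_covariates=data.x.shape[1], lambda1=1e-9, max_iter=50000, tol=1e-14
        )
        est.fit(_design(data), data.y)
        ols = fit_ols(data)
        np.testing.assert_allclose(est.alpha_m_, ols.alpha_m, atol=1e-4)
        np.testing.assert_allclose(est.alpha_r_, ols.alpha_r, atol=1e-4)

    def test_objective_monotone_in_iterations(self, mixed_small):
        # the solver is a monotone scheme: running it longer from the same
        # start can only lower the objective
        data, _ = mixed_small
        objs = []
        for iters in (1, 3, 5, 10, 20, 40, 100):
            est = LogContrastRegression(
                n_covariates=data.x.shape[1], lambda1=0.05, lambda2=0.02,
                beta_r=np.ones(data.n_taxa), max_iter=iters, tol=0.0,
            )
            est.fit(_design(data), data.y)
            objs.append(est.objective_)
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_sparse_recovery(self):
        # 3 active taxa of 20, strong signal: selection should find the
        # actives (sensitivity) without flooding in noise taxa (specificity)
        sens = spec = 0.0
        reps = 50
        for i in range(reps):
            data, truth = generate_study(preset("mixed", n_per_group=200, n_taxa=20, seed=500 + i))
            arr = _Arrays.from_study(data)
            d = DirichletRegression(gtol=1e-4).fit(np.column_stack([arr.r, arr.x]), arr.m)
            _, sel = fit_penalized(data, PenaltyConfig(), beta_r=d.beta_r_)
            act = set(truth["active_taxa"].tolist())
            sel = set(sel.tolist())
            sens += len(act & sel) / len(act)
            spec += (17 - len(sel - act)) / 17
        assert sens / reps >= 0.9
        assert spec / reps >= 0.8

    def test_group_weights_required(self, mixed_small):
        data, _ = mixed_small
        with pytest.raises(ValueError, match="beta_r"):
            fit_penalized(data, PenaltyConfig(lambda1=0.1, lambda2=0.1))


class TestRefit:
    def test_all_selected_equals_ols(self, mixed_small):
        data, _ = mixed_small
        full = fit_ols(data)
        refit = refit_unpenalized(data, np.arange(data.n_taxa))
        np.testing.assert_allclose(refit.alpha_m, full.alpha_m, atol=1e-10)
        np.testing.assert_allclose(refit.alpha_c, full.alpha_c, atol=1e-10)

    def test_empty_selection_reduces_to_group_difference(self):
        # with no taxa the model is Y ~ 1 + X + R: alpha_r is the
        # covariate-adjusted group difference
        data, y, out = _noiseless_study(k=0, j=4)
        import pandas as pd

        data.meta.frame["outcome"] = y
        refit = refit_unpenalized(data, np.array([], dtype=int))
        xz = np.column_stack([np.ones(len(y)), data.r])
        coef, *_ = np.linalg.lstsq(xz, y, rcond=None)
        assert refit.alpha_r == pytest.approx(coef[1], abs=1e-8)
        np.testing.assert_array_equal(refit.alpha_m, 0.0)

    def test_true_set_refit_recovery(self):
        hits = total = 0
        for rep in range(10):
            cfg = preset("mixed", n_per_group=300, n_taxa=10, seed=900 + rep)
            data, truth = generate_study(cfg)
            out = truth["config"].outcome
            refit = refit_unpenalized(data, truth["active_taxa"])
            se = refit.se
            hits += np.sum(np.abs(refit.alpha_m - out.alpha_m) < 3 * np.maximum(se["alpha_m"], 1e-12))
            total += data.n_taxa
        assert hits / total >= 0.9


class TestEstimatorProtocol:
    def test_clone_and_params(self, mixed_small):
        from sklearn.base import clone

        data, _ = mixed_small
        est = LogContrastRegression(n_covariates=1, lambda1=0.1)
        est2 = clone(est)
        assert est2.get_params()["lambda1"] == 0.1
        est2.set_params(lambda1=0.2).fit(_design(data), data.y)
        assert est2.selected_.dtype == bool

    def test_predict_consistency(self, mixed_small):
        data, _ = mixed_small
        est = LogContrastRegression(n_covariates=data.x.shape[1]).fit(_design(data), data.y)
        pred = est.predict(_design(data))
        resid_sd = np.std(data.y - pred)
        assert resid_sd < np.std(data.y)


class TestProxOperator:
    def test_compiled_prox_matches_reference(self, rng):
        # the numba prox and the pure-numpy dual solve are independent
        # implementations of the same exact operator
        from micromediate._solver import _prox_block
        from micromediate.outcome import _prox_l1_sumzero

        for _ in range(200):
            j = int(rng.integers(2, 15))
            v = rng.standard_normal(j) * rng.lognormal()
            t = float(rng.random() * 0.5)
            a = _prox_block(v, t)
            b = _prox_l1_sumzero(v, t)
            np.testing.assert_allclose(a, b, atol=1e-10)
            assert abs(a.sum()) < 1e-10

    def test_prox_optimality(self, rng):
        # KKT: result must beat nearby feasible points on the prox objective
        from micromediate._solver import _prox_block

        v = rng.standard_normal(8)
        t = 0.3
        a = _prox_block(v, t)

        def obj(u):
            return 0.5 * np.sum((u - v) ** 2) + t * np.abs(u).sum()

        for _ in range(100):
            d = rng.standard_normal(8)
            d -= d.mean()  # stay feasible
            assert obj(a) <= obj(a + 1e-3 * d) + 1e-12
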