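import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgmix.dataset import apply_transforms
from mgmix.model import MGMParameters, ParamVectorizer, neg_pseudo_loglik
from mgmix.network import collapse_edges
from mgmix.optim import (
    FitConfig,
    fit_mgm,
    kkt_violation,
    lambda_max,
    prox_step,
    regularization_path,
    select_lambda,
    soft_threshold,
)
from mgmix.simulate import gibbs_sample, make_ground_truth

from conftest import simulated_dataset
from test_model import random_params


def quiet_fit(d, cfg, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mgm(d, cfg, **kw)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,t,expected", [(1.5, 1.0, 0.5), (-0.3, 0.5, 0.0), (2.0, 0.0, 2.0), (-2.5, 1.0, -1.5)]
    )
    def test_values(self, v, t, expected):
        assert soft_threshold(v, t) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        v=st.floats(-1e6, 1e6, allow_nan=False),
        t=st.floats(0, 1e6, allow_nan=False),
    )
    def test_shrinks_toward_zero_by_at_most_t(self, v, t):
        out = soft_threshold(v, t)
        assert abs(out) <= abs(v)
        assert abs(v - out) <= t + 1e-9 * max(1.0, abs(v))
        if out != 0:
            assert np.sign(out) == np.sign(v)


class TestProxStep:
    def test_lambda_zero_is_plain_gradient_step(self):
        params = random_params(2, (2,), seed=0)
        grad = random_params(2, (2,), seed=1)
        out = prox_step(params, grad, step=0.1, lam=0.0)
        np.testing.assert_allclose(out.alpha, params.alpha - 0.1 * grad.alpha)
        np.testing.assert_allclose(out.rho, params.rho - 0.1 * grad.rho)

    def test_huge_lambda_zeroes_all_edges_from_origin(self):
        params = MGMParameters.zeros(3, (2, 2))
        grad = random_params(3, (2, 2), seed=2)
        out = prox_step(params, grad, step=1.0, lam=1e6)
        assert collapse_edges(out).n_edges() == 0
        # node potentials still take the plain step
        np.testing.assert_allclose(out.alpha, -grad.alpha)

    def test_matches_scalar_soft_threshold_oracle(self):
        params = random_params(3, (2, 3), seed=3)
        grad = random_params(3, (2, 3), seed=4)
        step, lam = 0.37, 0.21
        out = prox_step(params, grad, step, lam)
        vz = ParamVectorizer(3, (2, 3))
        v = vz.pack(params) - step * vz.pack(grad)
        expected = v.copy()
        for i in np.where(vz.penalty_mask)[0]:
            expected[i] = soft_threshold(v[i], step * lam)
        expected[vz.sl_diag] = np.minimum(expected[vz.sl_diag], -1e-4)
        np.testing.assert_allclose(vz.pack(out), expected, rtol=0, atol=1e-15)


class TestFit:
    def test_bivariate_gaussian_matches_sample_precision(self):
        truth = make_ground_truth(2, 0, (), density=1.0, weight_range=(0.4, 0.5), seed=8)
        d = gibbs_sample(truth, 1000, seed=9)
        params, _ = quiet_fit(d, FitConfig(lam=0.0, tol=1e-13, max_iter=20000))
        X = d.continuous_values - d.continuous_values.mean(axis=0)
        prec = np.linalg.inv(X.T @ X / d.n)
        assert params.beta[0, 1] == pytest.approx(-prec[0, 1], abs=1e-3)

    def test_empty_graph_at_lambda_above_lambda_max(self):
        _, d = simulated_dataset(p=4, q=2, n=250, seed=12, standardize=True)
        lmax = lambda_max(d)
        params, _ = fit_mgm(d, FitConfig(lam=1.01 * lmax, tol=1e-9, max_iter=2000))
        assert collapse_edges(params).n_edges() == 0

    def test_duplicated_variable_lambda_max_is_correlation(self, rng):
        from mgmix.dataset import MixedDataset, VariableSpec

        x = rng.normal(size=1000)
        x = (x - x.mean()) / x.std()  # MLE standardization so the gradient is exact
        d = MixedDataset(
            [VariableSpec("a", "continuous"), VariableSpec("b", "continuous")],
            np.column_stack([x, x]), np.zeros((1000, 0), int),
            [f"s{i}" for i in range(1000)],
        )
        # the tied pair parameter appears in both node regressions, so its
        # gradient is twice the empirical correlation (= 2 for a duplicate)
        assert lambda_max(d) == pytest.approx(2.0, abs=1e-9)

    def test_bitwise_deterministic(self):
        _, d = simulated_dataset(p=3, q=2, n=200, seed=13, standardize=True)
        cfg = FitConfig(lam=0.05, tol=1e-8)
        p1, _ = fit_mgm(d, cfg)
        p2, _ = fit_mgm(d, cfg)
        assert np.array_equal(p1.beta, p2.beta)
        assert np.array_equal(p1.rho, p2.rho)
        assert np.array_equal(p1.phi, p2.phi)

    def test_kkt_conditions_at_convergence(self):
        _, d = simulated_dataset(p=5, q=3, n=400, seed=14, standardize=True)
        lam = 0.3 * lambda_max(d)
        params, _ = fit_mgm(d, FitConfig(lam=lam, tol=1e-11, max_iter=20000))
        assert kkt_violation(params, d, lam) < 1e-4

    def test_objective_monotone_under_function_restart(self):
        _, d = simulated_dataset(p=4, q=2, n=300, seed=15, standardize=True)
        _, trace = fit_mgm(d, FitConfig(lam=0.02, tol=1e-10, max_iter=5000))
        assert np.all(np.diff(trace.objective) <= 1e-12)

    def test_fista_matches_ista_and_is_no_slower(self):
        _, d = simulated_dataset(p=5, q=2, n=400, seed=16, standardize=True)
        lam = 0.2 * lambda_max(d)
        # converged solutions agree ...
        fista, tr_f = fit_mgm(d, FitConfig(lam=lam, tol=1e-10, max_iter=50000))
        ista, tr_i = fit_mgm(
            d, FitConfig(lam=lam, tol=1e-10, max_iter=50000, momentum=False, restart="none")
        )
        assert abs(tr_f.objective[-1] - tr_i.objective[-1]) < 1e-5
        # ... and momentum does not cost iterations at the working tolerance
        _, tr_f6 = fit_mgm(d, FitConfig(lam=lam, tol=1e-6, max_iter=50000))
        _, tr_i6 = fit_mgm(
            d, FitConfig(lam=lam, tol=1e-6, max_iter=50000, momentum=False, restart="none")
        )
        assert tr_f6.n_iter <= tr_i6.n_iter

    def test_solution_invariant_under_variable_permutation(self):
        _, d = simulated_dataset(p=4, q=0, n=300, seed=17, standardize=True)
        cfg = FitConfig(lam=0.05, tol=1e-12, max_iter=20000)
        params, _ = fit_mgm(d, cfg)
        perm = [2, 0, 3, 1]
        from mgmix.dataset import MixedDataset

        d2 = MixedDataset(
            [d.specs[i] for i in perm], d.continuous_values[:, perm],
            d.categorical_values, d.sample_ids,
        )
        params2, _ = fit_mgm(d2, cfg)
        P = np.asarray(perm)
        np.testing.assert_allclose(params2.beta, params.beta[np.ix_(P, P)], atol=1e-9)
        np.testing.assert_allclose(params2.alpha, params.alpha[P], atol=1e-9)

    def test_nonstandardized_data_warns(self):
        _, d = simulated_dataset(p=3, q=0, n=200, seed=18, standardize=False)
        with pytest.warns(UserWarning, match="standardized"):
            fit_mgm(d, FitConfig(lam=0.1, tol=1e-6, max_iter=200))


class TestPathAndSelection:
    def test_single_lambda_path_equals_direct_fit(self):
        _, d = simulated_dataset(p=3, q=1, n=200, seed=20, standardize=True)
        cfg = FitConfig(tol=1e-9)
        lam = 0.4 * lambda_max(d)
        path = regularization_path(d, [lam], cfg)
        direct, _ = fit_mgm(d, dataclasses.replace(cfg, lam=lam))
        np.testing.assert_allclose(path[0][1].beta, direct.beta, atol=1e-12)

    def test_warm_start_no_worse_than_cold_start(self):
        _, d = simulated_dataset(p=4, q=2, n=300, seed=21, standardize=True)
        cfg = FitConfig(tol=1e-9, max_iter=5000)
        lmax = lambda_max(d)
        lambdas = lmax * np.array([0.8, 0.4, 0.2, 0.1])
        path = regularization_path(d, lambdas, cfg)
        for lam, params, _ in path:
            cold, _ = fit_mgm(d, dataclasses.replace(cfg, lam=lam))
            warm_obj = neg_pseudo_loglik(params, d) + lam * _l1_edges(params)
            cold_obj = neg_pseudo_loglik(cold, d) + lam * _l1_edges(cold)
            assert warm_obj <= cold_obj + 1e-6

    def test_lambdas_must_decrease(self):
        _, d = simulated_dataset(p=2, q=0, n=100, seed=22, standardize=True)
        with pytest.raises(ValueError, match="decreasing"):
            regularization_path(d, [0.1, 0.2], FitConfig())

    def test_ebic_on_pure_noise_keeps_graph_near_empty(self, rng):
        from mgmix.dataset import MixedDataset, VariableSpec

        n, p = 1000, 20
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        d = MixedDataset(
            [VariableSpec(f"v{i}", "continuous") for i in range(p)],
            X, np.zeros((n, 0), int), [f"s{i}" for i in range(n)],
        )
        _, params = select_lambda(d, method="ebic")
        assert collapse_edges(params).n_edges() <= 2

    def test_ebic_is_seed_free(self):
        _, d = simulated_dataset(p=4, q=1, n=300, seed=23, standardize=True)
        lam1, p1 = select_lambda(d, method="ebic", seed=1)
        lam2, p2 = select_lambda(d, method="ebic", seed=99)
        assert lam1 == lam2
        assert np.array_equal(p1.beta, p2.beta)

    def test_cv_runs_and_degenerate_fold_is_refused(self):
        truth, d = simulated_dataset(p=3, q=1, n=120, seed=24, standardize=True)
        lmax = lambda_max(d)
        lam, params = select_lambda(
            d, lambdas=lmax * np.array([0.8, 0.3]), method="cv", folds=3, seed=0
        )
        assert lam > 0
        # make one categorical level ultra-rare so some training fold must lose it
        d.categorical_values[:, 0] = 0
        d.categorical_values[0, 0] = 1
        with pytest.raises(ValueError, match="fold"):
            select_lambda(d, lambdas=lmax * np.array([0.5]), method="cv", folds=5, seed=0)


class TestGroupPenalty:
    def test_blocks_zeroed_jointly(self):
        # a 3-level categorical: each rho block must vanish or survive whole
        truth = make_ground_truth(3, 1, (3,), density=0.8, weight_range=(0.3, 0.6), seed=30)
        d3 = gibbs_sample(truth, 400, seed=31)
        from mgmix.dataset import apply_transforms

        d3 = apply_transforms(d3)
        lam = 0.5 * lambda_max(d3)
        params, _ = fit_mgm(d3, FitConfig(lam=lam, tol=1e-9, penalty="group"))
        for s in range(3):
            block = params.rho[s, 1:]
            assert np.all(block == 0.0) or np.all(block != 0.0)

    def test_matches_l1_for_binary_only_model(self):
        # with scalar blocks the two penalties coincide
        _, d = simulated_dataset(p=2, q=2, n=300, seed=32, standardize=True)
        lam = 0.3 * lambda_max(d)
        a, _ = fit_mgm(d, FitConfig(lam=lam, tol=1e-11, max_iter=20000, penalty="l1"))
        b, _ = fit_mgm(d, FitConfig(lam=lam, tol=1e-11, max_iter=20000, penalty="group"))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)
        np.testing.assert_allclose(a.rho, b.rho, atol=1e-6)
        np.testing.assert_allclose(a.phi, b.phi, atol=1e-6)


def _l1_edges(params):
    vz = ParamVectorizer(params.p, params.levels)
    v = vz.pack(params)
    return float(np.abs(v[vz.penalty_mask]).sum())
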