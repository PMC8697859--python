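"""GP with explicit basis: kernels, posterior, likelihood, recovery.

The dense-solve oracle implemented here follows the textbook explicit-basis
equations directly with `numpy.linalg.inv` — independent of the package's
Cholesky/profiling path.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist, pdist, squareform

from spectroml.gp import (
    GaussianProcessBasisRegressor,
    KernelSpec,
    _kernel_matrix,
    fit_gp,
    kernel_eval,
    log_marginal_likelihood,
)


def dense_oracle(X, y, Xq, kind, basis, sf, l, sy):
    """Brute-force explicit-basis GP posterior and log evidence."""
    n = X.shape[0]
    K = _kernel_matrix(squareform(pdist(X)), kind, sf, l) + sy**2 * np.eye(n)
    H = np.ones((n, 1)) if basis == "constant" else np.hstack([np.ones((n, 1)), X])
    Ki = np.linalg.inv(K)
    beta = np.linalg.inv(H.T @ Ki @ H) @ H.T @ Ki @ y
    r = y - H @ beta
    lml = -0.5 * r @ Ki @ r - 0.5 * np.linalg.slogdet(K)[1] - n / 2 * np.log(2 * np.pi)
    Kq = _kernel_matrix(cdist(Xq, X), kind, sf, l)
    Hq = np.ones((Xq.shape[0], 1)) if basis == "constant" else np.hstack(
        [np.ones((Xq.shape[0], 1)), Xq]
    )
    mean = Hq @ beta + Kq @ Ki @ r
    R = Hq.T - H.T @ Ki @ Kq.T
    var = (
        sf**2
        - np.einsum("ij,ji->i", Kq, Ki @ Kq.T)
        + np.einsum("ij,ij->i", R.T @ np.linalg.inv(H.T @ Ki @ H), R.T)
    )
    return mean, np.sqrt(np.clip(var, 0, None)), lml


class TestKernels:
    def test_closed_forms(self):
        sf = 1.7
        for kind in ("exponential", "matern52"):
            assert kernel_eval(0.0, KernelSpec(kind, sf, 0.9)) == pytest.approx(
                sf**2, abs=1e-12
            )
        assert kernel_eval(0.9, KernelSpec("exponential", 1.0, 0.9)) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )
        assert kernel_eval(0.9, KernelSpec("matern52", 1.0, 0.9)) == pytest.approx(
            (1 + np.sqrt(5) + 5 / 3) * np.exp(-np.sqrt(5)), abs=1e-12
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval(-0.1, KernelSpec())

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf")
        with pytest.raises(ValueError):
            KernelSpec("exponential", sigma_f=-1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.sampled_from(["exponential", "matern52"]),
        st.floats(0, 10), st.floats(0, 10), st.floats(0.1, 5),
    )
    def test_monotone_nonincreasing(self, kind, r1, r2, l):
        spec = KernelSpec(kind, 1.3, l)
        lo, hi = sorted((r1, r2))
        assert kernel_eval(hi, spec) <= kernel_eval(lo, spec) + 1e-15

    def test_psd_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for kind in ("exponential", "matern52"):
            X = rng.normal(size=(30, 4))
            K = _kernel_matrix(squareform(pdist(X)), kind, 1.1, 0.7)
            np.testing.assert_allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_matches_sklearn_matern(self):
        """Independent cross-check against scikit-learn's Matérn-5/2 kernel."""
        from sklearn.gaussian_process.kernels import Matern

        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        D = squareform(pdist(X))
        mine = _kernel_matrix(D, "matern52", 1.0, 0.8)
        theirs = Matern(length_scale=0.8, nu=2.5)(X)
        np.testing.assert_allclose(mine, theirs, atol=1e-12)
        mine_exp = _kernel_matrix(D, "exponential", 1.0, 0.8)
        theirs_exp = Matern(length_scale=0.8, nu=0.5)(X)
        np.testing.assert_allclose(mine_exp, theirs_exp, atol=1e-12)


class TestPosterior:
    @pytest.mark.parametrize("kind", ["exponential", "matern52"])
    @pytest.mark.parametrize("basis", ["constant", "linear"])
    def test_matches_dense_oracle(self, kind, basis):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n, d = rng.integers(5, 11), rng.integers(1, 4)
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            Xq = rng.normal(size=(4, d))
            sf, l, sy = rng.uniform(0.5, 2), rng.uniform(0.5, 2), rng.uniform(0.1, 0.5)
            model = GaussianProcessBasisRegressor(
                kernel=kind, basis=basis, sigma_f=sf, length_scale=l, sigma_y=sy,
                optimize=False, standardize=False, jitter=0.0,
            ).fit(X, y)
            mean, sd = model.predict(Xq, return_std=True)
            mean_o, sd_o, lml_o = dense_oracle(X, y, Xq, kind, basis, sf, l, sy)
            np.testing.assert_allclose(mean, mean_o, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(sd, sd_o, rtol=1e-8, atol=1e-10)
            assert model.log_marginal_likelihood_value_ == pytest.approx(
                lml_o, rel=1e-8
            )

    def test_constant_labels_constant_prediction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        model = fit_gp(X, np.full(10, 3.3), "matern52", "constant", random_state=0)
        np.testing.assert_allclose(model.predict(rng.normal(size=(5, 2))), 3.3, atol=1e-6)
        assert model.beta_[0] == pytest.approx(3.3, abs=1e-8)

    def test_degenerate_kernel_reduces_to_gls(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1] + 0.01 * rng.normal(size=20)
        model = GaussianProcessBasisRegressor(
            kernel="matern52", basis="linear", sigma_f=1e-8, length_scale=1.0,
            sigma_y=0.1, optimize=False, standardize=False,
        ).fit(X, y)
        design = np.hstack([np.ones((20, 1)), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        Xq = rng.normal(size=(6, 2))
        np.testing.assert_allclose(
            model.predict(Xq),
            np.hstack([np.ones((6, 1)), Xq]) @ ols,
            atol=1e-6,
        )

    def test_interpolation_limit(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = GaussianProcessBasisRegressor(
            kernel="matern52", basis="constant", sigma_f=1.0, length_scale=1.5,
            sigma_y=1e-10, optimize=False, standardize=False,
        ).fit(X, y)
        mean, sd = model.predict(X, return_std=True)
        assert np.max(np.abs(mean - y)) < 1e-6
        assert np.max(sd) < 1e-4 * 1.0

    def test_prior_reversion_far_from_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2))
        y = 2.0 + rng.normal(size=15)
        model = GaussianProcessBasisRegressor(
            kernel="exponential", basis="constant", sigma_f=1.0, length_scale=0.5,
            sigma_y=0.2, optimize=False, standardize=False,
        ).fit(X, y)
        Xq = np.full((3, 2), 50.0)
        mean, sd = model.predict(Xq, return_std=True)
        np.testing.assert_allclose(mean, model.beta_[0], atol=1e-8)
        assert np.all(sd >= 1.0 - 1e-8)  # at least the prior signal sd

    def test_mean_linear_in_labels(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(14, 2))
        y1, y2 = rng.normal(size=14), rng.normal(size=14)
        Xq = rng.normal(size=(5, 2))

        def pred(y):
            return GaussianProcessBasisRegressor(
                kernel="matern52", basis="linear", sigma_f=1.2, length_scale=0.8,
                sigma_y=0.3, optimize=False, standardize=False,
            ).fit(X, y).predict(Xq)

        np.testing.assert_allclose(pred(y1 + y2), pred(y1) + pred(y2), rtol=1e-9, atol=1e-10)

    def test_predictive_variance_nonnegative(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_gp(X, y, "exponential", "linear", random_state=1)
        _, sd = model.predict(rng.normal(size=(50, 3)) * 3, return_std=True)
        assert np.all(sd >= 0)

    def test_dimension_mismatch(self):
        model = fit_gp(np.random.default_rng(0).normal(size=(8, 2)),
                       np.zeros(8), random_state=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 5)))

    def test_ordinary_kriging_limit_matches_sklearn(self):
        """Cross-check: explicit constant basis equals scikit-learn's GPR with a
        huge-variance constant kernel (vague-prior limit of the intercept)."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

        rng = np.random.default_rng(21)
        X = rng.normal(size=(25, 2))
        y = 5.0 + np.sin(X[:, 0]) + 0.05 * rng.normal(size=25)
        Xq = rng.normal(size=(6, 2))
        mine = GaussianProcessBasisRegressor(
            kernel="matern52", basis="constant", sigma_f=1.0, length_scale=1.0,
            sigma_y=0.1, optimize=False, standardize=False,
        ).fit(X, y).predict(Xq)
        big = 1e6
        sk = GaussianProcessRegressor(
            kernel=Matern(length_scale=1.0, nu=2.5)
            + ConstantKernel(big, "fixed")
            + WhiteKernel(0.01, "fixed"),
            optimizer=None, normalize_y=False,
        ).fit(X, y)
        np.testing.assert_allclose(mine, sk.predict(Xq), atol=1e-2)


class TestLikelihoodAndFitting:
    def test_single_point_closed_form(self):
        # n=1 is below the fit minimum; verify the 1-D Gaussian via n=2 i.i.d.
        X = np.array([[0.0], [1000.0]])  # far apart: independent points
        y = np.array([0.3, -0.2])
        sf, sy = 0.8, 0.4
        model = GaussianProcessBasisRegressor(
            kernel="exponential", basis="constant", sigma_f=sf, length_scale=1.0,
            sigma_y=sy, optimize=False, standardize=False, jitter=0.0,
        ).fit(X, y)
        var = sf**2 + sy**2
        mu = y.mean()  # GLS intercept for iid points
        expect = sum(
            -0.5 * (yi - mu) ** 2 / var - 0.5 * np.log(2 * np.pi * var) for yi in y
        )
        assert model.log_marginal_likelihood_value_ == pytest.approx(expect, rel=1e-10)

    def test_overnoising_penalized(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0])
        model = GaussianProcessBasisRegressor(
            kernel="matern52", basis="constant", sigma_f=1.0, length_scale=1.0,
            sigma_y=0.1, optimize=False, standardize=False,
        ).fit(X, y)
        lmls = [model.log_marginal_likelihood(np.log([1.0, 1.0, sy]))
                for sy in (0.5, 2.0, 8.0, 32.0)]
        assert all(a > b for a, b in zip(lmls, lmls[1:]))

    def test_public_lml_wrapper(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        model = fit_gp(X, y, "matern52", "constant",
                       hyper_strategy="fixed", sigma_f=1.0, length_scale=1.0,
                       sigma_y=0.3, standardize=False)
        assert log_marginal_likelihood(model, X, y) == pytest.approx(
            model.log_marginal_likelihood_value_, rel=1e-12
        )

    def test_fit_requires_enough_samples(self):
        with pytest.raises(ValueError):
            fit_gp(np.zeros((2, 3)), np.zeros(2), basis_kind="linear")

    def test_parameter_recovery(self):
        """Length scale recovered within ×2 in >= 80% of seeded replicates."""
        true_sf, true_l, true_sy = 1.0, 1.5, 0.1
        hits = 0
        n = 150
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(n, 2))
            K = _kernel_matrix(squareform(pdist(X)), "matern52", true_sf, true_l)
            y = np.linalg.cholesky(K + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
            y += true_sy * rng.standard_normal(n)
            model = GaussianProcessBasisRegressor(
                kernel="matern52", basis="constant", standardize=False,
                n_restarts=3, random_state=seed,
            ).fit(X, y)
            if true_l / 2 <= model.length_scale_ <= true_l * 2:
                hits += 1
        assert hits >= 16

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(15, 3)) * [1.0, 10.0, 0.1]
        y = rng.normal(size=15)
        model = fit_gp(X, y, "exponential", "linear", random_state=0)
        clone = GaussianProcessBasisRegressor.from_json(model.to_json())
        Xq = rng.normal(size=(5, 3)) * [1.0, 10.0, 0.1]
        np.testing.assert_allclose(clone.predict(Xq), model.predict(Xq), rtol=1e-12)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = GaussianProcessBasisRegressor(kernel="matern52", n_restarts=2)
        params = clone(model).get_params()
        assert params["kernel"] == "matern52" and params["n_restarts"] == 2
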