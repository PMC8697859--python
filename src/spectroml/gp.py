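"""Gaussian-process regression with explicit basis functions.

The model is

    y(x) = h(x)ᵀβ + f(x) + ε,   f ~ GP(0, k),   ε ~ N(0, σ_y²),

with a parametric mean h(x)ᵀβ (constant or linear basis, β estimated by
generalized least squares) and a zero-mean GP residual under an isotropic
kernel on z-scored features:

* exponential:  k(r) = σ_f² exp(−r/l)
* Matérn 5/2:   k(r) = σ_f² (1 + √5 r/l + 5r²/(3l²)) exp(−√5 r/l)

where r is the Euclidean distance.  (σ_f, l, σ_y) are set by maximizing the
log marginal likelihood with β profiled out (multi-start L-BFGS-B, analytic
gradients); the posterior mean is used for prediction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "GaussianProcessBasisRegressor",
    "fit_gp",
    "log_marginal_likelihood",
]

logger = logging.getLogger(__name__)

KERNELS = ("exponential", "matern52")
BASES = ("constant", "linear")

_SQRT5 = math.sqrt(5.0)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind with signal standard deviation σ_f and length scale l."""

    kind: str = "exponential"
    sigma_f: float = 1.0
    length_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNELS:
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.sigma_f <= 0 or self.length_scale <= 0:
            raise ValueError("sigma_f and length_scale must be > 0")


def _kernel_matrix(r: np.ndarray, kind: str, sigma_f: float, length_scale: float) -> np.ndarray:
    s2 = sigma_f**2
    if kind == "exponential":
        return s2 * np.exp(-r / length_scale)
    if kind == "matern52":
        s = _SQRT5 * r / length_scale
        return s2 * (1.0 + s + s**2 / 3.0) * np.exp(-s)
    raise ValueError(f"unknown kernel {kind!r}")


def kernel_eval(r, spec: KernelSpec):
    """Evaluate the covariance at Euclidean distance(s) ``r`` ≥ 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    out = _kernel_matrix(r, spec.kind, spec.sigma_f, spec.length_scale)
    return float(out) if out.ndim == 0 else out


def _dk_dlog_l(r: np.ndarray, kind: str, sigma_f: float, length_scale: float) -> np.ndarray:
    s2 = sigma_f**2
    if kind == "exponential":
        u = r / length_scale
        return s2 * np.exp(-u) * u
    s = _SQRT5 * r / length_scale
    return s2 * np.exp(-s) * (s**2 / 3.0) * (1.0 + s)


def _basis_design(X: np.ndarray, basis: str) -> np.ndarray:
    n = X.shape[0]
    ones = np.ones((n, 1))
    if basis == "constant":
        return ones
    if basis == "linear":
        return np.hstack([ones, X])
    raise ValueError(f"unknown basis {basis!r}")


class GaussianProcessBasisRegressor(RegressorMixin, BaseEstimator):
    """GP regressor with explicit basis functions (scikit-learn API).

    Parameters
    ----------
    kernel:
        ``"exponential"`` or ``"matern52"``.
    basis:
        ``"constant"`` or ``"linear"`` explicit basis.
    sigma_f, length_scale, sigma_y:
        Initial (or, with ``optimize=False``, fixed) hyperparameters, in
        standardized-feature / label units.
    optimize:
        Maximize the log marginal likelihood over (σ_f, l, σ_y).
    n_restarts:
        Number of random restarts beyond the data-driven start.
    standardize:
        z-score columns with training statistics (isotropic kernels on
        mixed-unit features need this).
    length_scale_bounds, sigma_y_bounds:
        Optimization bounds; ``sigma_y_bounds=None`` means
        (1e-6, range(y)).
    jitter:
        Initial diagonal jitter, escalated ×100 up to 1e-6 on failure.
    random_state:
        Seed for the restart sampler.

    Attributes (after ``fit``)
    --------------------------
    sigma_f_, length_scale_, sigma_y_ : fitted hyperparameters.
    beta_ : basis coefficients (GLS).
    alpha_ : dual weights K⁻¹(y − Hβ).
    log_marginal_likelihood_value_ : profiled log evidence at the optimum.
    """

    def __init__(
        self,
        kernel: str = "exponential",
        basis: str = "constant",
        sigma_f: float = 1.0,
        length_scale: float = 1.0,
        sigma_y: float = 0.1,
        optimize: bool = True,
        n_restarts: int = 5,
        standardize: bool = True,
        length_scale_bounds: tuple[float, float] = (1e-2, 1e3),
        sigma_y_bounds: Optional[tuple[float, float]] = None,
        jitter: float = 1e-10,
        maxiter: int = 60,
        random_state: Optional[int] = None,
    ):
        self.kernel = kernel
        self.basis = basis
        self.sigma_f = sigma_f
        self.length_scale = length_scale
        self.sigma_y = sigma_y
        self.optimize = optimize
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.length_scale_bounds = length_scale_bounds
        self.sigma_y_bounds = sigma_y_bounds
        self.jitter = jitter
        self.maxiter = maxiter
        self.random_state = random_state

    # ----- internals -------------------------------------------------

    def _solve(self, theta: np.ndarray, want_grad: bool = False):
        """Factorize K(θ), profile β out, return lml (+grad) and caches."""
        sf, ln, sy = np.exp(theta)
        n = self._y.shape[0]
        Kf = _kernel_matrix(self._D, self.kernel, sf, ln)
        jitter = self.jitter
        while True:
            K = Kf + (sy**2 + jitter) * np.eye(n)
            try:
                cf = cho_factor(K, lower=True)
                break
            except LinAlgError:
                if jitter >= 1e-6:
                    raise
                jitter *= 100.0
                logger.warning("covariance factorization failed; jitter -> %g", jitter)
        H = self._H
        Kinv_H = cho_solve(cf, H)
        M = H.T @ Kinv_H
        Kinv_y = cho_solve(cf, self._y)
        try:
            beta = np.linalg.solve(M, H.T @ Kinv_y)
        except LinAlgError:
            ridge = 1e-8 * max(np.trace(M) / M.shape[0], 1.0)
            logger.warning("basis design rank-deficient; ridge fallback %g", ridge)
            beta = np.linalg.solve(M + ridge * np.eye(M.shape[0]), H.T @ Kinv_y)
        resid = self._y - H @ beta
        alpha = cho_solve(cf, resid)
        lml = (
            -0.5 * float(resid @ alpha)
            - float(np.sum(np.log(np.diag(cf[0]))))
            - 0.5 * n * math.log(2.0 * math.pi)
        )
        caches = (cf, Kf, beta, alpha, resid, Kinv_H, M, jitter, sy)
        if not want_grad:
            return lml, caches
        # envelope theorem: at the GLS β̂ the gradient is the standard one
        Kinv = cho_solve(cf, np.eye(n))
        grads = np.empty(3)
        dK_sf = 2.0 * Kf
        dK_l = _dk_dlog_l(self._D, self.kernel, sf, ln)
        dK_sy = 2.0 * sy**2 * np.eye(n)
        for j, dK in enumerate((dK_sf, dK_l, dK_sy)):
            grads[j] = 0.5 * (alpha @ dK @ alpha - float(np.sum(Kinv * dK)))
        return lml, grads, caches

    def _neg_lml_and_grad(self, theta: np.ndarray):
        try:
            lml, grads, _ = self._solve(theta, want_grad=True)
        except LinAlgError:
            return 1e25, np.zeros(3)
        if not np.isfinite(lml):
            return 1e25, np.zeros(3)
        return -lml, -grads

    # ----- scikit-learn API ------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")

        if self.standardize:
            self.X_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.X_scale_ = scale
        else:
            self.X_mean_ = np.zeros(X.shape[1])
            self.X_scale_ = np.ones(X.shape[1])
        Xs = (X - self.X_mean_) / self.X_scale_

        self._H = _basis_design(Xs, self.basis)
        if X.shape[0] < self._H.shape[1] + 1:
            raise ValueError(
                f"need at least {self._H.shape[1] + 1} samples for the "
                f"{self.basis!r} basis, got {X.shape[0]}"
            )
        self._y = y
        self._D = squareform(pdist(Xs))

        y_range = float(np.ptp(y))
        y_sd = max(float(np.std(y)), 1e-8)
        if self.optimize:
            lo_l, hi_l = self.length_scale_bounds
            if self.sigma_y_bounds is not None:
                lo_sy, hi_sy = self.sigma_y_bounds
            else:
                lo_sy, hi_sy = 1e-6, max(y_range, 1e-5)
            bounds = [
                (math.log(1e-6 * y_sd), math.log(max(10.0 * y_range, 1e-4))),
                (math.log(lo_l), math.log(hi_l)),
                (math.log(lo_sy), math.log(hi_sy)),
            ]
            starts = [
                np.array([
                    math.log(y_sd),
                    0.0,
                    math.log(np.clip(0.1 * y_sd, lo_sy, hi_sy)),
                ])
            ]
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.n_restarts):
                starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
            best = None
            for th0 in starts:
                th0 = np.clip(th0, [b[0] for b in bounds], [b[1] for b in bounds])
                res = minimize(
                    self._neg_lml_and_grad,
                    th0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": self.maxiter},
                )
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun) or best.fun >= 1e24:
                raise RuntimeError(
                    "marginal likelihood non-finite at every start; "
                    f"kernel={self.kernel}, basis={self.basis}, n={X.shape[0]}"
                )
            theta = best.x
        else:
            theta = np.log([self.sigma_f, self.length_scale, self.sigma_y])

        lml, caches = self._solve(theta)
        cf, Kf, beta, alpha, resid, Kinv_H, M, jitter, sy = caches
        self.sigma_f_, self.length_scale_, self.sigma_y_ = np.exp(theta)
        self.beta_ = beta
        self.alpha_ = alpha
        self.L_ = cf
        self.Kinv_H_ = Kinv_H
        self.M_ = M
        self.jitter_ = jitter
        self.X_train_ = Xs
        self.y_train_ = y
        self.log_marginal_likelihood_value_ = lml
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        Xs = (X - self.X_mean_) / self.X_scale_
        Kq = _kernel_matrix(
            cdist(Xs, self.X_train_), self.kernel, self.sigma_f_, self.length_scale_
        )
        Hq = _basis_design(Xs, self.basis)
        mean = Hq @ self.beta_ + Kq @ self.alpha_
        if not return_std:
            return mean
        V = cho_solve(self.L_, Kq.T)  # K⁻¹ kq, column per query
        var = self.sigma_f_**2 - np.einsum("ij,ji->i", Kq, V)
        R = Hq - Kq @ self.Kinv_H_
        try:
            var += np.einsum("ij,ij->i", R @ np.linalg.inv(self.M_), R)
        except LinAlgError:
            pass  # rank-deficient basis already ridged in fit; skip basis term
        return mean, np.sqrt(np.clip(var, 0.0, None))

    def log_marginal_likelihood(self, theta: Optional[np.ndarray] = None) -> float:
        """Profiled log evidence on the training cache (``theta`` in log space)."""
        check_is_fitted(self, "alpha_")
        if theta is None:
            return self.log_marginal_likelihood_value_
        lml, _ = self._solve(np.asarray(theta, float))
        return lml

    # ----- audit serialization ---------------------------------------

    def to_json(self) -> str:
        """Serialize hyperparameters, β and the training cache for exact re-prediction."""
        check_is_fitted(self, "alpha_")
        digest = hashlib.sha256(
            np.ascontiguousarray(self.X_train_).tobytes()
            + np.ascontiguousarray(self.y_train_).tobytes()
        ).hexdigest()
        return json.dumps(
            {
                "kernel": self.kernel,
                "basis": self.basis,
                "sigma_f": self.sigma_f_,
                "length_scale": self.length_scale_,
                "sigma_y": self.sigma_y_,
                "jitter": self.jitter_,
                "beta": self.beta_.tolist(),
                "alpha": self.alpha_.tolist(),
                "X_mean": self.X_mean_.tolist(),
                "X_scale": self.X_scale_.tolist(),
                "X_train_std": self.X_train_.tolist(),
                "y_train": self.y_train_.tolist(),
                "training_digest": digest,
                "log_marginal_likelihood": self.log_marginal_likelihood_value_,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "GaussianProcessBasisRegressor":
        """Rebuild a model for exact re-prediction from :meth:`to_json` output."""
        d = json.loads(doc)
        Xs = np.asarray(d["X_train_std"], float)
        y = np.asarray(d["y_train"], float)
        # rerun the linear algebra on the stored, already-standardized cache
        model = cls(
            kernel=d["kernel"], basis=d["basis"], sigma_f=d["sigma_f"],
            length_scale=d["length_scale"], sigma_y=d["sigma_y"],
            optimize=False, standardize=False, jitter=d["jitter"],
        ).fit(Xs, y)
        model.X_mean_ = np.asarray(d["X_mean"], float)
        model.X_scale_ = np.asarray(d["X_scale"], float)
        return model


def fit_gp(
    X,
    y,
    kernel_kind: str = "exponential",
    basis_kind: str = "constant",
    hyper_strategy: str = "ml",
    *,
    n_restarts: int = 5,
    random_state: Optional[int] = None,
    **fixed,
) -> GaussianProcessBasisRegressor:
    """Convenience wrapper returning a fitted :class:`GaussianProcessBasisRegressor`.

    ``hyper_strategy="ml"`` maximizes the marginal likelihood; ``"fixed"``
    uses the hyperparameters passed as keyword arguments
    (``sigma_f``, ``length_scale``, ``sigma_y``).
    """
    if hyper_strategy not in ("ml", "fixed"):
        raise ValueError("hyper_strategy must be 'ml' or 'fixed'")
    model = GaussianProcessBasisRegressor(
        kernel=kernel_kind,
        basis=basis_kind,
        optimize=(hyper_strategy == "ml"),
        n_restarts=n_restarts,
        random_state=random_state,
        **fixed,
    )
    return model.fit(X, y)


def log_marginal_likelihood(model: GaussianProcessBasisRegressor, X, y) -> float:
    """Profiled log evidence of ``model``'s hyperparameters on (X, y)."""
    check_is_fitted(model, "alpha_")
    probe = GaussianProcessBasisRegressor(
        kernel=model.kernel,
        basis=model.basis,
        sigma_f=model.sigma_f_,
        length_scale=model.length_scale_,
        sigma_y=model.sigma_y_,
        optimize=False,
        standardize=model.standardize,
        jitter=model.jitter,
    ).fit(X, y)
    return probe.log_marginal_likelihood_value_
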