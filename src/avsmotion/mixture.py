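"""Gaussian mixture model fitted by Expectation-Maximization, from scratch.

This is the unsupervised global layer's learning machinery. The model is the
standard K-component multivariate Gaussian mixture

    p(x) = sum_k pi_k N(x | mu_k, Sigma_k)

with full covariances. The E-step computes responsibilities
R_ik = pi_k N(x_i|mu_k, Sigma_k) / sum_j pi_j N(x_i|mu_j, Sigma_j); the
M-step re-estimates means, covariances and weights from the responsibility-
weighted data; iteration stops when the mean per-point log-likelihood change
falls below ``tol``.

All densities are evaluated in log space through a Cholesky factorization of
the regularized covariance: the index-vector clusters are rank-deficient (14
of 16 dimensions are constant within a cluster), so a small diagonal ridge
``reg_eps`` keeps every covariance positive definite, and literal density
ratios would under/overflow at these scales.

`GaussianMixtureEM` is a scikit-learn style estimator (``fit`` /
``predict`` / ``predict_proba`` / ``score``); the module-level functions
(`init_params`, `e_step`, `m_step`, ...) expose the individual EM pieces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "GMMParams",
    "Responsibilities",
    "FitResult",
    "GaussianMixtureEM",
    "init_params",
    "component_logpdf",
    "e_step",
    "m_step",
    "log_likelihood",
    "fit",
    "assign",
]


@dataclass
class GMMParams:
    """Mixture weights, means and covariances of a K-component model."""

    weights: np.ndarray  # K
    means: np.ndarray  # K x dim
    covariances: np.ndarray  # K x dim x dim
    reg_eps: float = 1e-6

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class Responsibilities:
    """Posterior component memberships R (N x K); rows sum to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def effective_counts(self) -> np.ndarray:
        """N_k: responsibility mass per component (column sums)."""
        return self.values.sum(axis=0)


@dataclass
class FitResult:
    """Outcome of one EM fit (the best restart when n_init > 1)."""

    params: GMMParams
    n_iter: int
    loglik_trace: np.ndarray
    converged: bool


def init_params(
    K: int,
    dim: int,
    seed: int | np.random.Generator,
    scheme: str = "random_uniform",
    X: np.ndarray | None = None,
    reg_eps: float = 1e-6,
) -> GMMParams:
    """Initial parameters: uniform weights, identity covariances, random means.

    ``random_uniform`` draws means uniformly over [0, 1]^dim (the scale of the
    normalized index vectors); ``random_datapoint`` picks K distinct rows of
    ``X`` instead.
    """
    if K < 1 or dim < 1:
        raise ValueError("K and dim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scheme == "random_uniform":
        means = rng.random((K, dim))
    elif scheme == "random_datapoint":
        if X is None:
            raise ValueError("random_datapoint init requires data")
        idx = rng.choice(len(X), size=K, replace=False)
        means = np.asarray(X, dtype=float)[idx].copy()
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    weights = np.full(K, 1.0 / K)
    covariances = np.broadcast_to(np.eye(dim), (K, dim, dim)).copy()
    return GMMParams(weights, means, covariances, reg_eps)


def component_logpdf(
    x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, reg_eps: float = 0.0
) -> np.ndarray:
    """log N(x | mu, sigma + reg_eps I) via a Cholesky factorization.

    ``x`` may be a single vector or an N x dim matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    mu = np.asarray(mu, dtype=float)
    dim = mu.size
    sigma = np.asarray(sigma, dtype=float) + reg_eps * np.eye(dim)
    try:
        chol, low = cho_factor(sigma, lower=True)
    except LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite even with reg_eps={reg_eps}: {exc}"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    dev = x - mu
    solved = cho_solve((chol, low), dev.T)
    maha = np.einsum("ij,ji->i", dev, solved)
    out = -0.5 * (dim * np.log(2.0 * np.pi) + logdet + maha)
    return float(out[0]) if single else out


def _weighted_logpdfs(params: GMMParams, X: np.ndarray) -> np.ndarray:
    """N x K matrix of log(pi_k) + log N(x_i | mu_k, Sigma_k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lp = np.empty((X.shape[0], params.K))
    for k in range(params.K):
        lp[:, k] = component_logpdf(
            X, params.means[k], params.covariances[k], params.reg_eps
        )
    return lp + np.log(params.weights)


def e_step(params: GMMParams, X: np.ndarray) -> Responsibilities:
    """Responsibilities R_ik, computed in log space and row-normalized."""
    lp = _weighted_logpdfs(params, X)
    lse = logsumexp(lp, axis=1, keepdims=True)
    if not np.all(np.isfinite(lse)):
        raise FloatingPointError("all component densities vanished for some point")
    return Responsibilities(np.exp(lp - lse))


def m_step(
    X: np.ndarray,
    R: Responsibilities,
    reg_eps: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> GMMParams:
    """Re-estimate weights, means and covariances from responsibilities.

    A component whose responsibility mass falls below 1e-10 is degenerate; it
    is reseeded to a random data point with identity covariance (and logged)
    when a generator is supplied, otherwise an error is raised.
    """
    X = np.asarray(X, dtype=float)
    resp = R.values
    n, dim = X.shape
    nk = resp.sum(axis=0)
    k_total = resp.shape[1]
    degenerate = np.flatnonzero(nk < 1e-10)
    if degenerate.size and rng is None:
        raise FloatingPointError(
            f"degenerate components {degenerate.tolist()} (responsibility mass ~ 0)"
        )
    means = np.empty((k_total, dim))
    covariances = np.empty((k_total, dim, dim))
    for k in range(k_total):
        if k in degenerate:
            logger.warning("reseeding degenerate component %d to a random data point", k)
            means[k] = X[rng.integers(n)]
            covariances[k] = np.eye(dim)
            nk[k] = 1.0
            continue
        means[k] = resp[:, k] @ X / nk[k]
        dev = X - means[k]
        covariances[k] = (resp[:, k, None] * dev).T @ dev / nk[k] + reg_eps * np.eye(dim)
    weights = nk / nk.sum()
    return GMMParams(weights, means, covariances, reg_eps)


def log_likelihood(params: GMMParams, X: np.ndarray) -> float:
    """Total data log-likelihood: sum_i log sum_k pi_k N(x_i | mu_k, Sigma_k)."""
    return float(logsumexp(_weighted_logpdfs(params, X), axis=1).sum())


class GaussianMixtureEM(ClusterMixin, BaseEstimator):
    """K-component full-covariance Gaussian mixture fitted by EM.

    Parameters
    ----------
    n_components : int
        Number of mixture components (8 for the eight motion directions).
    reg_eps : float
        Diagonal ridge added to every covariance; keeps the rank-deficient
        direction clusters positive definite.
    tol : float
        Convergence threshold on the mean per-point log-likelihood change.
    max_iter : int
        EM iteration cap per restart.
    n_init : int
        Number of random restarts; the fit with the highest final
        log-likelihood is kept.
    init_scheme : {"random_uniform", "random_datapoint"}
        How initial means are drawn. Weights start uniform and covariances
        start at identity in both schemes.
    random_state : int or numpy Generator, optional
        Seed for the restart streams.

    Attributes
    ----------
    weights_, means_, covariances_ : fitted mixture parameters.
    loglik_trace_ : per-iteration total log-likelihood of the kept restart.
    n_iter_ : EM iterations the kept restart executed.
    converged_ : whether the kept restart met ``tol`` before ``max_iter``.
    lower_bound_ : final total log-likelihood of the kept restart.
    """

    def __init__(
        self,
        n_components: int = 8,
        reg_eps: float = 1e-6,
        tol: float = 1e-3,
        max_iter: int = 100,
        n_init: int = 10,
        init_scheme: str = "random_uniform",
        random_state: int | np.random.Generator | None = None,
    ):
        self.n_components = n_components
        self.reg_eps = reg_eps
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.init_scheme = init_scheme
        self.random_state = random_state

    def _single_fit(self, X: np.ndarray, rng: np.random.Generator) -> FitResult:
        params = init_params(
            self.n_components, X.shape[1], rng, self.init_scheme, X, self.reg_eps
        )
        trace: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            lp = _weighted_logpdfs(params, X)
            lse = logsumexp(lp, axis=1, keepdims=True)
            ll = float(lse.sum())
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) / len(X) < self.tol:
                converged = True
                break
            resp = Responsibilities(np.exp(lp - lse))
            params = m_step(X, resp, self.reg_eps, rng)
        return FitResult(params, n_iter, np.asarray(trace), converged)

    def fit(self, X, y=None) -> "GaussianMixtureEM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be an N x dim matrix")
        if len(X) < self.n_components:
            raise ValueError(
                f"need at least n_components={self.n_components} points, got {len(X)}"
            )
        if isinstance(self.random_state, np.random.Generator):
            rngs = self.random_state.spawn(self.n_init)
        else:
            rngs = [
                np.random.default_rng(s)
                for s in np.random.SeedSequence(self.random_state).spawn(self.n_init)
            ]
        best: FitResult | None = None
        for rng in rngs:
            result = self._single_fit(X, rng)
            if best is None or result.loglik_trace[-1] > best.loglik_trace[-1]:
                best = result
        self.weights_ = best.params.weights
        self.means_ = best.params.means
        self.covariances_ = best.params.covariances
        self.loglik_trace_ = best.loglik_trace
        self.n_iter_ = best.n_iter
        self.converged_ = best.converged
        self.lower_bound_ = float(best.loglik_trace[-1])
        self.labels_ = self.predict(X)
        return self

    @property
    def params_(self) -> GMMParams:
        check_is_fitted(self, "weights_")
        return GMMParams(self.weights_, self.means_, self.covariances_, self.reg_eps)

    def predict_proba(self, X) -> np.ndarray:
        return e_step(self.params_, X).values

    def predict(self, X) -> np.ndarray:
        """Hard assignment: argmax responsibility, ties to the lowest index."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X) -> np.ndarray:
        return logsumexp(_weighted_logpdfs(self.params_, X), axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-point log-likelihood."""
        return float(self.score_samples(X).mean())


def fit(
    X: np.ndarray,
    K: int = 8,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-3,
    n_init: int = 10,
    reg_eps: float = 1e-6,
    init_scheme: str = "random_uniform",
) -> FitResult:
    """Functional wrapper: fit a mixture and return the best restart's result."""
    est = GaussianMixtureEM(
        n_components=K,
        reg_eps=reg_eps,
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        init_scheme=init_scheme,
        random_state=seed,
    ).fit(X)
    return FitResult(est.params_, est.n_iter_, est.loglik_trace_, est.converged_)


def assign(params: GMMParams, X: np.ndarray) -> np.ndarray:
    """Hard-assign each point to its maximum-responsibility component."""
    return np.argmax(e_step(params, X).values, axis=1)
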