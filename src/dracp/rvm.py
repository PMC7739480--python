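"""Relevance vector machine: sparse Bayesian learning with a Gaussian kernel.

The model is linear-in-parameters regression over kernel basis functions,
t = Phi w + eps with eps ~ N(0, sigma^2), where row i of the design matrix is
phi(x_i) = [1, K(x_i, x_1), ..., K(x_i, x_N)].  Each weight w_i carries an
independent zero-mean Gaussian prior with precision alpha_i; the alpha_i and
sigma^2 are optimised by type-II maximum likelihood (evidence maximisation)
with flat hyperpriors:

    Sigma = (sigma^-2 Phi'Phi + diag(alpha))^-1
    mu    = sigma^-2 Sigma Phi' t
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    sigma^2 <- ||t - Phi mu||^2 / (N - sum_i gamma_i)

Basis functions whose alpha exceeds a cap are pruned; the training points
behind the surviving kernel columns are the relevance vectors.  Binary
classification is regression on {0,1} targets thresholded at 0.5.

Prediction follows the posterior predictive: mean mu'phi(x*) and variance
sigma^2_MP + phi(x*)' Sigma phi(x*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel K(x, y) = exp(-||x - y||^2 / width^2)."""

    name: str = "gaussian"
    width: float = 6.0

    def __post_init__(self) -> None:
        if self.name != "gaussian":
            raise ValueError(f"unsupported kernel {self.name!r}")
        if self.width <= 0:
            raise ValueError("kernel width must be > 0")


def gaussian_kernel(x: np.ndarray, y: np.ndarray, width: float = 6.0) -> float:
    """exp(-||x - y||^2 / width^2) for a single pair of points."""
    if width <= 0:
        raise ValueError("kernel width must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / width**2))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Pairwise Gaussian kernel matrix, rows of X against rows of Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return np.exp(-cdist(X, Y, "sqeuclidean") / kernel.width**2)


def design_matrix(
    train_inputs: np.ndarray, query_inputs: np.ndarray, kernel: KernelSpec
) -> np.ndarray:
    """Rows phi(q) = [1, K(q, x_1), ..., K(q, x_N)] for each query q."""
    train_inputs = np.atleast_2d(np.asarray(train_inputs, dtype=float))
    query_inputs = np.atleast_2d(np.asarray(query_inputs, dtype=float))
    if train_inputs.shape[0] == 0:
        raise ValueError("empty training set")
    if train_inputs.shape[1] != query_inputs.shape[1]:
        raise ValueError(
            f"dimension mismatch: train d={train_inputs.shape[1]}, "
            f"query d={query_inputs.shape[1]}"
        )
    K = kernel_matrix(query_inputs, train_inputs, kernel)
    return np.hstack([np.ones((K.shape[0], 1)), K])


def posterior_stats(
    Phi: np.ndarray,
    t: np.ndarray,
    alpha: np.ndarray,
    sigma2: float,
    jitter: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the weights for fixed (alpha, sigma^2).

    Sigma = (sigma^-2 Phi'Phi + diag(alpha))^-1, mu = sigma^-2 Sigma Phi' t.
    A small jitter is added to the precision diagonal for stability.
    """
    Phi = np.asarray(Phi, dtype=float)
    t = np.asarray(t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    H = Phi.T @ Phi / sigma2 + np.diag(alpha)
    H[np.diag_indices_from(H)] += jitter
    c, low = cho_factor(H)
    Sigma = cho_solve((c, low), np.eye(H.shape[0]))
    mu = Sigma @ (Phi.T @ t) / sigma2
    return mu, Sigma


@dataclass
class RVMModel:
    """A fitted sparse Bayesian kernel machine.

    ``rv_indices`` point into the original training set for the surviving
    kernel columns; ``bias_included`` records whether the constant basis
    survived pruning.  ``weights``/``alpha``/``Sigma`` are over the retained
    basis in order [bias?, kernels...].
    """

    relevance_vectors: np.ndarray
    rv_indices: np.ndarray
    bias_included: bool
    weights: np.ndarray
    alpha: np.ndarray
    sigma2: float
    Sigma: np.ndarray
    kernel: KernelSpec
    converged: bool
    n_iter: int
    n_train: int
    n_active_history: list = field(default_factory=list)

    @property
    def n_relevance_vectors(self) -> int:
        return int(self.rv_indices.size)

    def to_dict(self) -> dict:
        return {
            "relevance_vectors": self.relevance_vectors.tolist(),
            "rv_indices": self.rv_indices.tolist(),
            "bias_included": bool(self.bias_included),
            "weights": self.weights.tolist(),
            "alpha": self.alpha.tolist(),
            "sigma2": float(self.sigma2),
            "Sigma": self.Sigma.tolist(),
            "kernel": {"name": self.kernel.name, "width": self.kernel.width},
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_train": int(self.n_train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RVMModel":
        return cls(
            relevance_vectors=np.array(d["relevance_vectors"], dtype=float),
            rv_indices=np.array(d["rv_indices"], dtype=int),
            bias_included=bool(d["bias_included"]),
            weights=np.array(d["weights"], dtype=float),
            alpha=np.array(d["alpha"], dtype=float),
            sigma2=float(d["sigma2"]),
            Sigma=np.array(d["Sigma"], dtype=float),
            kernel=KernelSpec(**d["kernel"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            n_train=int(d["n_train"]),
        )


ALPHA_PRUNE_CAP = 1e9
_SIGMA2_FLOOR = 1e-12


def _query_design(model: RVMModel, Xq: np.ndarray) -> np.ndarray:
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if model.relevance_vectors.size:
        if Xq.shape[1] != model.relevance_vectors.shape[1]:
            raise ValueError(
                f"query dimension {Xq.shape[1]} != relevance-vector dimension "
                f"{model.relevance_vectors.shape[1]}"
            )
        K = kernel_matrix(Xq, model.relevance_vectors, model.kernel)
    else:
        K = np.empty((Xq.shape[0], 0))
    cols = [np.ones((Xq.shape[0], 1))] if model.bias_included else []
    cols.append(K)
    return np.hstack(cols)


def fit_rvm(
    X: np.ndarray,
    t: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    max_iter: int = 100,
    tol: float = 1e-3,
    alpha_init: float = 1e-6,
    prune_cap: float = ALPHA_PRUNE_CAP,
) -> RVMModel:
    """Fit the RVM by iterated type-II maximum-likelihood updates.

    Deterministic: there is no randomness in the fit.  Stops when the largest
    change in log(alpha) over the surviving basis drops below ``tol`` or
    after ``max_iter`` iterations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    N = X.shape[0]
    if N < 2:
        raise ValueError("need at least 2 training samples")
    if t.size != N:
        raise ValueError("X and t disagree on sample count")
    if not (np.isfinite(X).all() and np.isfinite(t).all()):
        raise ValueError("non-finite values in training inputs or targets")

    if np.ptp(X, axis=0).max() == 0.0:
        # All rows identical: every kernel column equals the bias column.
        warnings.warn(
            "all training inputs identical; returning a bias-only model",
            stacklevel=2,
        )
        mu0 = float(t.mean())
        s2 = max(float(t.var()), _SIGMA2_FLOOR)
        return RVMModel(
            relevance_vectors=np.empty((0, X.shape[1])),
            rv_indices=np.empty(0, dtype=int),
            bias_included=True,
            weights=np.array([mu0]),
            alpha=np.array([1.0 / max(mu0**2, 1e-12)]),
            sigma2=s2,
            Sigma=np.array([[s2 / N]]),
            kernel=kernel,
            converged=True,
            n_iter=0,
            n_train=N,
        )

    Phi_full = design_matrix(X, X, kernel)  # N x (N+1), column 0 = bias
    active = np.arange(N + 1)  # indices into full basis
    alpha = np.full(N + 1, alpha_init)
    sigma2 = max(0.1 * float(t.var()), 1e-6)

    mu = np.zeros(N + 1)
    Sigma = np.eye(N + 1)
    converged = False
    n_iter = 0
    n_active_history: list[int] = [active.size]
    for n_iter in range(1, max_iter + 1):
        Phi = Phi_full[:, active]
        a = alpha[active]
        mu, Sigma = posterior_stats(Phi, t, a, sigma2)
        gamma = 1.0 - a * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-12, None)
        alpha_new = gamma / np.maximum(mu**2, 1e-300)
        resid = t - Phi @ mu
        denom = max(N - gamma.sum(), 1e-12)
        sigma2 = max(float(resid @ resid) / denom, _SIGMA2_FLOOR)

        keep = alpha_new < prune_cap
        if not keep.any():
            # Keep the best-supported basis function rather than go empty.
            keep[np.argmin(alpha_new)] = True
        delta = np.abs(np.log(alpha_new[keep]) - np.log(alpha[active][keep]))
        alpha[active] = alpha_new
        active = active[keep]
        n_active_history.append(active.size)
        if delta.max() < tol:
            converged = True
            break

    Phi = Phi_full[:, active]
    mu, Sigma = posterior_stats(Phi, t, alpha[active], sigma2)
    bias_included = bool(active[0] == 0)
    kernel_basis = active[active > 0] - 1  # training-point indices
    return RVMModel(
        relevance_vectors=X[kernel_basis],
        rv_indices=kernel_basis,
        bias_included=bias_included,
        weights=mu,
        alpha=alpha[active],
        sigma2=sigma2,
        Sigma=Sigma,
        kernel=kernel,
        converged=converged,
        n_iter=n_iter,
        n_train=N,
        n_active_history=n_active_history,
    )


def predict_rvm(model: RVMModel, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior predictive mean and variance at the query points.

    mean = mu' phi(x*);  var = sigma^2_MP + phi(x*)' Sigma phi(x*) >= sigma^2_MP.
    """
    Phi = _query_design(model, Xq)
    mean = Phi @ model.weights
    var = model.sigma2 + np.einsum("ij,jk,ik->i", Phi, model.Sigma, Phi)
    return mean, var


def classify_rvm(model: RVMModel, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels and scores from a model fitted on {0,1} targets.

    Score is the predictive mean clipped to [0, 1]; label is 1 iff
    score >= 0.5 (ties go to the positive class).
    """
    mean, _ = predict_rvm(model, Xq)
    scores = np.clip(mean, 0.0, 1.0)
    labels = (scores >= 0.5).astype(int)
    return labels, scores
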