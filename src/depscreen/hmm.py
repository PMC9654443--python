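"""Hidden Markov model with multivariate-Gaussian emissions.

The observation model is ``x_t | s_t = k ~ N(mu_k, Sigma_k)`` with a
homogeneous Markov chain over K hidden states. Provides exact log-space
forward-backward evaluation (posterior state marginals and expected
transition counts), maximum-likelihood fitting via Baum-Welch EM with
k-means initialisation and random restarts, Viterbi decoding, marginal
(gamma-argmax) decoding, and AIC/BIC-based selection of the number of
states.

All algorithms run in log space, so sequences up to T ~ 1e5 evaluate without
underflow. Covariances are regularised by adding ``cov_reg * I`` at every
M-step, guarding against singular within-state scatter. Ties in any argmax
break toward the lower state index, and every source of randomness is driven
by an explicit seed, so fits are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "HmmParameters",
    "PosteriorGamma",
    "StatePath",
    "FitReport",
    "log_forward_backward",
    "fit_em",
    "viterbi",
    "decode_gamma_argmax",
    "select_k",
]


@dataclass
class HmmParameters:
    """Model parameters: initial distribution, transitions, Gaussian emissions."""

    initial_probs: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K) row-stochastic
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d) symmetric positive definite

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.initial_probs)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        K = self.n_states
        if self.transition.shape != (K, K):
            raise ValidationError("transition matrix shape mismatch")
        if abs(self.initial_probs.sum() - 1.0) > 1e-10 or (self.initial_probs < 0).any():
            raise ValidationError("initial_probs must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > 1e-10 or (self.transition < 0).any():
            raise ValidationError("transition rows must sum to 1")
        if self.means.shape[0] != K or self.covariances.shape != (K, self.n_features, self.n_features):
            raise ValidationError("means/covariances shape mismatch")
        for k, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValidationError(f"covariance {k} not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValidationError(f"covariance {k} not positive definite")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.abs(np.real(vecs[:, i]))
        return v / v.sum()

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "initial_probs": self.initial_probs.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParameters":
        return cls(
            initial_probs=np.array(d["initial_probs"]),
            transition=np.array(d["transition"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
        )


@dataclass
class PosteriorGamma:
    """Posterior state marginals gamma (T,K), expected transition counts, log-likelihood."""

    gamma: np.ndarray
    xi_sums: np.ndarray
    log_likelihood: float


@dataclass
class StatePath:
    """A decoded state sequence and the decoding rule that produced it."""

    states: np.ndarray
    method: str  # "viterbi" | "gamma_argmax"


@dataclass
class FitReport:
    converged: bool
    n_iterations: int
    log_likelihood_trace: np.ndarray
    best_restart: int
    seed: int
    restart_log_likelihoods: list[float] = field(default_factory=list)


def _check_observations(params: HmmParameters, observations: np.ndarray) -> np.ndarray:
    X = np.asarray(observations, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError("observations must be a T x d matrix with T >= 1")
    if X.shape[1] != params.n_features:
        raise ValidationError(
            f"observation dimension {X.shape[1]} != model dimension {params.n_features}"
        )
    if not np.isfinite(X).all():
        raise ValidationError("observations contain non-finite values")
    return X


def _log_emission(X: np.ndarray, means: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """(T,K) log N(x_t; mu_k, Sigma_k) via Cholesky solves."""
    T, d = X.shape
    K = means.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(covariances[k])
        diff = X - means[k]
        z = solve_triangular(L, diff.T, lower=True)
        maha = (z**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
    return out


def log_forward_backward(params: HmmParameters, observations: np.ndarray) -> PosteriorGamma:
    """Exact posterior state marginals and expected transition counts.

    Runs the forward-backward recursions entirely in log space and returns
    the gamma matrix (each row a posterior distribution over states), the
    summed two-slice posteriors ``xi_sums`` (K x K expected transition
    counts) and the exact marginal log-likelihood of the observations.
    """
    params.validate()
    X = _check_observations(params, observations)
    T = X.shape[0]
    K = params.n_states
    A = params.transition
    log_B = _log_emission(X, params.means, params.covariances)
    # Emission weights are kept in the log domain and shifted by their
    # per-step maximum before exponentiation; together with the per-step
    # rescaling of alpha/beta this is the standard underflow-free scheme
    # (valid for T up to ~1e5) and is exact: ll = sum(log c_t) + sum(shifts).
    shift = log_B.max(axis=1)
    Bn = np.exp(log_B - shift[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = params.initial_probs * Bn[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * Bn[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    ll = float(np.log(c).sum() + shift.sum())

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (Bn[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    w = Bn[1:] * beta[1:] / c[1:, None]
    xi_sums = A * (alpha[:-1].T @ w)
    return PosteriorGamma(gamma=gamma, xi_sums=xi_sums, log_likelihood=ll)


def viterbi(params: HmmParameters, observations: np.ndarray) -> StatePath:
    """Maximum-a-posteriori state path; argmax ties break to the lower index."""
    params.validate()
    X = _check_observations(params, observations)
    T = X.shape[0]
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial_probs)
        log_A = np.log(params.transition)
    log_B = _log_emission(X, params.means, params.covariances)

    delta = log_pi + log_B[0]
    psi = np.zeros((T, params.n_states), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_A
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(params.n_states)] + log_B[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]
    return StatePath(states=states, method="viterbi")


def decode_gamma_argmax(gamma: PosteriorGamma | np.ndarray) -> StatePath:
    """Marginal decoding: per-row argmax of gamma, ties to the lower index."""
    g = gamma.gamma if isinstance(gamma, PosteriorGamma) else np.asarray(gamma)
    return StatePath(states=np.argmax(g, axis=1).astype(int), method="gamma_argmax")


def _initial_params(
    X: np.ndarray, K: int, cov_reg: float, random_state: int, self_bias: float = 0.9
) -> HmmParameters:
    T, d = X.shape
    if K == 1:
        labels = np.zeros(T, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=random_state)
        labels = km.fit_predict(X)
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    global_cov = np.cov(X, rowvar=False).reshape(d, d) + cov_reg * np.eye(d)
    for k in range(K):
        members = X[labels == k]
        means[k] = members.mean(axis=0) if len(members) else X.mean(axis=0)
        covs[k] = (
            np.cov(members, rowvar=False).reshape(d, d) + cov_reg * np.eye(d)
            if len(members) > d
            else global_cov
        )
    pi = np.full(K, 1.0 / K)
    if K == 1:
        A = np.ones((1, 1))
    else:
        A = np.full((K, K), (1.0 - self_bias) / (K - 1))
        np.fill_diagonal(A, self_bias)
    return HmmParameters(initial_probs=pi, transition=A, means=means, covariances=covs)


def fit_em(
    observations: np.ndarray,
    n_states: int,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    cov_reg: float | None = None,
    seed: int = 0,
) -> tuple[HmmParameters, FitReport]:
    """Fit by Baum-Welch EM with k-means initialisation and restarts.

    ``tol`` is the relative log-likelihood change declaring convergence;
    ``cov_reg`` defaults to ``1e-6 * trace(cov(X)) / d``. The restart with
    the highest final log-likelihood wins. Deterministic given ``seed``.
    """
    X = np.asarray(observations, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T, d = X.shape
    if n_states < 1:
        raise ValidationError("n_states must be >= 1")
    if T <= n_states:
        raise InsufficientDataError(f"need more than K={n_states} observations, got T={T}")
    if not np.isfinite(X).all():
        raise ValidationError("observations contain non-finite values")
    col_var = X.var(axis=0)
    if (col_var == 0).any():
        warnings.warn("zero-variance observation column; fit relies on covariance regularisation")
    if cov_reg is None:
        total = float(np.trace(np.cov(X, rowvar=False).reshape(d, d)))
        cov_reg = max(1e-6 * total / d, 1e-10)

    best: tuple[float, HmmParameters, np.ndarray, int] | None = None
    restart_lls: list[float] = []
    for r in range(n_restarts):
        params = _initial_params(X, n_states, cov_reg, random_state=seed + r)
        trace: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            post = log_forward_backward(params, X)
            trace.append(post.log_likelihood)
            params = _m_step(X, post, params, cov_reg)
            if prev_ll > -np.inf:
                rel = (post.log_likelihood - prev_ll) / max(abs(prev_ll), 1.0)
                if rel < tol:
                    break
            prev_ll = post.log_likelihood
        final_ll = trace[-1]
        restart_lls.append(final_ll)
        if best is None or final_ll > best[0]:
            best = (final_ll, params, np.array(trace), r)

    assert best is not None
    _, params, trace, r_best = best
    converged = len(trace) < max_iter
    report = FitReport(
        converged=converged,
        n_iterations=len(trace),
        log_likelihood_trace=trace,
        best_restart=r_best,
        seed=seed,
        restart_log_likelihoods=restart_lls,
    )
    return params, report


def _m_step(
    X: np.ndarray, post: PosteriorGamma, params: HmmParameters, cov_reg: float
) -> HmmParameters:
    gamma = post.gamma
    K = gamma.shape[1]
    d = X.shape[1]
    pi = gamma[0] / gamma[0].sum()
    if K == 1:
        A = np.ones((1, 1))
    else:
        row_sums = post.xi_sums.sum(axis=1, keepdims=True)
        A = np.where(row_sums > 0, post.xi_sums / np.where(row_sums == 0, 1.0, row_sums), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
    Nk = gamma.sum(axis=0)
    means = (gamma.T @ X) / Nk[:, None]
    covs = np.empty((K, d, d))
    for k in range(K):
        diff = X - means[k]
        covs[k] = (gamma[:, k][:, None] * diff).T @ diff / Nk[k] + cov_reg * np.eye(d)
        covs[k] = 0.5 * (covs[k] + covs[k].T)
    return HmmParameters(initial_probs=pi, transition=A, means=means, covariances=covs)


def n_parameters(K: int, d: int) -> int:
    """Free-parameter count: (K-1) + K(K-1) + K d + K d(d+1)/2."""
    return (K - 1) + K * (K - 1) + K * d + K * d * (d + 1) // 2


def select_k(
    observations: np.ndarray,
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5),
    **fit_config,
) -> pd.DataFrame:
    """One EM fit per candidate K with a shared seed policy; AIC/BIC table."""
    if not len(k_grid):
        raise ValidationError("k_grid must be non-empty")
    X = np.asarray(observations, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T, d = X.shape
    rows = []
    for K in k_grid:
        params, report = fit_em(X, K, **fit_config)
        ll = float(report.log_likelihood_trace[-1])
        p = n_parameters(K, d)
        rows.append(
            {
                "K": K,
                "log_likelihood": ll,
                "n_params": p,
                "AIC": -2.0 * ll + 2.0 * p,
                "BIC": -2.0 * ll + p * np.log(T),
            }
        )
    return pd.DataFrame(rows)
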