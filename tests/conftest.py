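import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from depscreen.hmm import HmmParameters


def random_hmm(rng: np.random.Generator, K: int, d: int) -> HmmParameters:
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    means = rng.normal(size=(K, d))
    covs = np.array(
        [np.eye(d) * rng.uniform(0.5, 2.0) + 0.1 * np.ones((d, d)) for _ in range(K)]
    )
    return HmmParameters(pi, A, means, covs)


def enumerate_paths(params: HmmParameters, X: np.ndarray):
    """Brute-force sum-product/max-product oracle over all K^T state paths.

    Returns (log_likelihood, gamma, best_path) where best_path breaks ties
    toward the lexicographically smaller (lower-index) path.
    """
    T, K = len(X), params.n_states
    log_probs = {}
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(params.initial_probs[path[0]])
        for t in range(1, T):
            lp += np.log(params.transition[path[t - 1], path[t]])
        for t in range(T):
            lp += multivariate_normal.logpdf(
                X[t], params.means[path[t]], params.covariances[path[t]]
            )
        log_probs[path] = lp
    lps = np.array(list(log_probs.values()))
    m = lps.max()
    ll = float(np.log(np.exp(lps - m).sum()) + m)
    gamma = np.zeros((T, K))
    for path, lp in log_probs.items():
        w = np.exp(lp - ll)
        for t, s in enumerate(path):
            gamma[t, s] += w
    best = min(log_probs, key=lambda p: (-log_probs[p], p))
    return ll, gamma, np.array(best)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def simulate_hmm_sequence(params: HmmParameters, T: int, rng: np.random.Generator):
    """Draw a state path and observations from a Gaussian-emission HMM."""
    K, d = params.n_states, params.n_features
    states = np.empty(T, dtype=int)
    X = np.empty((T, d))
    states[0] = rng.choice(K, p=params.initial_probs)
    for t in range(1, T):
        states[t] = rng.choice(K, p=params.transition[states[t - 1]])
    for t in range(T):
        X[t] = rng.multivariate_normal(params.means[states[t]], params.covariances[states[t]])
    return states, X
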