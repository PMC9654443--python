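import numpy as np
import pytest

from depscreen import (
    HmmParameters,
    InsufficientDataError,
    ValidationError,
    decode_gamma_argmax,
    fit_em,
    log_forward_backward,
    select_k,
    viterbi,
)
from depscreen.hmm import PosteriorGamma, n_parameters

from conftest import enumerate_paths, random_hmm, simulate_hmm_sequence


class TestForwardBackward:
    def test_matches_brute_force_enumeration(self):
        """Posterior marginals and likelihood equal the sum over all K^T paths."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            K = int(rng.integers(1, 4))
            T = int(rng.integers(1, 9 - K))  # keep K^T enumerable
            d = int(rng.integers(1, 3))
            params = random_hmm(rng, K, d)
            X = rng.normal(size=(T, d))
            post = log_forward_backward(params, X)
            ll, gamma, _ = enumerate_paths(params, X)
            assert post.log_likelihood == pytest.approx(ll, abs=1e-10)
            assert np.abs(post.gamma - gamma).max() < 1e-10

    def test_single_state_collapses_to_iid_loglik(self, rng):
        from scipy.stats import multivariate_normal

        params = HmmParameters([1.0], [[1.0]], np.zeros((1, 2)), np.eye(2)[None])
        X = rng.normal(size=(50, 2))
        post = log_forward_backward(params, X)
        assert np.allclose(post.gamma, 1.0)
        expected = multivariate_normal.logpdf(X, np.zeros(2), np.eye(2)).sum()
        assert post.log_likelihood == pytest.approx(expected, rel=1e-12)

    def test_symmetric_states_give_uniform_posterior(self, rng):
        K = 3
        params = HmmParameters(
            np.full(K, 1 / K), np.full((K, K), 1 / K),
            np.zeros((K, 2)), np.broadcast_to(np.eye(2), (K, 2, 2)).copy(),
        )
        X = rng.normal(size=(20, 2))
        post = log_forward_backward(params, X)
        assert np.abs(post.gamma - 1 / K).max() < 1e-12

    def test_gamma_rows_normalized_and_long_sequences_stable(self, rng):
        params = random_hmm(rng, 3, 2)
        X = rng.normal(size=(20_000, 2)) * 5  # far tails stress underflow
        post = log_forward_backward(params, X)
        assert np.isfinite(post.log_likelihood)
        assert np.abs(post.gamma.sum(axis=1) - 1).max() < 1e-8
        assert post.gamma.min() >= 0 and post.gamma.max() <= 1

    def test_agreement_with_hmmlearn(self, rng):
        """Independent cross-check of the likelihood against hmmlearn."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = random_hmm(rng, 3, 2)
        X = rng.normal(size=(200, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = params.initial_probs
        ref.transmat_ = params.transition
        ref.means_ = params.means
        ref.covars_ = params.covariances
        assert log_forward_backward(params, X).log_likelihood == pytest.approx(
            ref.score(X), rel=1e-10
        )

    def test_dimension_and_finiteness_validation(self, rng):
        params = random_hmm(rng, 2, 3)
        with pytest.raises(ValidationError):
            log_forward_backward(params, rng.normal(size=(5, 2)))
        X = rng.normal(size=(5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValidationError):
            log_forward_backward(params, X)


class TestViterbi:
    def test_matches_enumerated_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            K = int(rng.integers(1, 4))
            T = int(rng.integers(1, 9 - K))
            params = random_hmm(rng, K, 1)
            X = rng.normal(size=(T, 1))
            _, _, best = enumerate_paths(params, X)
            np.testing.assert_array_equal(viterbi(params, X).states, best)

    def test_single_state_constant_path(self, rng):
        params = HmmParameters([1.0], [[1.0]], np.zeros((1, 1)), np.eye(1)[None])
        assert (viterbi(params, rng.normal(size=(9, 1))).states == 0).all()

    def test_sticky_chain_piecewise_constant(self):
        params = HmmParameters(
            [0.5, 0.5], [[0.999, 0.001], [0.001, 0.999]],
            np.array([[-3.0], [3.0]]), np.broadcast_to(np.eye(1), (2, 1, 1)).copy(),
        )
        X = np.array([-3, -3.2, -2.9, -3.1, 3.0, 2.8, 3.1, 2.9])[:, None]
        path = viterbi(params, X).states
        switches = (np.diff(path) != 0).sum()
        assert switches <= 1
        _, _, best = enumerate_paths(params, X)
        np.testing.assert_array_equal(path, best)


class TestGammaArgmaxDecoding:
    def test_row_argmax_and_tie_breaks(self):
        g = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0], [1 / 3, 1 / 3, 1 / 3]])
        path = decode_gamma_argmax(PosteriorGamma(g, np.zeros((3, 3)), 0.0))
        np.testing.assert_array_equal(path.states, [1, 0, 0])
        assert path.method == "gamma_argmax"


class TestFitEm:
    def test_two_state_parameter_recovery(self, rng):
        """Well-separated 2-state chain: means and transitions recovered."""
        truth = HmmParameters(
            [0.6, 0.4], [[0.92, 0.08], [0.06, 0.94]],
            np.array([[0.0, 0.0], [5.0, 5.0]]),
            np.broadcast_to(np.eye(2), (2, 2, 2)).copy(),
        )
        _, X = simulate_hmm_sequence(truth, 2000, rng)
        params, report = fit_em(X, 2, n_restarts=3, seed=0)
        order = np.argsort(params.means[:, 0])
        assert np.abs(params.means[order] - truth.means).max() < 0.1
        perm_A = params.transition[np.ix_(order, order)]
        assert np.abs(perm_A - truth.transition).max() < 0.05

    def test_monotone_log_likelihood(self, rng):
        X = rng.normal(size=(300, 3))
        _, report = fit_em(X, 2, n_restarts=2, max_iter=50, seed=1)
        trace = report.log_likelihood_trace
        assert (np.diff(trace) >= -1e-8).all()

    def test_single_state_closed_form(self, rng):
        X = rng.normal(size=(100, 2)) @ np.array([[1.0, 0.3], [0.0, 1.0]])
        cov_reg = 1e-4
        params, _ = fit_em(X, 1, n_restarts=1, cov_reg=cov_reg, seed=0)
        np.testing.assert_allclose(params.means[0], X.mean(axis=0), atol=1e-10)
        expected = np.cov(X, rowvar=False, ddof=0) + cov_reg * np.eye(2)
        np.testing.assert_allclose(params.covariances[0], expected, atol=1e-8)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(200, 2))
        p1, _ = fit_em(X, 2, n_restarts=2, seed=5)
        p2, _ = fit_em(X, 2, n_restarts=2, seed=5)
        np.testing.assert_array_equal(p1.means, p2.means)
        np.testing.assert_array_equal(p1.transition, p2.transition)

    def test_recovery_bias_shrinks_with_sequence_length(self):
        truth = HmmParameters(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]],
            np.array([[0.0], [3.0]]), np.broadcast_to(np.eye(1), (2, 1, 1)).copy(),
        )

        def mean_error(T, seed):
            rng = np.random.default_rng(seed)
            _, X = simulate_hmm_sequence(truth, T, rng)
            params, _ = fit_em(X, 2, n_restarts=2, seed=seed)
            order = np.argsort(params.means[:, 0])
            return np.abs(params.means[order] - truth.means).max()

        short = np.mean([mean_error(200, s) for s in range(4)])
        long = np.mean([mean_error(2000, s) for s in range(4)])
        assert long < short

    def test_generator_relabeling_invariance(self, rng):
        """Permuting the generating state labels leaves the fit invariant up to permutation."""
        truth = HmmParameters(
            [0.5, 0.5], [[0.9, 0.1], [0.2, 0.8]],
            np.array([[0.0], [4.0]]), np.broadcast_to(np.eye(1), (2, 1, 1)).copy(),
        )
        swapped = HmmParameters(
            truth.initial_probs[::-1].copy(), truth.transition[::-1, ::-1].copy(),
            truth.means[::-1].copy(), truth.covariances[::-1].copy(),
        )
        _, X1 = simulate_hmm_sequence(truth, 800, np.random.default_rng(3))
        _, X2 = simulate_hmm_sequence(swapped, 800, np.random.default_rng(3))
        p1, _ = fit_em(X1, 2, n_restarts=2, seed=0)
        p2, _ = fit_em(X2, 2, n_restarts=2, seed=0)
        o1, o2 = np.argsort(p1.means[:, 0]), np.argsort(p2.means[:, 0])
        assert np.abs(p1.means[o1] - p2.means[o2]).max() < 0.5

    def test_insufficient_data_and_zero_variance(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_em(rng.normal(size=(2, 1)), 2)
        X = rng.normal(size=(50, 2))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            params, _ = fit_em(X, 1, n_restarts=1, seed=0)
        assert np.isfinite(params.covariances).all()


class TestSelectK:
    def test_bic_recovers_three_states(self):
        truth = HmmParameters(
            np.full(3, 1 / 3),
            np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]),
            np.array([[-4.0], [0.0], [4.0]]),
            np.broadcast_to(np.eye(1), (3, 1, 1)).copy(),
        )
        _, X = simulate_hmm_sequence(truth, 3000, np.random.default_rng(0))
        table = select_k(X, k_grid=(1, 2, 3, 4), n_restarts=2, seed=0)
        assert int(table.loc[table["BIC"].idxmin(), "K"]) == 3

    def test_white_noise_prefers_one_state(self, rng):
        X = rng.normal(size=(1000, 2))
        table = select_k(X, k_grid=(1, 2), n_restarts=2, seed=0)
        bic = table.set_index("K")["BIC"]
        assert bic[1] < bic[2]

    def test_aic_formula_identity(self, rng):
        X = rng.normal(size=(200, 2))
        table = select_k(X, k_grid=(2,), n_restarts=1, seed=0)
        row = table.iloc[0]
        assert row["n_params"] == n_parameters(2, 2)
        assert row["AIC"] == pytest.approx(-2 * row["log_likelihood"] + 2 * row["n_params"])
        assert row["BIC"] == pytest.approx(
            -2 * row["log_likelihood"] + row["n_params"] * np.log(200)
        )
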