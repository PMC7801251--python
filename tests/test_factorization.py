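import numpy as np
import pytest
from scipy.stats import pearsonr

from dctnet import (
    ExpressionMatrix,
    estimate_conserved_correlation,
    jcnmf_fit,
)
from dctnet.factorization import _objective_one


def _em(label, values, tissues=None, genes=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(label,
                            tissues or [f"t{i}" for i in range(m)],
                            genes or [f"g{i}" for i in range(n)],
                            values)


class TestConservedCorrelation:
    def test_proportional_rows_give_one(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 5, 30)
        X = _em("c", np.vstack([base, 2 * base]))
        R = estimate_conserved_correlation(X, X).R
        assert R[0, 1] == pytest.approx(1.0)

    def test_uncorrelated_rows_clip_to_identity(self):
        # rows chosen so their sample correlation is exactly zero
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 0.0, 0.0, 2.0])
        assert pearsonr(a, b).statistic == pytest.approx(0.0, abs=1e-12)
        X = _em("c", np.vstack([a, b]))
        np.testing.assert_allclose(estimate_conserved_correlation(X, X).R,
                                   np.eye(2), atol=1e-12)

    def test_matches_elementwise_pcc_oracle(self, small_pair):
        X1, X2 = small_pair
        R = estimate_conserved_correlation(X1, X2).R
        m = X1.n_tissues
        oracle = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                r1 = pearsonr(X1.values[i], X1.values[j]).statistic
                r2 = pearsonr(X2.values[i], X2.values[j]).statistic
                oracle[i, j] = oracle[j, i] = max(0.0, (r1 + r2) / 2.0)
        np.testing.assert_allclose(R, oracle, atol=1e-12)

    def test_zero_variance_tissue_named(self):
        X = _em("c", [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                tissues=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            estimate_conserved_correlation(X, X)

    def test_bounds_and_symmetry(self, small_pair):
        cc = estimate_conserved_correlation(*small_pair)
        R = cc.R
        assert np.all(R >= 0) and np.all(R <= 1)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)


def _exact_low_rank(seed, m=7, k=3, n=40):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, (m, k))
    H = rng.uniform(0.1, 1.0, (k, n))
    X = W @ H
    return _em("case", X), _em("control", X)


class TestSolver:
    def test_exact_low_rank_reconstruction(self):
        X1, X2 = _exact_low_rank(0)
        fit = jcnmf_fit(X1, X2, k=3, mode="none", max_iter=2000, tol=0.0,
                        seed=0, n_restarts=3)
        assert fit.reconstruction_error(X1.values, X2.values) < 1e-3

    def test_hard_mode_residual_exactly_zero(self, small_pair):
        fit = jcnmf_fit(*small_pair, k=2, mode="hard", max_iter=200, seed=1)
        assert fit.constraint_residual == 0.0
        assert fit.W1 is fit.W2

    def test_lambda_zero_soft_equals_none(self, small_pair):
        soft = jcnmf_fit(*small_pair, k=2, lambda_=0.0, mode="soft",
                         max_iter=300, tol=0.0, seed=5, n_restarts=2)
        none = jcnmf_fit(*small_pair, k=2, mode="none",
                         max_iter=300, tol=0.0, seed=5, n_restarts=2)
        assert abs(soft.objective - none.objective) <= 1e-10 * none.objective

    @pytest.mark.parametrize("seed", range(20))
    def test_trace_monotone_mode_none(self, seed):
        rng = np.random.default_rng(seed)
        X1 = _em("case", rng.uniform(0, 5, (5, 30)))
        X2 = _em("control", rng.uniform(0, 5, (5, 30)))
        fit = jcnmf_fit(X1, X2, k=3, mode="none", max_iter=150, tol=0.0,
                        seed=seed, n_restarts=1)
        trace = np.array(fit.objective_trace)
        # slack anchored to the problem scale: at exact convergence the
        # residual is floating-point noise and per-step ratios are undefined
        assert np.all(np.diff(trace) <= 1e-12 * trace[0])

    @pytest.mark.parametrize("seed", range(20))
    def test_trace_monotone_mode_soft(self, seed):
        rng = np.random.default_rng(100 + seed)
        X1 = _em("case", rng.uniform(0, 5, (5, 30)))
        X2 = _em("control", rng.uniform(0, 5, (5, 30)))
        fit = jcnmf_fit(X1, X2, k=3, lambda_=1.0, mode="soft",
                        max_iter=150, tol=0.0, seed=seed, n_restarts=1)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace)
                      <= np.maximum(1e-9 * trace[:-1], 1e-12 * trace[0]))

    @pytest.mark.parametrize("mode", ["none", "soft", "hard"])
    def test_factors_nonnegative(self, small_pair, mode):
        fit = jcnmf_fit(*small_pair, k=2, mode=mode, max_iter=100, seed=2)
        for M in (fit.W1, fit.W2, fit.H1, fit.H2):
            assert np.all(M >= 0)

    def test_reproducible_bit_identical(self, small_pair):
        a = jcnmf_fit(*small_pair, k=2, mode="soft", max_iter=100, seed=9)
        b = jcnmf_fit(*small_pair, k=2, mode="soft", max_iter=100, seed=9)
        for x, y in ((a.W1, b.W1), (a.H1, b.H1), (a.W2, b.W2), (a.H2, b.H2)):
            np.testing.assert_array_equal(x, y)
        assert a.objective_trace == b.objective_trace

    def test_different_seeds_differ(self, small_pair):
        a = jcnmf_fit(*small_pair, k=2, mode="none", max_iter=50, seed=1,
                      n_restarts=1)
        b = jcnmf_fit(*small_pair, k=2, mode="none", max_iter=50, seed=2,
                      n_restarts=1)
        assert not np.array_equal(a.W1, b.W1)

    def test_k_too_large_rejected(self, small_pair):
        with pytest.raises(ValueError):
            jcnmf_fit(*small_pair, k=4, mode="none")

    def test_all_zero_input_rejected(self):
        Z = _em("case", np.zeros((3, 10)))
        with pytest.raises(ValueError):
            jcnmf_fit(Z, Z, k=2, mode="none")

    def test_scale_consistency_objective_identity(self, small_pair):
        # J(W, cH; cX, c^2 lambda) = c^2 J(W, H; X, lambda) algebraically
        X1, _ = small_pair
        rng = np.random.default_rng(4)
        W = rng.uniform(0.1, 1, (3, 2))
        H = rng.uniform(0.1, 1, (2, 50))
        R = np.eye(3)
        c, lam = 3.7, 0.8
        lhs = _objective_one(c * X1.values, W, c * H, c * c * lam, R)
        rhs = c * c * _objective_one(X1.values, W, H, lam, R)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_scale_consistency_mode_none_trajectory(self, small_pair):
        X1, X2 = small_pair
        c = 2.5
        sX1 = _em("case", c * X1.values)
        sX2 = _em("control", c * X2.values)
        base = jcnmf_fit(X1, X2, k=2, mode="none", max_iter=80, tol=0.0,
                         seed=7, n_restarts=1)
        scaled = jcnmf_fit(sX1, sX2, k=2, mode="none", max_iter=80, tol=0.0,
                           seed=7, n_restarts=1)
        ratio = np.array(scaled.objective_trace) / np.array(base.objective_trace)
        np.testing.assert_allclose(ratio, c * c, rtol=1e-8)

    def test_residual_nonincreasing_in_lambda(self, default_synthetic):
        case, control, _ = default_synthetic
        resids = []
        for lam in (0.0, 0.1, 1.0, 10.0):
            fit = jcnmf_fit(case, control, k=7, lambda_=lam, mode="soft",
                            max_iter=800, tol=1e-7, seed=1, n_restarts=1)
            resids.append(fit.constraint_residual)
        for lo, hi in zip(resids[1:], resids[:-1]):
            assert lo <= hi * (1 + 1e-9)
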