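import numpy as np
import pytest

from mspls import EmptyModelError, PenaltySpec, enet_update, lambda_for_cardinality, ust_update
from mspls.penalties import enet_objective


def _standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0, ddof=1)
    return X


class TestUst:
    def test_no_threshold_limit(self, rng):
        X = _standardized(rng, 20, 5)
        zt = rng.standard_normal(20)
        np.testing.assert_allclose(ust_update(X, zt, 0.0), X.T @ zt)

    def test_full_shrinkage_is_error(self, rng):
        X = _standardized(rng, 20, 5)
        zt = rng.standard_normal(20)
        lam = 2.0 * np.max(np.abs(X.T @ zt)) + 1e-9
        with pytest.raises(EmptyModelError, match="too large"):
            ust_update(X, zt, lam)

    def test_matches_per_coordinate_minimization(self, rng):
        # independent oracle: numerically minimize the lambda2->inf objective
        # coordinate-wise, w_j^2 - 2 c_j w_j + lam |w_j|
        X = _standardized(rng, 20, 5)
        zt = rng.standard_normal(20)
        lam = 1.1 * np.median(np.abs(X.T @ zt)) * 2
        w = ust_update(X, zt, lam)
        c = X.T @ zt

        def golden(f, lo, hi, iters=200):
            phi = (np.sqrt(5) - 1) / 2
            a, b = lo, hi
            x1, x2 = b - phi * (b - a), a + phi * (b - a)
            f1, f2 = f(x1), f(x2)
            for _ in range(iters):
                if f1 <= f2:
                    b, x2, f2 = x2, x1, f1
                    x1 = b - phi * (b - a)
                    f1 = f(x1)
                else:
                    a, x1, f1 = x1, x2, f2
                    x2 = a + phi * (b - a)
                    f2 = f(x2)
            return (a + b) / 2

        for j in range(5):
            cj = np.longdouble(c[j])  # extended precision: the quadratic is
            lamL = np.longdouble(lam)  # flat near its minimum at float64

            def obj(v):
                v = np.longdouble(v)
                return v * v - 2 * cj * v + lamL * abs(v)

            xstar = golden(obj, -2 * abs(c[j]) - 1, 2 * abs(c[j]) + 1)
            assert abs(w[j] - xstar) < 1e-8

    def test_support_is_exactly_above_half_lambda(self, rng):
        X = _standardized(rng, 25, 8)
        zt = rng.standard_normal(25)
        c = np.abs(X.T @ zt)
        lam = float(np.median(c)) * 2
        w = ust_update(X, zt, lam)
        np.testing.assert_array_equal(w != 0, c > lam / 2)

    def test_selection_path_monotone_in_lambda(self, rng):
        X = _standardized(rng, 25, 10)
        zt = rng.standard_normal(25)
        lams = np.linspace(0, 1.9 * np.max(np.abs(X.T @ zt)), 15)
        nnz = []
        for lam in lams:
            try:
                nnz.append(int(np.count_nonzero(ust_update(X, zt, lam))))
            except EmptyModelError:
                nnz.append(0)
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestEnet:
    def test_unpenalized_equals_normal_equations(self, rng):
        X = _standardized(rng, 30, 3)
        zt = rng.standard_normal(30)
        w = enet_update(X, zt, 0.0, 0.0)
        oracle = np.linalg.solve(X.T @ X, X.T @ zt)
        np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_unpenalized_high_dimensional_refused(self, rng):
        X = _standardized(rng, 10, 20)
        with pytest.raises(np.linalg.LinAlgError):
            enet_update(X, rng.standard_normal(10), 0.0, 0.0)

    @pytest.mark.parametrize("lam2", [1e3, 1e6])
    def test_large_ridge_limit_matches_ust(self, rng, lam2):
        X = _standardized(rng, 20, 6)
        zt = rng.standard_normal(20)
        lam1 = float(np.median(np.abs(X.T @ zt)))
        w_enet = enet_update(X, zt, lam1, lam2)
        w_ust = ust_update(X, zt, lam1)
        nz = w_ust != 0
        # agreement tightens as lambda2 grows; 1e-3 relative is the contract
        # at lambda2=1e6
        rel = 1e-3 if lam2 >= 1e6 else 5e-2
        np.testing.assert_allclose(w_enet[nz], w_ust[nz], rtol=rel)
        assert np.allclose(w_enet[~nz], 0.0, atol=1e-3)

    def test_objective_non_increasing_over_sweeps(self, rng):
        X = _standardized(rng, 25, 8)
        zt = rng.standard_normal(25)
        lam1, lam2 = 2.0, 0.5
        vals = []
        for sweeps in range(1, 8):
            w = enet_update(X, zt, lam1, lam2, tol=0.0, max_sweeps=sweeps)
            vals.append(enet_objective(X, zt, w, lam1, lam2))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestCardinality:
    def test_k_equals_p_means_no_selection(self, rng):
        X = _standardized(rng, 15, 4)
        assert lambda_for_cardinality(X, rng.standard_normal(15), 4) == 0.0

    def test_top_k_support(self):
        # construct a block whose |c| ranking is known: c = X' zt
        n = 12
        zt = np.zeros(n)
        zt[0], zt[1] = 1.0, -1.0
        cols = [zt * s for s in (5, 4, 3, 2, 1)]
        rng = np.random.default_rng(0)
        X = np.column_stack(cols) + 1e-6 * rng.standard_normal((n, 5))
        lam = lambda_for_cardinality(X, zt, 2)
        w = ust_update(X, zt, lam)
        assert np.count_nonzero(w) == 2
        assert set(np.flatnonzero(w)) == {0, 1}

    def test_tie_keeps_all_tied(self):
        n = 10
        zt = np.zeros(n)
        zt[0] = 1.0
        X = np.column_stack([zt * 3, zt * 2, zt * 2, zt * 1])
        with pytest.warns(UserWarning, match="tie"):
            lam = lambda_for_cardinality(X, zt, 2)
        w = ust_update(X, zt, lam)
        assert np.count_nonzero(w) == 3  # the tied pair is kept whole

    def test_k_out_of_range(self, rng):
        X = _standardized(rng, 15, 4)
        with pytest.raises(ValueError):
            lambda_for_cardinality(X, rng.standard_normal(15), 5)


def test_penalty_spec_validation():
    with pytest.raises(ValueError):
        PenaltySpec(kind="lasso")
    with pytest.raises(ValueError):
        PenaltySpec(kind="cardinality")
    spec = PenaltySpec(kind="ust", lambda1={"X1": 0.5, "X2": 0.7})
    assert spec.lambda1_for("X2") == 0.7
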