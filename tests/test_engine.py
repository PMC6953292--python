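import numpy as np
import pytest
from scipy.linalg import eigh

from mspls import (
    ConnectivityMatrix,
    EmptyModelError,
    MultiBlockDataset,
    OmicsBlock,
    PenaltySpec,
    fit,
)
from mspls.engine import (
    compute_lv,
    estimate_inner,
    reestimate_lvs,
    update_weights_modeA,
)


def _unit_lvs(rng, n, Q):
    Z = rng.standard_normal((n, Q))
    Z -= Z.mean(axis=0)
    Z /= Z.std(axis=0, ddof=1)
    return Z


class TestComputeLv:
    def test_single_column_identity(self, rng):
        x = rng.standard_normal(20)
        x = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(compute_lv(x[:, None], [1.0]), x, atol=1e-12)

    def test_unit_variance_contract(self, rng):
        X = rng.standard_normal((30, 4))
        z = compute_lv(X, [1.0, -2.0, 0.0, 3.0])
        assert abs(z.std(ddof=1) - 1) < 1e-10
        assert abs(z.mean()) < 1e-12

    def test_perfect_correlation_with_projection(self, rng):
        X = rng.standard_normal((30, 4))
        w = np.array([1.0, -2.0, 0.0, 3.0])
        z = compute_lv(X, w)
        assert abs(np.corrcoef(z, X @ w)[0, 1] - 1) < 1e-12

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            compute_lv(rng.standard_normal((10, 3)), np.zeros(3))


class TestEstimateInner:
    def test_worked_three_block_pattern(self, rng):
        C = ConnectivityMatrix([[0, 1, 0], [1, 0, 0], [1, 1, 0]])
        Z = _unit_lvs(rng, 25, 3)
        Theta = estimate_inner(C, Z)
        cor = np.corrcoef(Z.T)
        # symmetric pair entries are correlations (step b-ii overwrites b-i)
        assert Theta[1, 0] == pytest.approx(cor[0, 1], abs=1e-12)
        assert Theta[0, 1] == pytest.approx(cor[0, 1], abs=1e-12)
        assert Theta[2, 0] == pytest.approx(cor[0, 2], abs=1e-12)
        assert Theta[2, 1] == pytest.approx(cor[1, 2], abs=1e-12)
        # the column feeding the terminal block comes from two-regressor OLS
        Ze = Z[:, :2]
        oracle = np.linalg.solve(Ze.T @ Ze, Ze.T @ Z[:, 2])
        np.testing.assert_allclose(Theta[:2, 2], oracle, atol=1e-12)
        assert np.all(np.diag(Theta) == 0)

    def test_identical_pair_gives_unit_correlation(self, rng):
        C = ConnectivityMatrix([[0, 1], [1, 0]])
        z = rng.standard_normal(20)
        z = (z - z.mean()) / z.std(ddof=1)
        Z = np.column_stack([z, z])
        Theta = estimate_inner(C, Z)
        assert Theta[0, 1] == pytest.approx(1.0)
        assert Theta[1, 0] == pytest.approx(1.0)

    def test_sparsity_pattern_matches_relations(self, rng):
        C = ConnectivityMatrix([[0, 1, 0], [1, 0, 0], [1, 1, 0]])
        Theta = estimate_inner(C, _unit_lvs(rng, 40, 3))
        allowed = (C.C.T | C.C).astype(bool)
        assert np.all(Theta[~allowed] == 0)


class TestReestimate:
    def test_single_entry_selection(self, rng):
        Z = _unit_lvs(rng, 15, 3)
        Theta = np.zeros((3, 3))
        Theta[0, 1] = 1.0
        Zt = reestimate_lvs(Z, Theta)
        np.testing.assert_allclose(Zt[:, 1], Z[:, 0])

    def test_zero_theta_is_error(self, rng):
        with pytest.raises(ValueError, match="zero"):
            reestimate_lvs(_unit_lvs(rng, 15, 3), np.zeros((3, 3)))

    def test_matches_naive_summation(self, rng):
        Z = _unit_lvs(rng, 15, 3)
        Theta = rng.standard_normal((3, 3))
        Zt = reestimate_lvs(Z, Theta)
        naive = np.zeros_like(Zt)
        for q in range(3):
            for m in range(3):
                naive[:, q] += Z[:, m] * Theta[m, q]
        np.testing.assert_allclose(Zt, naive, atol=1e-14)


class TestModeA:
    def test_self_regression_weight_one(self, rng):
        zt = rng.standard_normal(20)
        assert update_weights_modeA(zt[:, None], zt)[0] == pytest.approx(1.0)

    def test_orthogonal_column_weight_zero(self, rng):
        zt = rng.standard_normal(40)
        x = rng.standard_normal(40)
        x -= (x @ zt) / (zt @ zt) * zt
        w = update_weights_modeA(x[:, None], zt)
        assert abs(w[0]) < 1e-12

    def test_matches_per_column_slopes(self, rng):
        X = rng.standard_normal((40, 6))
        zt = rng.standard_normal(40)
        w = update_weights_modeA(X, zt)
        for j in range(6):
            slope = np.linalg.lstsq(zt[:, None], X[:, j], rcond=None)[0][0]
            assert w[j] == pytest.approx(slope, abs=1e-12)


class TestFit:
    def test_two_block_symmetric_recovers_first_canonical_correlation(self, rng):
        # unpenalized symmetric pair: the stationary point is the CCA solution
        n, p1, p2 = 30, 4, 3
        X = rng.standard_normal((n, p1))
        Y = 0.6 * X[:, :2] @ rng.standard_normal((2, p2)) + rng.standard_normal((n, p2))
        ds = MultiBlockDataset([OmicsBlock("A", X), OmicsBlock("B", Y)]).standardize()
        C = ConnectivityMatrix([[0, 1], [1, 0]])
        f = fit(ds, C)
        r = abs(np.corrcoef(f.scores["A"], f.scores["B"])[0, 1])
        S11 = ds["A"].values.T @ ds["A"].values
        S22 = ds["B"].values.T @ ds["B"].values
        S12 = ds["A"].values.T @ ds["B"].values
        M = np.linalg.solve(S11, S12) @ np.linalg.solve(S22, S12.T)
        rho1 = np.sqrt(np.max(np.linalg.eigvals(M).real))
        assert r == pytest.approx(rho1, abs=1e-6)
        # the response-branch objective equals rho1^2 for each block
        assert f.of_per_block["A"] == pytest.approx(rho1**2, abs=1e-6)

    def test_asymmetric_pair_matches_redundancy_analysis(self, rng):
        # one explanatory block (Mode B, unpenalized), one terminal response
        # block (Mode A): the explanatory weights maximize the sum of squared
        # correlations with the response MVs — the RDA dominant eigenvector
        n, p1, p2 = 40, 5, 3
        X = rng.standard_normal((n, p1))
        Y = 0.8 * np.outer(X @ rng.standard_normal(p1), rng.standard_normal(p2))
        Y += rng.standard_normal((n, p2))
        ds = MultiBlockDataset([OmicsBlock("E", X), OmicsBlock("R", Y)]).standardize()
        C = ConnectivityMatrix([[0, 0], [1, 0]])  # E explanatory for R
        f = fit(ds, C)
        Xs, Ys = ds["E"].values, ds["R"].values
        S11 = Xs.T @ Xs / (n - 1)
        S12 = Xs.T @ Ys / (n - 1)
        mu = eigh(S12 @ S12.T, S11, eigvals_only=True)[-1]
        assert f.of_per_block["R"] == pytest.approx(mu, abs=1e-6)
        assert f.modes == {"E": "B", "R": "A"}

    def test_converged_contract(self, toy_dataset3, C3):
        f = fit(toy_dataset3, C3, PenaltySpec("ust", lambda1=0.1))
        assert f.converged
        assert f.crt_trace[-1] < 1e-6
        assert len(f.crt_trace) == f.n_iter
        for z in f.scores.values():
            assert abs(z.std(ddof=1) - 1) < 1e-10
        for w in f.weights.values():
            assert np.linalg.norm(w) == pytest.approx(1.0)
            assert w[np.argmax(np.abs(w))] > 0  # sign alignment

    def test_theta_sparsity_pattern(self, toy_dataset3, C3):
        f = fit(toy_dataset3, C3, PenaltySpec("ust", lambda1=0.1))
        allowed = (C3.C.T | C3.C).astype(bool)
        assert np.all(f.theta[~allowed] == 0)
        # entries fed by responses are correlations, hence within [-1, 1]
        for q in range(3):
            for m in C3.responses(q):
                assert abs(f.theta[m, q]) <= 1.0

    def test_unpenalized_high_dimensional_mode_b_refused(self, rng):
        n = 10
        ds = MultiBlockDataset(
            [
                OmicsBlock("A", rng.standard_normal((n, 30))),
                OmicsBlock("B", rng.standard_normal((n, 3))),
            ]
        ).standardize()
        C = ConnectivityMatrix([[0, 1], [1, 0]])
        with pytest.raises(np.linalg.LinAlgError):
            fit(ds, C)

    def test_cardinality_penalty_hits_target_support(self, toy_dataset3, C3):
        f = fit(toy_dataset3, C3, PenaltySpec("cardinality", k_target=3))
        for name in ("X1", "X2"):  # penalized blocks only
            assert int(np.count_nonzero(f.weights[name])) == 3
        assert f.converged

    def test_too_large_lambda_advises_smaller(self, toy_dataset3, C3):
        with pytest.raises(EmptyModelError, match="too large"):
            fit(toy_dataset3, C3, PenaltySpec("ust", lambda1=50.0))

    def test_crt_decreases_to_tolerance_quickly(self, toy_dataset3, C3):
        f = fit(toy_dataset3, C3)
        assert f.converged and f.n_iter <= 100
        assert np.all(np.isfinite(f.crt_trace))
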