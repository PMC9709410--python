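"""Sparseness measures and the alternating analysis-dictionary learner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosparse_eeg import sparse_model as sm


def det3_cofactor(M):
    """Independent 3x3 determinant by cofactor expansion."""
    return (M[0, 0] * (M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1])
            - M[0, 1] * (M[1, 0] * M[2, 2] - M[1, 2] * M[2, 0])
            + M[0, 2] * (M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0]))


class TestSparsityMeasure:
    @pytest.mark.parametrize("kind", ["l0", "l1", "l2"])
    def test_zero_vector(self, kind):
        assert sm.sparsity_measure(np.zeros(3), kind) == 0.0

    def test_direct_formulas(self):
        g = np.array([3.0, -4.0])
        assert sm.sparsity_measure(g, "l1") == 7.0
        assert sm.sparsity_measure(g, "l2") == 5.0

    def test_l0_threshold(self):
        g = np.array([1e-12, 2.0])
        assert sm.sparsity_measure(g, "l0", zero_tol=1e-9) == 1

    def test_unknown_kind_lists_valid(self):
        with pytest.raises(sm.MeasureError, match="l0"):
            sm.sparsity_measure(np.ones(2), "l7")


class TestDeterminantMeasure:
    def test_identity_is_one(self):
        assert sm.determinant_measure(np.eye(2)) == pytest.approx(1.0)

    def test_orthogonal_single_support_rows(self):
        Y = np.array([[0.0, 5.0, 0.0], [3.0, 0.0, 0.0]])
        assert sm.determinant_measure(Y, normalize=True) == pytest.approx(1.0)

    def test_identical_rows_give_zero(self):
        Y = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert sm.determinant_measure(Y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cofactor_oracle(self, rng):
        Y = rng.uniform(0.1, 1.0, size=(3, 4))
        Y = Y / np.linalg.norm(Y, axis=1)[:, None]
        expected = det3_cofactor(Y @ Y.T)
        assert sm.determinant_measure(Y, normalize=False) == pytest.approx(
            expected, abs=1e-10)
        assert 0.0 <= expected <= 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sm.determinant_measure(np.array([[1.0, -0.1]]))

    def test_zero_row_with_normalize_rejected(self):
        with pytest.raises(ValueError, match="zero row"):
            sm.determinant_measure(np.array([[0.0, 0.0], [1.0, 0.0]]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_row_normalized_bounds_property(self, seed):
        r = np.random.default_rng(seed)
        Y = r.uniform(0.0, 1.0, size=(r.integers(1, 5), r.integers(1, 6)))
        Y += 1e-6  # avoid zero rows
        val = sm.determinant_measure(Y, normalize=True)
        assert -1e-12 <= val <= 1.0 + 1e-12


class TestCosparsity:
    def test_identity_dictionary_counts_zeros(self):
        assert sm.cosparsity(np.eye(3), np.array([0.0, 5.0, 0.0])) == 2

    def test_zero_signal_gives_n_atoms(self, rng):
        Omega = rng.standard_normal((7, 4))
        assert sm.cosparsity(Omega, np.zeros(4)) == 7

    def test_matches_loop_oracle(self, rng):
        Omega = rng.standard_normal((6, 5))
        z = rng.standard_normal(5)
        z[rng.integers(5)] = 0.0
        tol = 0.3
        expected = sum(1 for row in Omega if abs(row @ z) <= tol)
        assert sm.cosparsity(Omega, z, zero_tol=tol) == expected

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            sm.cosparsity(np.eye(3), np.zeros(4))


class TestCodeUpdate:
    def test_l1_vanishing_penalty_limit(self, rng):
        Omega = rng.standard_normal((4, 4))
        Z = rng.standard_normal((4, 5))
        X = sm.update_code(Omega, Z, "l1", beta=1e12)
        np.testing.assert_allclose(X, Omega @ Z, atol=1e-9)

    def test_l1_scalar_prox_oracle(self):
        # min |x| + beta (x - v)^2 via dense scan, beta=0.5, v=0.7
        v, beta = 0.7, 0.5
        grid = np.linspace(-2, 2, 400001)
        best = grid[np.argmin(np.abs(grid) + beta * (grid - v) ** 2)]
        X = sm.update_code(np.array([[1.0]]), np.array([[v]]), "l1", beta)
        assert X[0, 0] == pytest.approx(best, abs=1e-5)
        assert X[0, 0] == pytest.approx(0.0, abs=1e-12)  # 0.7 - 1.0 < 0

    def test_l0_scalar_enumeration_oracle(self):
        # min 1{x!=0} + beta (x - v)^2: candidates are 0 and v
        beta = 1.0
        for v, want in [(0.5, 0.0), (2.0, 2.0)]:
            X = sm.update_code(np.array([[1.0]]), np.array([[v]]), "l0", beta)
            cand = {0.0: 0.0 + beta * v ** 2, v: 1.0}
            assert X[0, 0] == min(cand, key=cand.get) == want

    def test_determinant_update_non_negative_and_improving(self, rng):
        Omega = rng.standard_normal((3, 6))
        Z = rng.uniform(0.2, 1.0, size=(6, 4))
        beta = 1.0
        V = Omega @ Z
        X = sm.update_code(Omega, Z, "determinant", beta)
        assert np.all(X >= 0)
        f = lambda M: -sm.determinant_measure(np.abs(M) + 1e-12) \
            + beta * np.linalg.norm(V - M) ** 2
        assert f(X) <= f(np.maximum(V, 0.0)) + 1e-9

    def test_unknown_measure(self):
        with pytest.raises(sm.MeasureError):
            sm.update_code(np.eye(2), np.eye(2), "l7", 1.0)


class TestSignalUpdate:
    def test_beta_zero_returns_T(self, rng):
        T = rng.standard_normal((4, 6))
        Z = sm.update_signal(T, rng.standard_normal((3, 4)),
                             rng.standard_normal((3, 6)), lam=1.0, beta=0.0)
        np.testing.assert_array_equal(Z, T)

    def test_dominant_fidelity_limit(self, rng):
        T = rng.standard_normal((4, 6))
        Omega = rng.standard_normal((3, 4))
        X = rng.standard_normal((3, 6))
        Z = sm.update_signal(T, Omega, X, lam=1e12, beta=1.0)
        np.testing.assert_allclose(Z, T, rtol=1e-6)

    def test_matches_dense_inverse_oracle(self, rng):
        p, n, N = 5, 4, 7
        T = rng.standard_normal((p, N))
        Omega = rng.standard_normal((n, p))
        X = rng.standard_normal((n, N))
        lam, beta = 0.7, 1.3
        A = lam * np.eye(p) + beta * Omega.T @ Omega
        expected = np.linalg.inv(A) @ (lam * T + beta * Omega.T @ X)
        Z = sm.update_signal(T, Omega, X, lam, beta)
        np.testing.assert_allclose(Z, expected, atol=1e-8)


class TestDictionaryUpdate:
    def test_identity_system(self):
        X = np.array([[0.6, 0.8], [1.0, 0.0]])
        Omega = sm.update_dictionary(np.eye(2), X, method="project")
        np.testing.assert_allclose(Omega, X, atol=1e-12)

    def test_zero_target_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            sm.update_dictionary(np.eye(3), np.zeros((2, 3)), method="project")

    def test_project_matches_normal_equations_oracle(self, rng):
        Z = rng.standard_normal((4, 6))
        X = rng.standard_normal((4, 6))
        Omega = sm.update_dictionary(Z, X, method="project")
        pre = X @ Z.T @ np.linalg.inv(Z @ Z.T)
        np.testing.assert_allclose(
            Omega, pre / np.linalg.norm(pre, axis=1)[:, None], atol=1e-8)

    def test_exact_beats_or_matches_projection(self, rng):
        for _ in range(5):
            Z = rng.standard_normal((5, 8))
            X = rng.standard_normal((4, 8))
            exact = sm.update_dictionary(Z, X, method="exact")
            proj = sm.update_dictionary(Z, X, method="project")
            r = lambda O: np.linalg.norm(O @ Z - X) ** 2
            assert r(exact) <= r(proj) + 1e-9
            np.testing.assert_allclose(np.linalg.norm(exact, axis=1), 1.0,
                                       atol=1e-9)

    def test_rank_deficient_auto_ridge(self, rng):
        Z = np.zeros((4, 6))
        Z[0] = rng.standard_normal(6)   # rank 1
        X = rng.standard_normal((3, 6))
        Omega = sm.update_dictionary(Z, X, method="exact")
        np.testing.assert_allclose(np.linalg.norm(Omega, axis=1), 1.0,
                                   atol=1e-9)


class TestADLA:
    def test_fixed_point_converges_immediately(self, rng):
        # T cosparse under the initial dictionary: near-stationary objective
        cfg = sm.ADLAConfig(n_atoms=6, lam=1.0, beta=0.5, measure="l1",
                            max_iter=30, tol=1e-4, seed=0,
                            replace_duplicate_atoms=False)
        T = rng.standard_normal((6, 20)) * 1e-4   # tiny signals -> X0 ~ 0
        model = sm.adla_fit(T, cfg)
        assert len(model.objective_trace) <= 4
        np.testing.assert_allclose(model.Z, T, atol=1e-3)

    def test_trace_bookkeeping_single_sweep(self, rng):
        cfg = sm.ADLAConfig(n_atoms=4, max_iter=1, tol=1e-12, seed=0)
        model = sm.adla_fit(rng.standard_normal((5, 12)), cfg)
        assert len(model.objective_trace) == 2

    def test_unit_rows_after_fit(self, rng):
        cfg = sm.ADLAConfig(n_atoms=5, max_iter=4, seed=1)
        model = sm.adla_fit(rng.standard_normal((6, 30)), cfg)
        np.testing.assert_allclose(np.linalg.norm(model.Omega, axis=1), 1.0,
                                   atol=1e-9)

    def test_reproducible_given_seed(self, rng):
        T = rng.standard_normal((6, 24))
        cfg = sm.ADLAConfig(n_atoms=5, max_iter=5, seed=3)
        a = sm.adla_fit(T, cfg)
        b = sm.adla_fit(T, cfg)
        np.testing.assert_array_equal(a.Omega, b.Omega)
        assert a.objective_trace == b.objective_trace

    def test_objective_non_increasing_l1_and_l0(self, rng):
        for measure in ("l1", "l0"):
            cfg = sm.ADLAConfig(n_atoms=8, measure=measure, max_iter=10,
                                tol=1e-12, seed=2,
                                replace_duplicate_atoms=False)
            model = sm.adla_fit(rng.standard_normal((8, 40)), cfg)
            diffs = np.diff(model.objective_trace)
            assert np.all(diffs <= 1e-8)

    def test_planted_dictionary_beats_random(self):
        """Signals built orthogonal to subsets of a planted dictionary are
        cosparser under the learned dictionary than under a random one."""
        r = np.random.default_rng(5)
        p, n_atoms, N = 12, 12, 120
        Omega_star = r.standard_normal((n_atoms, p))
        Omega_star /= np.linalg.norm(Omega_star, axis=1)[:, None]
        cols = []
        for _ in range(N):
            rows = r.choice(n_atoms, size=7, replace=False)
            basis = np.linalg.svd(Omega_star[rows])[2][7:]   # null space
            coef = r.standard_normal(basis.shape[0])
            cols.append(basis.T @ coef)
        T = np.array(cols).T
        cfg = sm.ADLAConfig(n_atoms=n_atoms, lam=1.0, beta=10.0,
                            measure="l1", max_iter=40, tol=1e-8, seed=0)
        model = sm.adla_fit(T, cfg)
        zero_tol = 1e-3

        def mean_cosparsity(Om, Z):
            return np.mean(np.abs(Om @ Z) <= zero_tol)

        rand = r.standard_normal((n_atoms, p))
        rand /= np.linalg.norm(rand, axis=1)[:, None]
        assert mean_cosparsity(model.Omega, model.Z) > \
            mean_cosparsity(rand, model.Z)

    def test_sparsity_report_fields(self, rng):
        cfg = sm.ADLAConfig(n_atoms=4, max_iter=3, seed=0)
        model = sm.adla_fit(rng.standard_normal((5, 15)), cfg)
        rep = sm.sparsity_report(model)
        assert rep["measure_name"] == "l1"
        assert 0 <= rep["cosparsity"] <= 4
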