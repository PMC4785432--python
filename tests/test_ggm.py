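import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy.optimize import minimize

from mirlink import (
    TargetDB,
    build_zero_mask,
    cv_predict_mirna,
    fit_constrained_glasso,
    glasso_objective,
    permutation_validate,
    precision_to_regression,
    select_rho,
)


def _random_spd(rng, p, cond=0.5):
    a = rng.normal(size=(p + 3, p))
    return a.T @ a / (p + 3) + cond * np.eye(p)


class TestConstrainedGlasso:
    def test_unpenalized_full_mask_is_matrix_inverse(self, rng):
        s = _random_spd(rng, 5)
        fit = fit_constrained_glasso(s, 0.0, np.ones((5, 5), bool), tol=1e-9)
        np.testing.assert_allclose(fit.theta, np.linalg.inv(s), atol=1e-7)

    def test_forbidden_offdiagonal_two_by_two(self):
        s = np.array([[2.0, 0.8], [0.8, 4.0]])
        fit = fit_constrained_glasso(s, 0.0, np.eye(2, dtype=bool))
        np.testing.assert_allclose(fit.theta, np.diag([0.5, 0.25]), atol=1e-10)

    def test_all_shrunk_closed_form(self, rng):
        s = _random_spd(rng, 4)
        rho = float(np.abs(s - np.diag(np.diag(s))).max()) + 0.1
        fit = fit_constrained_glasso(s, rho, np.ones((4, 4), bool))
        np.testing.assert_allclose(np.diag(fit.theta), 1.0 / (np.diag(s) + rho), atol=1e-10)
        off = fit.theta - np.diag(np.diag(fit.theta))
        assert np.abs(off).max() == 0.0

    def test_objective_matches_generic_solver_3x3(self, rng):
        for trial in range(3):
            s = _random_spd(rng, 3)
            mask = np.ones((3, 3), bool)
            mask[0, 2] = mask[2, 0] = False
            rho = [0.0, 0.05, 0.2][trial]
            fit = fit_constrained_glasso(s, rho, mask, tol=1e-10)

            def neg(x):
                t = np.array([[x[0], x[1], 0.0], [x[1], x[2], x[3]], [0.0, x[3], x[4]]])
                return -glasso_objective(t, s, rho)

            x0 = [fit.theta[0, 0], fit.theta[0, 1], fit.theta[1, 1], fit.theta[1, 2],
                  fit.theta[2, 2]]
            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000})
            ours = glasso_objective(fit.theta, s, rho)
            assert ours == pytest.approx(-res.fun, abs=1e-6)

    def test_forbidden_entries_exactly_zero(self, rng):
        for _ in range(5):
            p = 6
            s = _random_spd(rng, p)
            mask = rng.random((p, p)) < 0.5
            mask = mask | mask.T
            np.fill_diagonal(mask, True)
            fit = fit_constrained_glasso(s, 0.05, mask)
            assert np.abs(fit.theta[~mask]).max() == 0.0

    def test_theta_positive_definite_and_symmetric(self, rng):
        s = _random_spd(rng, 6)
        mask = np.ones((6, 6), bool)
        mask[0, 1] = mask[1, 0] = False
        fit = fit_constrained_glasso(s, 0.1, mask)
        np.testing.assert_allclose(fit.theta, fit.theta.T)
        assert np.linalg.eigvalsh(fit.theta).min() > 0

    def test_invalid_inputs(self, rng):
        s = _random_spd(rng, 3)
        with pytest.raises(ValueError):
            fit_constrained_glasso(s, -0.1, np.ones((3, 3), bool))
        bad_mask = np.ones((3, 3), bool)
        bad_mask[0, 1] = False  # asymmetric
        with pytest.raises(ValueError):
            fit_constrained_glasso(s, 0.1, bad_mask)


class TestPrecisionToRegression:
    def test_bivariate_slope_equals_correlation(self):
        r = 0.6
        theta = np.linalg.inv(np.array([[1.0, r], [r, 1.0]]))
        coef = precision_to_regression(theta, 1)
        assert coef[0] == pytest.approx(r)

    def test_forbidden_edge_gives_zero_coefficient(self):
        theta = np.diag([2.0, 3.0])
        assert precision_to_regression(theta, 0)[1] == 0.0

    def test_matches_conditional_gaussian_oracle(self, rng):
        # coefficients for predicting j must equal Sigma_{j,-j} Sigma_{-j,-j}^{-1}
        sigma = _random_spd(rng, 3)
        theta = np.linalg.inv(sigma)
        for j in range(3):
            others = [i for i in range(3) if i != j]
            oracle = np.linalg.solve(sigma[np.ix_(others, others)], sigma[others, j])
            got = precision_to_regression(theta, j)[others]
            np.testing.assert_allclose(got, oracle, atol=1e-10)


class TestZeroMask:
    def test_empty_annotations_only_diagonal(self):
        mask = build_zero_mask(["m1"], ["g1", "g2"], TargetDB({}, 2), nx.Graph())
        assert mask.n_free_offdiag == 0
        np.testing.assert_array_equal(mask.matrix, np.eye(3, dtype=bool))

    def test_single_target_single_edge(self):
        tdb = TargetDB({"m1": {"g1"}}, 2)
        mask = build_zero_mask(["m1"], ["g1", "g2"], tdb, nx.Graph())
        assert mask.n_free_offdiag == 1
        assert mask.matrix[0, 1] and mask.matrix[1, 0]

    def test_counts_match_annotations(self, rng):
        genes = [f"g{i}" for i in range(10)]
        mirnas = ["m1", "m2"]
        tdb = TargetDB({"m1": {"g0", "g3"}, "m2": {"g5"}}, 10)
        ppi = nx.Graph([("g0", "g1"), ("g2", "g3"), ("g4", "g5")])
        mask = build_zero_mask(mirnas, genes, tdb, ppi)
        assert mask.n_free_offdiag == 3 + 3
        # miRNA-miRNA always forbidden
        assert not mask.matrix[0, 1]

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError):
            build_zero_mask(["x"], ["x", "g"], TargetDB({}, 1), nx.Graph())


class TestCvPredict:
    def test_perfectly_predictable_mirna(self, rng):
        n = 20
        g = rng.normal(size=n)
        data = pd.DataFrame({"m": g, "g1": g, "g2": rng.normal(size=n)})
        mask = np.ones((3, 3), bool)
        mse, r2 = cv_predict_mirna(data, mask, 1e-4, "m")
        assert mse < 0.01
        assert r2 > 0.99

    def test_independent_mirna_unpredictable(self, rng):
        n = 40
        data = pd.DataFrame(rng.normal(size=(n, 4)), columns=["m", "g1", "g2", "g3"])
        mask = np.ones((4, 4), bool)
        mse, r2 = cv_predict_mirna(data, mask, 0.05, "m")
        assert r2 < 0.3
        assert mse == pytest.approx(np.var(data["m"], ddof=0), rel=0.5)

    def test_no_permitted_neighbours_mean_predictor(self, rng):
        n = 12
        data = pd.DataFrame(rng.normal(size=(n, 2)), columns=["m", "g1"])
        mask = np.eye(2, dtype=bool)
        mse, r2 = cv_predict_mirna(data, mask, 0.03, "m")
        x = data["m"].to_numpy()
        loo_preds = np.array([np.delete(x, i).mean() for i in range(n)])
        assert mse == pytest.approx(float(np.mean((loo_preds - x) ** 2)))
        assert r2 == 0.0

    def test_needs_five_samples(self, rng):
        data = pd.DataFrame(rng.normal(size=(4, 2)), columns=["m", "g"])
        with pytest.raises(ValueError):
            cv_predict_mirna(data, np.ones((2, 2), bool), 0.03, "m")


class TestSelectRho:
    def test_single_point_grid(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 2)), columns=["m", "g"])
        assert select_rho(data, np.ones((2, 2), bool), [0.07], mirna_cols=["m"]) == 0.07

    def test_pure_noise_prefers_largest_rho(self):
        r = np.random.default_rng(3)
        data = pd.DataFrame(r.normal(size=(25, 4)), columns=["m", "g1", "g2", "g3"])
        rho = select_rho(data, np.ones((4, 4), bool), [0.0, 0.5, 2.0], mirna_cols=["m"])
        assert rho == 2.0

    def test_planted_structure_prefers_small_rho(self):
        r = np.random.default_rng(4)
        g = r.normal(size=30)
        data = pd.DataFrame({"m": g + r.normal(0, 0.05, 30), "g1": g,
                             "g2": r.normal(size=30)})
        grid = [0.01, 2.0]
        rho = select_rho(data, np.ones((3, 3), bool), grid, mirna_cols=["m"])
        assert rho == 0.01

    def test_empty_grid_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 2)), columns=["m", "g"])
        with pytest.raises(ValueError):
            select_rho(data, np.ones((2, 2), bool), [], mirna_cols=["m"])


class TestPermutationValidate:
    @staticmethod
    def _full_builder(genes):
        p = len(genes) + 1
        mask = np.ones((p, p), bool)
        return mask

    def test_perfect_candidates_beat_all_repetitions(self, rng):
        n = 15
        signal = rng.normal(size=n)
        gene_cols = {f"g{i}": rng.normal(size=n) for i in range(30)}
        gene_cols["gsig"] = signal
        gene_data = pd.DataFrame(gene_cols)
        mir = pd.Series(signal, name="m")
        res = permutation_validate(gene_data, mir, ["gsig"], self._full_builder,
                                   rho=1e-3, n_rep=30, seed=0)
        assert res["p_mse"] == 0.0
        assert res["p_r2"] == 0.0

    def test_zero_repetitions_rejected(self, rng):
        gene_data = pd.DataFrame({"g1": rng.normal(size=10), "g2": rng.normal(size=10)})
        mir = pd.Series(rng.normal(size=10), name="m")
        with pytest.raises(ValueError):
            permutation_validate(gene_data, mir, ["g1"], self._full_builder,
                                 rho=0.03, n_rep=0)

    def test_pool_must_exceed_candidates(self, rng):
        gene_data = pd.DataFrame({"g1": rng.normal(size=10)})
        mir = pd.Series(rng.normal(size=10), name="m")
        with pytest.raises(ValueError):
            permutation_validate(gene_data, mir, ["g1"], self._full_builder,
                                 rho=0.03, n_rep=5)
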