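"""rho_A, disattenuation, OLS/ridge path estimation and lambda selection."""

import numpy as np
import pytest

from regplsc import (
    DesignCell,
    SingularMatrixError,
    UndefinedReliabilityError,
    build_population,
    default_lambda_grid,
    disattenuate,
    fit,
    fit_from_moments,
    generate_sample,
    ols_paths,
    rho_A,
    ridge_paths,
    select_lambda,
)
from regplsc.model_spec import coefficients_for_cell, load_coefficient_table


def rho_a_naive(w, S):
    """Independent double-loop evaluation of the reliability formula."""
    p = len(w)
    a = sum(w[k] * w[k] for k in range(p))
    num = sum(w[k] * S[k, l] * w[l] for k in range(p) for l in range(p) if k != l)
    den = sum(w[k] * w[k] * w[l] * w[l] for k in range(p) for l in range(p) if k != l)
    return a**2 * num / den


class TestRhoA:
    def test_population_block_high_reliability(self):
        S = np.full((4, 4), 0.5)
        np.fill_diagonal(S, 1.0)
        w = np.full(4, np.sqrt(0.1))
        value, valid = rho_A(w, S)
        assert value == pytest.approx(0.8, abs=1e-12)
        assert valid

    def test_perfect_indicators(self):
        value, valid = rho_A(np.full(4, 0.25), np.ones((4, 4)))
        assert value == pytest.approx(1.0, abs=1e-12)
        assert valid

    def test_out_of_range_flagged_not_clamped(self):
        S = np.full((4, 4), 1.2)  # inflated off-diagonals push rho above 1
        np.fill_diagonal(S, 1.0)
        value, valid = rho_A(np.full(4, 0.25), S)
        assert value > 1.0 and not valid

    def test_single_effective_indicator_undefined(self):
        S = np.eye(3)
        with pytest.raises(UndefinedReliabilityError):
            rho_A(np.array([1.0, 0.0, 0.0]), S)

    def test_matches_naive_oracle_on_random_blocks(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            A = rng.standard_normal((4, 4))
            S = A @ A.T
            w = rng.standard_normal(4)
            expected = rho_a_naive(w, S)
            got, _ = rho_A(w, S)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestDisattenuate:
    def test_unit_reliabilities_identity(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        cc = disattenuate(R, np.array([1.0, 1.0]))
        np.testing.assert_allclose(cc.matrix.to_numpy(), R)
        assert cc.positive_definite

    def test_recovers_population_phi(self):
        cc = disattenuate(np.array([[1.0, 0.32], [0.32, 1.0]]), np.array([0.8, 0.8]))
        assert cc.matrix.iloc[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_inflated_entry_retained_and_flagged(self):
        cc = disattenuate(np.array([[1.0, 0.75], [0.75, 1.0]]), np.array([0.6, 0.6]))
        assert cc.matrix.iloc[0, 1] == pytest.approx(1.25, abs=1e-12)
        assert not cc.positive_definite  # |r| > 1 fails the 2x2 minor

    def test_nonpositive_reliability_rejected(self):
        with pytest.raises(ValueError):
            disattenuate(np.eye(2), np.array([0.8, -0.1]))


class TestPathSolvers:
    def test_single_predictor_is_correlation(self):
        assert ols_paths([[1.0]], [0.37])[0] == pytest.approx(0.37)

    def test_two_predictor_oracle(self):
        # hand-inverted 2x2 system
        beta = ols_paths([[1.0, 0.5], [0.5, 1.0]], [0.6, 0.4])
        np.testing.assert_allclose(beta, [0.4 / 0.75, 0.1 / 0.75], atol=1e-12)

    def test_singular_matrix_error(self):
        with pytest.raises(SingularMatrixError):
            ols_paths([[1.0, 1.0], [1.0, 1.0]], [0.5, 0.5])

    def test_ridge_oracle(self):
        beta = ridge_paths([[1.0, 0.5], [0.5, 1.0]], [0.6, 0.4], 0.1)
        np.testing.assert_allclose(beta, [0.46 / 0.96, 0.14 / 0.96], atol=1e-12)

    def test_ridge_zero_equals_ols(self):
        Rx = np.array([[1.0, 0.5], [0.5, 1.0]])
        rxy = np.array([0.6, 0.4])
        np.testing.assert_array_equal(ridge_paths(Rx, rxy, 0.0), ols_paths(Rx, rxy))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ridge_paths(np.eye(2), [0.1, 0.2], -0.01)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        Rx = A @ A.T + np.eye(3)
        Rx = Rx / np.sqrt(np.outer(np.diag(Rx), np.diag(Rx)))
        rxy = rng.uniform(-0.5, 0.5, 3)
        norms = [
            np.linalg.norm(ridge_paths(Rx, rxy, lam))
            for lam in np.concatenate([[0.0], np.logspace(-3, 2, 30)])
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestSelectLambda:
    def test_singleton_zero_grid(self, sim_spec, sample_medium):
        sel = select_lambda(sample_medium, sim_spec, grid=[0.0], seed=0)
        assert all(lam == 0.0 for lam in sel.lambdas.values())

    def test_loo_when_small_sample(self, pop_high_rel):
        X = generate_sample(pop_high_rel, 30, seed=9)
        sel = select_lambda(X, pop_high_rel.spec, seed=0)
        assert sel.K == 30  # automatic leave-one-out below N=40
        assert sel.folds_used == 30

    def test_deterministic_given_seed(self, sim_spec, sample_medium):
        a = select_lambda(sample_medium, sim_spec, seed=42)
        b = select_lambda(sample_medium, sim_spec, seed=42)
        assert a.lambdas == b.lambdas
        np.testing.assert_array_equal(a.curves.to_numpy(), b.curves.to_numpy())

    def test_collinearity_increases_selected_lambda(self):
        """Stronger exogenous correlation should push CV toward heavier
        shrinkage on average (paired seeds, 40 datasets of N=60)."""
        means = {}
        for phi in (0.4, 0.8):
            pop = build_population(DesignCell(60, phi, 0.6, 0.25))
            lams = []
            for s in range(40):
                X = generate_sample(pop, 60, seed=1000 + s)
                sel = select_lambda(X, pop.spec, seed=s)
                lams.append(np.mean(list(sel.lambdas.values())))
            means[phi] = np.mean(lams)
        assert means[0.8] > means[0.4]


class TestFit:
    @pytest.mark.parametrize("phi", [0.4, 0.6, 0.8])
    @pytest.mark.parametrize("r2", [0.25, 0.50])
    @pytest.mark.parametrize("rel", [0.6, 0.8])
    def test_population_consistency_whole_table(self, phi, r2, rel):
        """Population-moment PLSc reproduces every true coefficient."""
        cell = DesignCell(30, phi, rel, r2)
        pop = build_population(cell)
        truth = coefficients_for_cell(cell)
        res = fit_from_moments(pop.Sigma, pop.spec, "plsc")
        for lab, val in res.paths.coefficients.items():
            assert val == pytest.approx(truth[lab], abs=0.005), lab

    def test_population_reliabilities_exact(self, pop_high_rel):
        res = fit_from_moments(pop_high_rel.Sigma, pop_high_rel.spec, "plsc")
        np.testing.assert_allclose(res.reliabilities.values, 0.8, atol=1e-10)
        # disattenuation inverts attenuation at the population
        np.testing.assert_allclose(
            res.consistent.matrix.to_numpy(), pop_high_rel.Phi, atol=1e-6
        )

    def test_regplsc_lambda_zero_equals_plsc(self, pop_high_rel):
        a = fit_from_moments(pop_high_rel.Sigma, pop_high_rel.spec, "plsc")
        b = fit_from_moments(pop_high_rel.Sigma, pop_high_rel.spec, "regplsc", lambdas=0.0)
        for lab in a.paths.coefficients:
            assert a.paths.coefficients[lab] == pytest.approx(
                b.paths.coefficients[lab], abs=1e-12
            )

    def test_large_sample_recovery(self, pop_high_rel, truth_high_rel):
        X = generate_sample(pop_high_rel, 100_000, seed=21)
        res = fit(X, pop_high_rel.spec, "plsc")
        for lab, val in res.paths.coefficients.items():
            assert val == pytest.approx(truth_high_rel[lab], abs=0.02), lab

    def test_regplsc_succeeds_where_plsc_fails(self):
        """On near-singular small samples the ridge route stays finite."""
        pop = build_population(DesignCell(30, 0.8, 0.6, 0.25))
        plsc_ok = regplsc_ok = 0
        n_trials = 60
        for s in range(n_trials):
            X = generate_sample(pop, 30, seed=3000 + s)
            plsc_worked = False
            try:
                fit(X, pop.spec, "plsc")
                plsc_worked = True
                plsc_ok += 1
            except Exception:
                pass
            try:
                res = fit(X, pop.spec, "regplsc", grid=[0.01, 0.1, 1.0], seed=s)
                assert all(np.isfinite(v) for v in res.paths.coefficients.values())
                regplsc_ok += 1
            except Exception:
                # the ridge route may only fail where disattenuation itself
                # is impossible (rho_A <= 0) — never where plsc succeeded
                assert not plsc_worked
        assert regplsc_ok > plsc_ok


def test_grid_shape():
    g = default_lambda_grid()
    assert g[0] == 0.0 and len(g) == 31
    assert g[1] == pytest.approx(1e-4) and g[-1] == pytest.approx(1.0)
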