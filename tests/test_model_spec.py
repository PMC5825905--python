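"""Model specification, population construction and their invariants."""

import json

import numpy as np
import pytest
from scipy.optimize import brentq

from regplsc import (
    DesignCell,
    InvalidPopulationError,
    ModelSpec,
    SpecError,
    build_population,
    equal_orthogonal_coefficient,
    implied_latent_correlations,
    implied_r2,
    loading_for_reliability,
    simulation_model_spec,
)
from regplsc.model_spec import coefficients_for_cell


def composite_reliability(lam, p):
    """Unit-weight composite reliability of p equally loading indicators."""
    return (p * lam) ** 2 / ((p * lam) ** 2 + p * (1 - lam**2))


class TestLoadingForReliability:
    @pytest.mark.parametrize(
        "rho,p,expected",
        [
            (0.8, 4, np.sqrt(0.5)),  # high-reliability design condition
            (0.6, 4, 0.5222329678670935),  # low-reliability condition
        ],
    )
    def test_design_conditions(self, rho, p, expected):
        lam = loading_for_reliability(rho, p)
        assert lam == pytest.approx(expected, abs=1e-10)
        # independent root-finding oracle on the reliability identity
        oracle = brentq(lambda x: composite_reliability(x, p) - rho, 1e-9, 1 - 1e-9)
        assert lam == pytest.approx(oracle, abs=1e-9)

    def test_perfect_indicators_limit(self):
        assert loading_for_reliability(1 - 1e-12, 4) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, rho):
        with pytest.raises(ValueError):
            loading_for_reliability(rho, 4)

    def test_single_indicator_rejected(self):
        with pytest.raises(ValueError):
            loading_for_reliability(0.8, 1)


class TestModelSpecValidation:
    def test_cycle_detection(self):
        with pytest.raises(SpecError, match="recursive"):
            ModelSpec(
                ("a", "b"),
                {"a": ("a1", "a2"), "b": ("b1", "b2")},
                (("a", "b", "p1"), ("b", "a", "p2")),
            )

    def test_single_indicator_block_rejected(self):
        with pytest.raises(SpecError, match="at least 2"):
            ModelSpec(("a", "b"), {"a": ("a1",), "b": ("b1", "b2")}, (("a", "b", "p"),))

    def test_indicator_in_two_blocks_rejected(self):
        with pytest.raises(SpecError, match="more than one block"):
            ModelSpec(
                ("a", "b"),
                {"a": ("x1", "x2"), "b": ("x2", "x3")},
                (("a", "b", "p"),),
            )

    def test_exo_correlation_on_endogenous_rejected(self):
        with pytest.raises(SpecError, match="endogenous"):
            ModelSpec(
                ("a", "b"),
                {"a": ("a1", "a2"), "b": ("b1", "b2")},
                (("a", "b", "p"),),
                {("a", "b"): 0.3},
            )

    def test_serialization_roundtrip(self, sim_spec, tmp_path):
        path = tmp_path / "spec.json"
        sim_spec.to_json(path)
        loaded = ModelSpec.from_dict(json.loads(path.read_text()))
        assert loaded == sim_spec

    def test_yaml_roundtrip(self, sim_spec, tmp_path):
        import yaml

        path = tmp_path / "spec.yaml"
        path.write_text(yaml.safe_dump(sim_spec.to_dict()))
        assert ModelSpec.from_file(path) == sim_spec

    def test_structure_views(self, sim_spec):
        assert sim_spec.exogenous == ("xi1", "xi2", "xi3")
        assert sim_spec.endogenous == ("eta1", "eta2", "eta3")
        assert sim_spec.parents("eta2") == ("xi1", "xi2", "xi3")
        assert sim_spec.path_labels == (
            "gamma11", "gamma12", "gamma21", "gamma22", "gamma23", "beta31", "beta32",
        )


class TestImpliedLatentCorrelations:
    def test_zero_coefficients_give_exogenous_block_only(self, sim_spec):
        coeffs = {lab: 0.0 for lab in sim_spec.path_labels}
        Phi = implied_latent_correlations(sim_spec, coeffs).to_numpy()
        expected = np.eye(6)
        expected[0, 1] = expected[1, 0] = 0.4
        np.testing.assert_allclose(Phi, expected, atol=1e-12)

    def test_first_equation_transmission(self, sim_spec, truth_high_rel):
        # corr(eta1, xi1) = gamma11 + phi * gamma12 by path tracing
        Phi = implied_latent_correlations(sim_spec, truth_high_rel)
        assert Phi.loc["eta1", "xi1"] == pytest.approx(
            0.318 + 0.4 * 0.279, abs=1e-12
        )
        assert Phi.loc["xi1", "xi2"] == pytest.approx(0.4)

    def test_monte_carlo_oracle(self, sim_spec, truth_high_rel):
        """Simulate the standardized structural equations directly and
        compare the empirical latent correlations with the path-traced ones."""
        rng = np.random.default_rng(7)
        n = 400_000
        c = truth_high_rel
        phi = 0.4
        xi12 = rng.multivariate_normal([0, 0], [[1, phi], [phi, 1]], size=n).T
        xi1, xi2 = xi12
        xi3 = rng.standard_normal(n)
        for_eta1 = c["gamma11"] * xi1 + c["gamma12"] * xi2
        eta1 = for_eta1 + rng.standard_normal(n) * np.sqrt(1 - np.var(for_eta1))
        for_eta2 = c["gamma21"] * xi1 + c["gamma23"] * xi3
        eta2 = for_eta2 + rng.standard_normal(n) * np.sqrt(1 - np.var(for_eta2))
        for_eta3 = c["beta31"] * eta1 + c["beta32"] * eta2
        eta3 = for_eta3 + rng.standard_normal(n) * np.sqrt(1 - np.var(for_eta3))
        emp = np.corrcoef(np.vstack([xi1, xi2, xi3, eta1, eta2, eta3]))
        Phi = implied_latent_correlations(sim_spec, c).to_numpy()
        np.testing.assert_allclose(Phi, emp, atol=0.01)

    def test_overexplained_variance_rejected(self, sim_spec):
        coeffs = dict.fromkeys(sim_spec.path_labels, 0.0)
        coeffs.update({"gamma11": 0.9, "gamma12": 0.9})  # explains > 100%
        with pytest.raises(InvalidPopulationError):
            implied_latent_correlations(sim_spec, coeffs)

    def test_implied_r2_matches_design_level(self, sim_spec, truth_high_rel):
        assert implied_r2(sim_spec, truth_high_rel, "eta1") == pytest.approx(
            0.25, abs=0.002
        )
        assert implied_r2(sim_spec, truth_high_rel, "eta2") == pytest.approx(
            0.25, abs=0.002
        )


class TestPopulationModel:
    def test_reference_cell_structure(self, pop_high_rel):
        assert pop_high_rel.Sigma.shape == (24, 24)
        np.testing.assert_array_equal(np.diag(pop_high_rel.Sigma), np.ones(24))
        assert np.linalg.eigvalsh(pop_high_rel.Sigma)[0] > 0

    def test_within_block_covariance_is_loading_squared(self, pop_high_rel):
        # same-block off-diagonals equal lambda^2 = 0.5 at reliability 0.8
        block = pop_high_rel.Sigma[:4, :4]
        off = block[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)
        np.testing.assert_allclose(np.diag(pop_high_rel.Theta), 0.5, atol=1e-12)

    @pytest.mark.parametrize("N", [30])
    @pytest.mark.parametrize("phi", [0.4, 0.6, 0.8])
    @pytest.mark.parametrize("rel", [0.6, 0.8])
    @pytest.mark.parametrize("r2", [0.25, 0.50])
    def test_all_cells_valid(self, N, phi, rel, r2):
        pop = build_population(DesignCell(N, phi, rel, r2))
        np.testing.assert_array_equal(np.diag(pop.Sigma), np.ones(24))
        assert np.linalg.eigvalsh(pop.Sigma)[0] > 0

    def test_orthogonal_pair_identity(self, table):
        # the two orthogonal-predictor coefficients satisfy 2 c^2 = R^2
        for _, row in table.iterrows():
            for lab in ("gamma21", "gamma23"):
                assert 2 * row[lab] ** 2 == pytest.approx(row["r2"], abs=0.002)
        assert equal_orthogonal_coefficient(0.25) == pytest.approx(0.35355, abs=5e-6)
        assert equal_orthogonal_coefficient(0.50) == pytest.approx(0.5)

    def test_sample_covariance_matches_sigma(self, pop_high_rel):
        from regplsc import generate_sample

        X = generate_sample(pop_high_rel, 100_000, seed=3)
        S = np.cov(X.to_numpy(), rowvar=False)
        assert np.abs(S - pop_high_rel.Sigma).max() < 0.02


def test_coefficients_include_null_path(cell_high_rel):
    co = coefficients_for_cell(cell_high_rel)
    assert co["gamma22"] == 0.0
    assert co["gamma21"] == pytest.approx(0.354)
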