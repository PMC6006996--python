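import math

import numpy as np
import pytest

from dynmet.balancing import (
    BalancingConfig,
    GaussianDistribution,
    assemble_measurements,
    assemble_priors,
    balance,
    build_quantity_system,
    derive_all_quantities,
    haldane_residuals,
    sample_parameters,
    wegscheider_residuals,
)
from dynmet.search import ParameterRecord
from dynmet.synthetic import NetworkSpec, draw_true_parameters, random_network

from conftest import make_ab, make_chain, make_triangle


class TestQuantitySystem:
    def test_keq_row_coefficients(self, ab_network):
        system = build_quantity_system(ab_network)
        RT = system.config.RT
        row = system.row("keq", reaction_id="R1")
        assert row[system.index("mu0", metabolite_id="A")] == pytest.approx(1 / RT)
        assert row[system.index("mu0", metabolite_id="B")] == pytest.approx(-1 / RT)
        assert np.count_nonzero(row) == 2

    def test_kcat_forward_row_closed_form(self, ab_network):
        system = build_quantity_system(ab_network)
        RT = system.config.RT
        row = system.row("kcat_forward", reaction_id="R1")
        # ln kcat+ = ln kV − ½ (μ°_B − μ°_A)/RT − ½ (ln kM_B − ln kM_A)
        assert row[system.index("kV", reaction_id="R1")] == 1.0
        assert row[system.index("mu0", metabolite_id="B")] == pytest.approx(-0.5 / RT)
        assert row[system.index("mu0", metabolite_id="A")] == pytest.approx(+0.5 / RT)
        assert row[system.index("kM", "R1", "B")] == pytest.approx(-0.5)
        assert row[system.index("kM", "R1", "A")] == pytest.approx(+0.5)

    def test_haldane_identity_is_algebraic(self):
        """h·ln keq = ln kcat+ − ln kcat− + h·Σ n_ij ln kM for random q."""
        net = random_network(NetworkSpec(n_metabolites=8, n_reactions=8,
                                         max_coefficient=2, seed=21))
        system = build_quantity_system(net)
        rng = np.random.default_rng(0)
        for _ in range(100):
            q = rng.normal(size=system.dim)
            for rid, rxn in net.reactions.items():
                lhs = rxn.cooperativity * (system.row("keq", reaction_id=rid) @ q)
                rhs = (system.row("kcat_forward", reaction_id=rid) @ q
                       - system.row("kcat_reverse", reaction_id=rid) @ q)
                for met, n in rxn.stoichiometry.items():
                    rhs += rxn.cooperativity * n * q[
                        system.index("kM", rid, met)]
                assert abs(lhs - rhs) < 1e-10

    def test_empty_reaction_rejected(self, ab_network):
        ab_network.reactions["R1"].stoichiometry = {}
        with pytest.raises(ValueError, match="no participants"):
            build_quantity_system(ab_network)


class TestPriors:
    def test_dimension_count(self, ab_network):
        system = build_quantity_system(ab_network)
        # 2 μ° + 2 kM + 1 kV + 1 u + 2 c
        assert system.dim == 8
        prior = assemble_priors(system)
        assert prior.dim == 8

    def test_km_median_override(self, ab_network):
        cfg = BalancingConfig()
        cfg.pseudo_priors["kM"] = (1.0, math.log(10))
        system = build_quantity_system(ab_network, cfg)
        prior = assemble_priors(system, cfg)
        for rid, mid in system.km_pairs:
            assert prior.mean[system.index("kM", rid, mid)] == 0.0

    def test_prior_covariance_diagonal(self, ab_network):
        system = build_quantity_system(ab_network)
        prior = assemble_priors(system)
        assert np.allclose(prior.cov, np.diag(np.diag(prior.cov)))
        assert np.all(np.diag(prior.cov) > 0)

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            BalancingConfig(pseudo_priors={"kM": (0.1, 0.0), "kV": (10, 1),
                                           "u": (0.01, 1), "c": (0.1, 1),
                                           "mu0": (0, 1)})


class TestMeasurements:
    def test_keq_record_uses_dependency_row(self, ab_network):
        system = build_quantity_system(ab_network)
        rec = ParameterRecord("keq", 0.5, "dimensionless", reaction_id="R1",
                              provenance=["x"])
        Q, x, v = assemble_measurements(system, [rec])
        np.testing.assert_allclose(Q[0], system.row("keq", reaction_id="R1"))
        assert x[0] == pytest.approx(math.log(0.5))

    def test_zero_records_empty_design(self, ab_network):
        system = build_quantity_system(ab_network)
        Q, x, v = assemble_measurements(system, [])
        assert Q.shape == (0, system.dim) and x.size == 0

    def test_stacking_matches_rowwise_oracle(self):
        net = random_network(NetworkSpec(n_metabolites=7, n_reactions=8,
                                         p_regulation=0.0, seed=31))
        truth = draw_true_parameters(net, seed=32)
        system = build_quantity_system(net)
        rng = np.random.default_rng(33)
        recs = [truth[i] for i in rng.choice(len(truth), size=10, replace=False)]
        Q, x, v = assemble_measurements(system, recs)
        for i, rec in enumerate(recs):
            row = system.row(rec.quantity_type, reaction_id=rec.reaction_id,
                             metabolite_id=rec.metabolite_id)
            np.testing.assert_allclose(Q[i], row)
            expected = rec.value if rec.quantity_type == "mu0" \
                else math.log(rec.value)
            assert x[i] == pytest.approx(expected)

    def test_unknown_subject_rejected(self, ab_network):
        system = build_quantity_system(ab_network)
        rec = ParameterRecord("keq", 1.0, "dimensionless", reaction_id="NOPE",
                              provenance=["x"])
        with pytest.raises(ValueError, match="NOPE"):
            assemble_measurements(system, [rec])


class TestBalance:
    def test_zero_measurements_returns_prior_exactly(self, ab_network):
        system = build_quantity_system(ab_network)
        prior = assemble_priors(system)
        post = balance(prior, assemble_measurements(system, []))
        np.testing.assert_array_equal(post.mean, prior.mean)
        np.testing.assert_array_equal(post.cov, prior.cov)

    def test_scalar_precision_weighted_average(self):
        prior = GaussianDistribution(np.array([1.0]), np.array([4.0]))
        Q = np.array([[1.0]])
        x = np.array([3.0])
        noise = np.array([2.0])
        post = balance(prior, (Q, x, noise))
        expected = (1.0 / 4.0 * 1.0 + 1.0 / 2.0 * 3.0) / (1.0 / 4.0 + 1.0 / 2.0)
        assert post.mean[0] == pytest.approx(expected, abs=1e-12)
        assert post.cov[0, 0] == pytest.approx(1.0 / (0.25 + 0.5), abs=1e-12)

    def test_matches_kalman_form_oracle(self):
        """Covariance-form (Kalman) update as an independent algebraic route."""
        net = make_triangle()
        system = build_quantity_system(net)
        prior = assemble_priors(system)
        rng = np.random.default_rng(3)
        rows = [system.row("keq", reaction_id="R_AB"),
                system.row("kcat_forward", reaction_id="R_BC"),
                system.row("kM", "R_CA", "C")]
        Q = np.vstack(rows)
        x = rng.normal(size=3)
        noise = np.array([0.5, 0.2, 0.1])
        post = balance(prior, (Q, x, noise))
        S0 = prior.cov
        K = S0 @ Q.T @ np.linalg.inv(Q @ S0 @ Q.T + np.diag(noise))
        mean = prior.mean + K @ (x - Q @ prior.mean)
        cov = (np.eye(system.dim) - K @ Q) @ S0
        np.testing.assert_allclose(post.mean, mean, atol=1e-9)
        np.testing.assert_allclose(post.cov, cov, atol=1e-9)

    def test_posterior_never_exceeds_prior_variance(self):
        net = random_network(NetworkSpec(n_metabolites=6, n_reactions=7,
                                         seed=41))
        truth = draw_true_parameters(net, seed=42)
        system = build_quantity_system(net)
        prior = assemble_priors(system)
        post = balance(prior, assemble_measurements(system, truth[:20]))
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = rng.normal(size=system.dim)
            assert d @ post.cov @ d <= d @ prior.cov @ d + 1e-9

    def test_data_dominance_at_tiny_noise(self):
        net = make_chain(3)
        truth = draw_true_parameters(net, seed=50)
        system = build_quantity_system(net)
        prior = assemble_priors(system)
        for rec in truth:
            rec.uncertainty = 1e-6
        post = balance(prior, assemble_measurements(system, truth))
        Q, x, _ = assemble_measurements(system, truth)
        np.testing.assert_allclose(Q @ post.mean, x, atol=1e-6)


class TestDerivedQuantities:
    def _balanced(self, net, records=()):
        system = build_quantity_system(net)
        prior = assemble_priors(system)
        post = balance(prior, assemble_measurements(system, list(records)))
        return system, post, derive_all_quantities(system, post)

    def test_symmetric_potentials_give_unit_keq(self, ab_network):
        _, _, balanced = self._balanced(ab_network)
        # prior μ° means are equal (both 0) → median keq = 1
        assert balanced.median("keq", reaction_id="R1") == pytest.approx(1.0)

    def test_variances_nonnegative(self, triangle_network):
        _, _, balanced = self._balanced(triangle_network)
        assert all(s >= 0 for s in balanced.stds.values())

    def test_medians_match_sampling_oracle(self, ab_network):
        system, post, balanced = self._balanced(ab_network)
        rng = np.random.default_rng(11)
        draws = rng.multivariate_normal(post.mean, post.cov, size=100_000)
        row = system.row("keq", reaction_id="R1")
        ln_keq = draws @ row
        se = ln_keq.std() / math.sqrt(len(ln_keq))
        assert balanced.log_mean("keq", reaction_id="R1") == pytest.approx(
            ln_keq.mean(), abs=3 * se)


class TestThermodynamicIdentities:
    def test_haldane_residuals_vanish_by_construction(self):
        for seed in range(5):
            net = random_network(NetworkSpec(n_metabolites=6, n_reactions=7,
                                             seed=seed))
            truth = draw_true_parameters(net, seed=seed + 100)
            system = build_quantity_system(net)
            prior = assemble_priors(system)
            post = balance(prior, assemble_measurements(system, truth[:10]))
            balanced = derive_all_quantities(system, post)
            assert np.abs(haldane_residuals(balanced, net)).max() < 1e-9

    def test_perturbed_kcat_shifts_residual_by_ln2(self, ab_network):
        system = build_quantity_system(ab_network)
        prior = assemble_priors(system)
        post = balance(prior, assemble_measurements(system, []))
        balanced = derive_all_quantities(system, post)
        balanced.means[("kcat_forward", "R1", None)] += math.log(2)
        res = haldane_residuals(balanced, ab_network)
        assert res[0] == pytest.approx(-math.log(2))

    def test_wegscheider_cycle_residual(self, triangle_network):
        system = build_quantity_system(triangle_network)
        prior = assemble_priors(system)
        post = balance(prior, assemble_measurements(system, []))
        balanced = derive_all_quantities(system, post)
        res, basis = wegscheider_residuals(balanced, triangle_network)
        assert res.size == 1
        assert abs(res[0]) < 1e-9

    def test_acyclic_chain_has_no_cycles(self):
        net = make_chain(4)
        system = build_quantity_system(net)
        prior = assemble_priors(system)
        balanced = derive_all_quantities(
            system, balance(prior, assemble_measurements(system, [])))
        res, _ = wegscheider_residuals(balanced, net)
        assert res.size == 0

    def test_perturbed_keq_breaks_cycle_by_ln10(self, triangle_network):
        system = build_quantity_system(triangle_network)
        balanced = derive_all_quantities(
            system, balance(assemble_priors(system),
                            assemble_measurements(system, [])))
        balanced.means[("keq", "R_AB", None)] += math.log(10)
        res, basis = wegscheider_residuals(balanced, triangle_network)
        gamma = basis[0, 0]  # R_AB component of the cycle basis vector
        assert res[0] == pytest.approx(gamma * math.log(10))


class TestSampling:
    def _posterior(self, net, n_records=10, seed=60):
        truth = draw_true_parameters(net, seed=seed)
        system = build_quantity_system(net)
        prior = assemble_priors(system)
        post = balance(prior, assemble_measurements(system, truth[:n_records]))
        return system, post

    def test_width_zero_reproduces_medians(self, triangle_network):
        system, post = self._posterior(triangle_network)
        balanced = derive_all_quantities(system, post)
        draw = sample_parameters(system, post, width=0.0, seed=1)
        for key, mean in balanced.means.items():
            assert draw.means[key] == pytest.approx(mean, abs=1e-12)

    def test_same_seed_identical(self, triangle_network):
        system, post = self._posterior(triangle_network)
        d1 = sample_parameters(system, post, width=1.0, seed=9)
        d2 = sample_parameters(system, post, width=1.0, seed=9)
        np.testing.assert_array_equal(d1.basic_mean, d2.basic_mean)

    def test_negative_width_rejected(self, triangle_network):
        system, post = self._posterior(triangle_network)
        with pytest.raises(ValueError):
            sample_parameters(system, post, width=-1.0, seed=0)

    def test_draws_satisfy_haldane_and_wegscheider(self, triangle_network):
        system, post = self._posterior(triangle_network)
        for seed in range(20):
            draw = sample_parameters(system, post, width=2.0, seed=seed)
            assert np.abs(haldane_residuals(draw, triangle_network)).max() < 1e-9
            res, _ = wegscheider_residuals(draw, triangle_network)
            assert np.abs(res).max() < 1e-9

    def test_sample_covariance_matches_posterior(self, ab_network):
        system, post = self._posterior(ab_network, n_records=5)
        rng = np.random.default_rng(77)
        draws = np.array([
            sample_parameters(system, post, width=1.0, rng=rng).basic_mean
            for _ in range(10_000)])
        sample_cov = np.cov(draws.T)
        err = np.linalg.norm(sample_cov - post.cov) / np.linalg.norm(post.cov)
        assert err < 0.05
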