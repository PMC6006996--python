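import math

import numpy as np
import pytest
import scipy.linalg

from dynmet.balancing import (
    assemble_measurements,
    assemble_priors,
    balance,
    build_quantity_system,
    derive_all_quantities,
)
from dynmet.kinetics import (
    KineticModel,
    Pulse,
    RateLawParameters,
    SimulationSchedule,
    assemble_ode_system,
    build_rate_law,
    equilibrium_flux_check,
    rate_laws_from_balanced,
    simulate,
)
from dynmet.network import (
    Compartment,
    Metabolite,
    Network,
    Reaction,
    Regulation,
    stoichiometric_matrix,
)
from dynmet.synthetic import NetworkSpec, draw_true_parameters, random_network

from conftest import make_ab


def _balanced(net):
    system = build_quantity_system(net)
    post = balance(assemble_priors(system),
                   assemble_measurements(system, []))
    return derive_all_quantities(system, post)


class TestRateLawClosedForms:
    def _irreversible(self, u=2.0, kcat=5.0, km=0.3):
        rxn = Reaction("R", "", {"A": -1.0, "B": 1.0}, reversible=False)
        params = RateLawParameters(kcat_f=kcat, kcat_r=0.0,
                                   kM={"A": km, "B": 1.0}, u=u)
        return rxn, params

    def test_half_saturation_value(self):
        rxn, params = self._irreversible()
        v = build_rate_law(rxn, params)
        # a = kM, b = 0: v = u·kcat⁺·1 / (2 + 1 − 1)
        assert v({"A": params.kM["A"], "B": 0.0}) == pytest.approx(
            params.u * params.kcat_f / 2.0, abs=1e-12)

    def test_saturation_limit(self):
        rxn, params = self._irreversible()
        v = build_rate_law(rxn, params)
        assert v({"A": 1e9 * params.kM["A"], "B": 0.0}) == pytest.approx(
            params.u * params.kcat_f, rel=1e-8)

    def test_activator_at_km_contributes_half(self):
        rxn = Reaction("R", "", {"A": -1.0, "B": 1.0}, reversible=False,
                       regulators=[Regulation("X", "activator", "R")])
        params = RateLawParameters(kcat_f=5.0, kcat_r=0.0,
                                   kM={"A": 0.3, "B": 1.0},
                                   kM_reg={"X": 0.7}, u=2.0)
        v = build_rate_law(rxn, params)
        # x = kM: f_reg = 1/2 and D_reg = 1
        a = params.kM["A"]
        expected = 2.0 * 0.5 * 5.0 * 1.0 / (2.0 + 1.0 - 1.0 + 1.0)
        assert v({"A": a, "B": 0.0, "X": 0.7}) == pytest.approx(expected,
                                                                abs=1e-12)

    def test_reversible_flux_vanishes_at_equilibrium(self):
        # construct parameters satisfying the Haldane identity, then pick
        # concentrations with b/a = keq: the net flux must vanish
        kM = {"A": 0.4, "B": 2.5}
        kV, mu_a, mu_b = 3.0, -5.0, -9.0
        RT = 8.314 * 300 / 1000
        keq = math.exp(-(mu_b - mu_a) / RT)
        s = 0.5 * ((mu_b - mu_a) / RT + math.log(kM["B"]) - math.log(kM["A"]))
        params = RateLawParameters(kcat_f=kV * math.exp(-s),
                                   kcat_r=kV * math.exp(+s), kM=kM, u=1.0)
        rxn = Reaction("R", "", {"A": -1.0, "B": 1.0})
        v = build_rate_law(rxn, params)
        a = 0.7
        assert abs(v({"A": a, "B": keq * a})) < 1e-12 * params.u * params.kcat_f

    def test_zero_km_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RateLawParameters(kcat_f=1.0, kcat_r=0.0, kM={"A": 0.0}, u=1.0)


class TestOdeAssembly:
    def test_closed_system_conserves_total(self, ab_network):
        balanced = _balanced(ab_network)
        model = assemble_ode_system(ab_network, balanced)
        traj = simulate(model, SimulationSchedule(t_end=50.0, n_points=51),
                        initial={"A": 1.0, "B": 0.2})
        totals = traj.concentrations.sum(axis=1)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_cross_compartment_amount_conserved(self):
        net = Network()
        net.add_compartment(Compartment("c1", 1.0))
        net.add_compartment(Compartment("c2", 2.0))
        net.add_metabolite(Metabolite("A", "", "c1", initial_concentration=1.0))
        net.add_metabolite(Metabolite("B", "", "c2", initial_concentration=0.1))
        net.add_reaction(Reaction("R", "", {"A": -1.0, "B": 1.0}))
        balanced = _balanced(net)
        model = assemble_ode_system(net, balanced)
        traj = simulate(model, SimulationSchedule(t_end=50.0, n_points=26),
                        initial={"A": 1.0, "B": 0.1})
        amount = traj.column("A") * 1.0 + traj.column("B") * 2.0
        np.testing.assert_allclose(amount, amount[0], rtol=1e-6)

    def test_rhs_matches_per_reaction_bruteforce(self):
        net = random_network(NetworkSpec(n_metabolites=9, n_reactions=10,
                                         p_regulation=0.1, seed=55))
        balanced = _balanced(net)
        model = assemble_ode_system(net, balanced)
        laws = rate_laws_from_balanced(net, balanced)
        S = stoichiometric_matrix(net)
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.uniform(0.01, 2.0, size=len(net.metabolites))
            xmap = dict(zip(net.metabolite_ids, x))
            v = np.array([build_rate_law(r, laws[r.id])(xmap)
                          for r in net.reactions.values()])
            expected = S @ v
            for i, mid in enumerate(net.metabolite_ids):
                expected[i] /= net.volume_of(mid)
                if net.metabolites[mid].is_boundary:
                    expected[i] = 0.0
            np.testing.assert_allclose(model.rhs(0.0, x), expected,
                                       rtol=1e-10, atol=1e-12)

    def test_jacobian_matches_finite_differences(self):
        net = random_network(NetworkSpec(n_metabolites=9, n_reactions=10,
                                         p_regulation=0.15, max_coefficient=2,
                                         seed=66))
        balanced = _balanced(net)
        model = assemble_ode_system(net, balanced)
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.uniform(0.05, 2.0, size=len(net.metabolites))
            J = model.jacobian(0.0, x).copy()
            eps = 1e-7
            for m in range(x.size):
                xp, xm = x.copy(), x.copy()
                xp[m] += eps
                xm[m] -= eps
                fd = (model.rhs(0.0, xp).copy() - model.rhs(0.0, xm)) / (2 * eps)
                np.testing.assert_allclose(J[:, m], fd, rtol=5e-5, atol=1e-7)

    def test_missing_parameters_named(self, ab_network):
        with pytest.raises(ValueError, match="R1"):
            KineticModel(ab_network, {})

    def test_conservation_along_left_nullspace(self):
        # seed chosen so the network carries a conserved moiety
        net = random_network(NetworkSpec(n_metabolites=8, n_reactions=8,
                                         n_exchange=2, seed=8))
        balanced = _balanced(net)
        model = assemble_ode_system(net, balanced)
        internal = net.internal_metabolite_ids()
        S = stoichiometric_matrix(net, internal)
        left_null = scipy.linalg.null_space(S.T)
        assert left_null.shape[1] >= 1
        traj = simulate(model, SimulationSchedule(t_end=20.0, n_points=21),
                        initial=balanced.concentrations())
        cols = [traj.species.index(m) for m in internal]
        proj = traj.concentrations[:, cols] @ left_null
        np.testing.assert_allclose(proj - proj[0], 0.0, atol=1e-6)


class TestSimulate:
    def test_dead_model_constant(self, ab_network):
        params = {"R1": RateLawParameters(kcat_f=0.0, kcat_r=0.0,
                                          kM={"A": 1.0, "B": 1.0}, u=1.0)}
        model = KineticModel(ab_network, params)
        traj = simulate(model, SimulationSchedule(t_end=10.0, n_points=11),
                        initial={"A": 1.0, "B": 2.0})
        np.testing.assert_array_equal(traj.concentrations[-1],
                                      traj.concentrations[0])

    def test_pulse_multiplies_concentration(self, ab_network):
        balanced = _balanced(ab_network)
        model = assemble_ode_system(ab_network, balanced)
        sched = SimulationSchedule(t_end=400.0, n_points=401,
                                   pulses=[Pulse(200.0, "A", "multiply", 10.0)])
        traj = simulate(model, sched, initial={"A": 1.0, "B": 1.0})
        rec = traj.diagnostics["pulses"][0]
        assert rec["post"] == pytest.approx(10.0 * rec["pre"], rel=1e-9)
        k = int(np.argwhere(np.isclose(traj.times, 200.0))[0, 0])
        assert traj.column("A")[k] == pytest.approx(rec["post"])

    def test_linear_chain_matches_matrix_exponential(self):
        # far below saturation the law linearises: dx/dt ≈ K x with
        # K built from u·kcat/kM; compare against expm on [0, 1] s
        net = Network()
        net.add_compartment(Compartment("c", 1.0))
        for m in "ABC":
            net.add_metabolite(Metabolite(m, "", "c"))
        net.add_reaction(Reaction("R1", "", {"A": -1.0, "B": 1.0},
                                  reversible=False))
        net.add_reaction(Reaction("R2", "", {"B": -1.0, "C": 1.0},
                                  reversible=False))
        params = {
            "R1": RateLawParameters(kcat_f=0.5, kcat_r=0.0,
                                    kM={"A": 100.0, "B": 100.0}, u=1.0),
            "R2": RateLawParameters(kcat_f=0.2, kcat_r=0.0,
                                    kM={"B": 100.0, "C": 100.0}, u=1.0),
        }
        model = KineticModel(net, params)
        x0 = {"A": 1e-4, "B": 0.0, "C": 0.0}
        traj = simulate(model, SimulationSchedule(t_end=1.0, n_points=11),
                        initial=x0, rtol=1e-10, atol=1e-14)
        # far below saturation den → 1, so the linearised rate is u·kcat/kM
        k1 = 1.0 * 0.5 / 100.0
        k2 = 1.0 * 0.2 / 100.0
        K = np.array([[-k1, 0, 0], [k1, -k2, 0], [0, k2, 0]])
        v0 = np.array([1e-4, 0.0, 0.0])
        for i, t in enumerate(traj.times):
            expected = scipy.linalg.expm(K * t) @ v0
            np.testing.assert_allclose(traj.concentrations[i], expected,
                                       rtol=2e-6, atol=1e-16)

    def test_positivity(self):
        net = random_network(NetworkSpec(n_metabolites=7, n_reactions=8,
                                         seed=91))
        balanced = _balanced(net)
        model = assemble_ode_system(net, balanced)
        traj = simulate(model, SimulationSchedule(t_end=100.0, n_points=51),
                        initial=balanced.concentrations())
        assert traj.concentrations.min() >= -1e-8


class TestEquilibriumFluxCheck:
    def test_balanced_model_has_zero_flux_at_ra_zero(self, triangle_network):
        balanced = _balanced(triangle_network)
        model = assemble_ode_system(triangle_network, balanced)
        residuals = equilibrium_flux_check(model, balanced)
        assert residuals
        assert max(residuals.values()) < 1e-10

    def test_broken_haldane_detected(self, triangle_network):
        balanced = _balanced(triangle_network)
        model = assemble_ode_system(triangle_network, balanced)
        model.params["R_AB"].kcat_f *= 2.0
        residuals = equilibrium_flux_check(model, balanced)
        assert residuals["R_AB"] > 0.1

    def test_irreversible_skipped(self):
        net = make_ab(reversible=False)
        balanced = _balanced(net)
        model = assemble_ode_system(net, balanced)
        assert equilibrium_flux_check(model, balanced) == {}
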