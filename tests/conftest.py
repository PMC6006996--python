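import math

import numpy as np
import pytest

from dynmet.network import (
    Compartment,
    Metabolite,
    Network,
    Reaction,
    Regulation,
)


def make_ab(reversible: bool = True) -> Network:
    """Minimal A ⇌ B network."""
    net = Network()
    net.add_compartment(Compartment("c", 1.0))
    net.add_metabolite(Metabolite("A", "met A", "c", initial_concentration=1.0))
    net.add_metabolite(Metabolite("B", "met B", "c", initial_concentration=0.5))
    net.add_reaction(Reaction("R1", "A to B", {"A": -1.0, "B": 1.0},
                              reversible=reversible))
    return net


def make_triangle() -> Network:
    """A ⇌ B ⇌ C ⇌ A: one stoichiometric cycle."""
    net = Network()
    net.add_compartment(Compartment("c", 1.0))
    for m in "ABC":
        net.add_metabolite(Metabolite(m, f"met {m}", "c",
                                      initial_concentration=1.0))
    net.add_reaction(Reaction("R_AB", "", {"A": -1.0, "B": 1.0}))
    net.add_reaction(Reaction("R_BC", "", {"B": -1.0, "C": 1.0}))
    net.add_reaction(Reaction("R_CA", "", {"C": -1.0, "A": 1.0}))
    return net


def make_chain(n: int = 3, reversible: bool = True) -> Network:
    """Linear chain M0 → M1 → … → M(n-1)."""
    net = Network()
    net.add_compartment(Compartment("c", 1.0))
    for i in range(n):
        net.add_metabolite(Metabolite(f"M{i}", f"met {i}", "c",
                                      initial_concentration=1.0))
    for i in range(n - 1):
        net.add_reaction(Reaction(f"R{i}", "", {f"M{i}": -1.0, f"M{i+1}": 1.0},
                                  reversible=reversible))
    return net


@pytest.fixture
def ab_network() -> Network:
    return make_ab()


@pytest.fixture
def triangle_network() -> Network:
    return make_triangle()


@pytest.fixture
def regulated_network() -> Network:
    """Five-reaction network with compartments and both regulator modes."""
    net = Network()
    net.add_compartment(Compartment("cyt", 1.0))
    net.add_compartment(Compartment("ext", 2.0))
    for i in range(5):
        net.add_metabolite(Metabolite(
            f"M{i}", f"met {i}", "cyt" if i < 4 else "ext",
            initial_concentration=0.1 * (i + 1),
            xrefs={"kegg_compound": f"C{i:05d}"} if i == 0 else {}))
    net.add_reaction(Reaction("R0", "r0", {"M0": -1.0, "M1": 1.0},
                              reversible=True,
                              xrefs={"kegg_reaction": "R00001"}))
    net.add_reaction(Reaction("R1", "r1", {"M1": -2.0, "M2": 1.0},
                              reversible=False, flux_bounds=(0.0, 50.0)))
    net.add_reaction(Reaction("R2", "r2", {"M2": -1.0, "M3": 1.0},
                              regulators=[Regulation("M0", "activator", "R2")]))
    net.add_reaction(Reaction("R3", "r3", {"M3": -1.0, "M4": 1.0},
                              regulators=[Regulation("M1", "inhibitor", "R3")]))
    net.add_reaction(Reaction("EX_M4", "export", {"M4": -1.0}))
    net.objective_reaction_id = "EX_M4"
    return net
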