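"""In-memory representation of a metabolic reaction network.

A :class:`Network` holds metabolites, reactions, compartments and regulation
edges, and is the single structural input to every downstream stage: the
parameter search, parameter balancing, rate-law assembly, flux-based
reduction and the robustness harness.

Concentrations are stored in mM, enzyme concentrations in mM, volumes in
litres (a relative scale is fine — only ratios matter for cross-compartment
rescaling), and flux bounds in mmol·s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Compartment",
    "Metabolite",
    "Regulation",
    "Reaction",
    "Network",
    "NetworkError",
    "ValidationFinding",
    "stoichiometric_matrix",
    "validate_network",
]

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"


class NetworkError(ValueError):
    """Structural problem in a network definition."""


@dataclass
class Compartment:
    id: str
    volume: float = 1.0


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment_id: str = "c"
    initial_concentration: Optional[float] = None  # mM; None = not given
    is_boundary: bool = False
    xrefs: dict[str, str] = field(default_factory=dict)


@dataclass
class Regulation:
    metabolite_id: str
    mode: str  # "activator" | "inhibitor"
    target_reaction_id: str

    def __post_init__(self) -> None:
        if self.mode not in (ACTIVATOR, INHIBITOR):
            raise NetworkError(f"regulation mode must be activator|inhibitor, got {self.mode!r}")


@dataclass
class Reaction:
    """One reaction with signed stoichiometry.

    ``stoichiometry`` maps metabolite id to the signed coefficient n_ij:
    negative entries are substrates (multiplicity α), positive entries are
    products (multiplicity β). A one-sided stoichiometry marks a
    boundary/exchange reaction whose missing side is an external pool.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = True
    enzyme_concentration: Optional[float] = None  # u, mM; None = take prior
    cooperativity: float = 1.0  # h
    regulators: list[Regulation] = field(default_factory=list)
    xrefs: dict[str, str] = field(default_factory=dict)
    flux_bounds: Optional[tuple[float, float]] = None  # mmol/s

    @property
    def substrates(self) -> list[tuple[str, float]]:
        """(metabolite_id, multiplicity α) pairs, in stoichiometry order."""
        return [(m, -n) for m, n in self.stoichiometry.items() if n < 0]

    @property
    def products(self) -> list[tuple[str, float]]:
        """(metabolite_id, multiplicity β) pairs, in stoichiometry order."""
        return [(m, n) for m, n in self.stoichiometry.items() if n > 0]

    @property
    def participants(self) -> list[str]:
        return list(self.stoichiometry)

    def default_bounds(self, cap: float = 1000.0) -> tuple[float, float]:
        if self.flux_bounds is not None:
            return self.flux_bounds
        return (0.0 if not self.reversible else -cap, cap)


@dataclass
class Network:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    objective_reaction_id: Optional[str] = None

    # -- construction helpers -------------------------------------------------
    def add_compartment(self, compartment: Compartment) -> "Network":
        self.compartments[compartment.id] = compartment
        return self

    def add_metabolite(self, metabolite: Metabolite) -> "Network":
        if metabolite.id in self.metabolites:
            raise NetworkError(f"duplicate metabolite id {metabolite.id!r}")
        if metabolite.compartment_id not in self.compartments:
            self.compartments.setdefault(
                metabolite.compartment_id, Compartment(metabolite.compartment_id)
            )
        self.metabolites[metabolite.id] = metabolite
        return self

    def add_reaction(self, reaction: Reaction) -> "Network":
        if reaction.id in self.reactions:
            raise NetworkError(f"duplicate reaction id {reaction.id!r}")
        self.reactions[reaction.id] = reaction
        return self

    # -- views ----------------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_boundary]

    def volume_of(self, metabolite_id: str) -> float:
        met = self.metabolites[metabolite_id]
        return self.compartments[met.compartment_id].volume


def stoichiometric_matrix(
    network: Network, metabolite_ids: Optional[Iterable[str]] = None
) -> np.ndarray:
    """Stoichiometric matrix S with entry (i, j) = n_ij.

    Rows follow ``metabolite_ids`` (default: network insertion order, all
    metabolites including boundary species — callers doing steady-state work
    should restrict rows to :meth:`Network.internal_metabolite_ids`), columns
    follow reaction insertion order.
    """
    mids = list(metabolite_ids) if metabolite_ids is not None else network.metabolite_ids
    row = {m: i for i, m in enumerate(mids)}
    S = np.zeros((len(mids), len(network.reactions)))
    for j, rxn in enumerate(network.reactions.values()):
        for met, n in rxn.stoichiometry.items():
            if met in row:
                S[row[met], j] = n
    return S


@dataclass
class ValidationFinding:
    code: str
    message: str


def validate_network(network: Network) -> list[ValidationFinding]:
    """Check every structural invariant; an empty report means a valid network."""
    findings: list[ValidationFinding] = []

    def bad(code: str, msg: str) -> None:
        findings.append(ValidationFinding(code, msg))

    if not network.reactions:
        bad("no-reactions", "network has no reactions")
    for comp in network.compartments.values():
        if not comp.volume > 0:
            bad("bad-volume", f"compartment {comp.id!r} has non-positive volume")
    used: set[str] = set()
    for met in network.metabolites.values():
        if met.compartment_id not in network.compartments:
            bad("dangling-compartment", f"metabolite {met.id!r} references missing "
                f"compartment {met.compartment_id!r}")
        if met.initial_concentration is not None and met.initial_concentration < 0:
            bad("negative-concentration", f"metabolite {met.id!r} has negative "
                "initial concentration")
    for rxn in network.reactions.values():
        if not rxn.stoichiometry:
            bad("empty-stoichiometry", f"reaction {rxn.id!r} has no participants")
        for met, n in rxn.stoichiometry.items():
            if met not in network.metabolites:
                bad("dangling-species", f"reaction {rxn.id!r} references missing "
                    f"metabolite {met!r}")
            if n == 0:
                bad("zero-coefficient", f"reaction {rxn.id!r} has zero coefficient "
                    f"for {met!r}")
            used.add(met)
        if not rxn.cooperativity > 0:
            bad("bad-cooperativity", f"reaction {rxn.id!r} has non-positive h")
        if rxn.enzyme_concentration is not None and not rxn.enzyme_concentration > 0:
            bad("bad-enzyme-concentration", f"reaction {rxn.id!r} has non-positive u")
        if rxn.flux_bounds is not None:
            lo, hi = rxn.flux_bounds
            if lo > hi:
                bad("inverted-bounds", f"reaction {rxn.id!r} has lower bound > upper")
            if not rxn.reversible and lo < 0:
                bad("irreversible-negative-bound", f"irreversible reaction {rxn.id!r} "
                    "has negative lower bound")
        for reg in rxn.regulators:
            if reg.metabolite_id not in network.metabolites:
                bad("dangling-regulator", f"regulator {reg.metabolite_id!r} of "
                    f"reaction {rxn.id!r} does not exist")
            if reg.target_reaction_id != rxn.id:
                bad("regulator-target-mismatch", f"regulation on {rxn.id!r} targets "
                    f"{reg.target_reaction_id!r}")
            used.add(reg.metabolite_id)
    for met_id in network.metabolites:
        if met_id not in used:
            bad("orphan-metabolite", f"metabolite {met_id!r} participates in no reaction")
    if (network.objective_reaction_id is not None
            and network.objective_reaction_id not in network.reactions):
        bad("dangling-objective", f"objective reaction "
            f"{network.objective_reaction_id!r} does not exist")
    return findings
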