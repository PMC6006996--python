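"""Flux-based model reduction: FVA pruning and linear-pathway compression.

Works purely on the constraint-based view of the network (before any
parameter work): reactions whose flux variability is smallest are removed
one at a time as long as the FBA optimum stays within a growth tolerance
of the full model, and linear chains coupled through an intermediate that
appears in exactly two reactions are lumped into single effective
reactions. Lumped reactions no longer correspond to physical reactions, so
they are flagged synthetic and the parameter search skips them.

FBA and FVA are delegated to COBRApy.
"""

from __future__ import annotations

import copy
import numpy as np
from dataclasses import dataclass, field
from typing import Optional

import cobra
from cobra.flux_analysis import flux_variability_analysis

from .network import Network, Reaction

__all__ = ["FluxRange", "ReductionSpec", "InfeasibleModelError", "to_cobra",
           "fba_optimum", "flux_variability", "prune", "compress"]

DEFAULT_BOUND = 1000.0  # mmol/s, used when the input carries no bounds
LUMPED_FLAG = "lumped"


class InfeasibleModelError(RuntimeError):
    pass


@dataclass
class FluxRange:
    reaction_id: str
    minimum: float
    maximum: float

    @property
    def variability(self) -> float:
        return self.maximum - self.minimum


@dataclass
class ReductionSpec:
    objective_reaction_id: Optional[str] = None  # default: network objective
    protected_reactions: set[str] = field(default_factory=set)
    protected_metabolites: set[str] = field(default_factory=set)
    growth_tolerance: float = 0.01
    fva_fraction: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 < self.growth_tolerance < 1.0:
            raise ValueError("growth tolerance must lie in (0, 1)")


def to_cobra(network: Network) -> cobra.Model:
    """Constraint-based view: boundary species are dropped from mass balance."""
    model = cobra.Model("dynmet")
    mets = {}
    for m in network.metabolites.values():
        if m.is_boundary:
            continue
        cm = cobra.Metabolite(m.id, compartment=m.compartment_id)
        mets[m.id] = cm
    for rxn in network.reactions.values():
        cr = cobra.Reaction(rxn.id)
        lo, hi = rxn.default_bounds(DEFAULT_BOUND)
        cr.lower_bound, cr.upper_bound = lo, hi
        model.add_reactions([cr])
        cr.add_metabolites({mets[m]: n for m, n in rxn.stoichiometry.items()
                            if m in mets})
    return model


def _objective_id(network: Network, objective: Optional[str]) -> str:
    obj = objective or network.objective_reaction_id
    if obj is None or obj not in network.reactions:
        raise ValueError(f"no valid objective reaction ({obj!r})")
    return obj


def fba_optimum(network: Network, objective: Optional[str] = None) -> float:
    """max v_obj subject to S·v = 0 (internal species) and the flux bounds."""
    obj = _objective_id(network, objective)
    model = to_cobra(network)
    model.objective = obj
    value = model.slim_optimize(error_value=float("nan"))
    if not np.isfinite(value):
        raise InfeasibleModelError(
            f"FBA {model.solver.status} for objective {obj!r}")
    return float(value)


def flux_variability(network: Network, objective: Optional[str] = None,
                     fraction: float = 0.99) -> list[FluxRange]:
    """Per-reaction flux range at ≥ fraction of the FBA optimum."""
    obj = _objective_id(network, objective)
    model = to_cobra(network)
    model.objective = obj
    if not np.isfinite(model.slim_optimize(error_value=float("nan"))):
        raise InfeasibleModelError("FVA on an infeasible model")
    df = flux_variability_analysis(model, fraction_of_optimum=fraction,
                                   processes=1)
    return [FluxRange(rid, float(row["minimum"]), float(row["maximum"]))
            for rid, row in df.iterrows()]


def _drop_orphan_metabolites(network: Network) -> list[str]:
    used: set[str] = set()
    for rxn in network.reactions.values():
        used.update(rxn.stoichiometry)
        used.update(r.metabolite_id for r in rxn.regulators)
    dropped = [m for m in list(network.metabolites) if m not in used]
    for m in dropped:
        del network.metabolites[m]
    return dropped


def prune(network: Network,
          spec: ReductionSpec) -> tuple[Network, list[dict]]:
    """Iteratively remove the unprotected reaction with least flux variability.

    A removal commits only if the reduced FBA optimum stays within the
    growth tolerance of the full model's and every previously active
    protected reaction can still carry flux; otherwise the reaction is
    marked unremovable. Ties break lexicographically by reaction id.
    Returns the reduced network and a removal log.
    """
    obj = _objective_id(network, spec.objective_reaction_id)
    full_opt = fba_optimum(network, obj)  # raises before any removal
    floor = (1.0 - spec.growth_tolerance) * full_opt
    net = copy.deepcopy(network)
    protected = set(spec.protected_reactions) | {obj}
    # protected reactions that can carry flux now must stay unblocked
    active_protected = {
        fr.reaction_id
        for fr in flux_variability(net, obj, fraction=0.0)
        if fr.reaction_id in protected
        and (abs(fr.minimum) > 1e-9 or abs(fr.maximum) > 1e-9)
    }
    unremovable: set[str] = set()
    log: list[dict] = []
    while True:
        ranges = flux_variability(net, obj, fraction=spec.fva_fraction)
        candidates = [fr for fr in ranges
                      if fr.reaction_id not in protected
                      and fr.reaction_id not in unremovable]
        if not candidates:
            break
        candidates.sort(key=lambda fr: (fr.variability, fr.reaction_id))
        victim = candidates[0]
        trial = copy.deepcopy(net)
        del trial.reactions[victim.reaction_id]
        entry = {"reaction_id": victim.reaction_id,
                 "variability": victim.variability}
        try:
            opt = fba_optimum(trial, obj)
        except InfeasibleModelError:
            opt = None
        ok = opt is not None and opt >= floor
        if ok and active_protected:
            still = {
                fr.reaction_id
                for fr in flux_variability(trial, obj, fraction=0.0)
                if (abs(fr.minimum) > 1e-9 or abs(fr.maximum) > 1e-9)
            }
            ok = active_protected <= still
        if ok:
            net = trial
            entry.update(action="removed", optimum_after=opt)
        else:
            unremovable.add(victim.reaction_id)
            entry.update(action="unremovable",
                         optimum_after=opt if opt is not None else float("nan"))
        log.append(entry)
    dropped = _drop_orphan_metabolites(net)
    for m in dropped:
        log.append({"reaction_id": "", "action": "orphan-metabolite-dropped",
                    "variability": float("nan"), "optimum_after": float("nan"),
                    "metabolite_id": m})
    return net, log


def _lump_pair(net: Network, met: str, prod_rxn: Reaction,
               cons_rxn: Reaction) -> Reaction:
    p = prod_rxn.stoichiometry[met]        # +p
    q = -cons_rxn.stoichiometry[met]       # consumed with -q
    stoich: dict[str, float] = {}
    for m, n in prod_rxn.stoichiometry.items():
        stoich[m] = stoich.get(m, 0.0) + q * n
    for m, n in cons_rxn.stoichiometry.items():
        stoich[m] = stoich.get(m, 0.0) + p * n
    stoich = {m: n for m, n in stoich.items() if abs(n) > 1e-12}
    l1, u1 = prod_rxn.default_bounds(DEFAULT_BOUND)
    l2, u2 = cons_rxn.default_bounds(DEFAULT_BOUND)
    # lumped flux w gives v1 = q·w and v2 = p·w
    lo = max(l1 / q, l2 / p)
    hi = min(u1 / q, u2 / p)
    lumped = Reaction(
        id=f"{prod_rxn.id}__{cons_rxn.id}",
        name=f"lumped {prod_rxn.id}+{cons_rxn.id}",
        stoichiometry=stoich,
        reversible=prod_rxn.reversible and cons_rxn.reversible,
        flux_bounds=(lo, hi),
        xrefs={"synthetic": LUMPED_FLAG},
    )
    for reg in list(prod_rxn.regulators) + list(cons_rxn.regulators):
        if reg.metabolite_id in stoich or reg.metabolite_id == met:
            continue
        lumped.regulators.append(
            type(reg)(reg.metabolite_id, reg.mode, lumped.id))
    return lumped


def compress(network: Network,
             spec: ReductionSpec) -> tuple[Network, list[dict]]:
    """Lump linear pathways through two-reaction intermediates.

    Every internal, unprotected metabolite occurring in exactly two
    reactions — one producing it with +p, one consuming it with −q — is
    eliminated by the flux-coupled combination q·R₁ + p·R₂ (the
    intermediate cancels). Applied iteratively, so maximal chains collapse
    to single effective reactions. Lumped reactions are flagged synthetic.
    """
    net = copy.deepcopy(network)
    obj = network.objective_reaction_id
    protected = set(spec.protected_reactions)
    if spec.objective_reaction_id:
        protected.add(spec.objective_reaction_id)
    log: list[dict] = []
    changed = True
    while changed:
        changed = False
        for met_id, met in list(net.metabolites.items()):
            if met.is_boundary or met_id in spec.protected_metabolites:
                continue
            touching = [r for r in net.reactions.values()
                        if met_id in r.stoichiometry]
            if len(touching) != 2:
                continue
            producing = [r for r in touching if r.stoichiometry[met_id] > 0]
            consuming = [r for r in touching if r.stoichiometry[met_id] < 0]
            if len(producing) != 1 or len(consuming) != 1:
                continue
            r1, r2 = producing[0], consuming[0]
            if r1.id in protected or r2.id in protected:
                continue
            lumped = _lump_pair(net, met_id, r1, r2)
            if not lumped.stoichiometry:
                continue  # a pure cycle would vanish entirely; keep it
            del net.reactions[r1.id]
            del net.reactions[r2.id]
            net.add_reaction(lumped)
            if obj in (r1.id, r2.id):
                net.objective_reaction_id = lumped.id
                obj = lumped.id
            log.append({"metabolite_id": met_id, "members": [r1.id, r2.id],
                        "lumped_id": lumped.id})
            changed = True
            break
    _drop_orphan_metabolites(net)
    return net, log
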