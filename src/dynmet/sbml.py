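"""SBML reader/writer (libsbml-backed).

Reads Level 2 and Level 3 documents into :class:`~dynmet.network.Network`,
writes Level 3 Version 1, optionally attaching common-modular-rate-law
kineticLaws. Species annotations (identifiers.org URNs/URIs and plain CV
terms) are mapped into the ``xrefs`` dictionaries used by the parameter
search; fbc-package flux bounds and objective are honoured when present.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Optional

import libsbml

from .network import (
    ACTIVATOR,
    INHIBITOR,
    Compartment,
    Metabolite,
    Network,
    NetworkError,
    Reaction,
    Regulation,
)

__all__ = ["read_sbml", "write_sbml", "SBMLParseError"]

log = logging.getLogger(__name__)

# identifiers.org collection -> internal namespace
_COLLECTION_MAP = {
    "kegg.reaction": "kegg_reaction",
    "kegg.compound": "kegg_compound",
    "rhea": "rhea",
    "biocyc": "metacyc",
    "metacyc.reaction": "metacyc",
    "metacyc.compound": "metacyc",
    "ec-code": "ec_number",
    "metanetx.reaction": "metanetx",
    "metanetx.chemical": "metanetx",
}

# SBO terms distinguishing modifier roles (inhibitor vs activator/stimulator)
_SBO_INHIBITOR = {20, 206, 207, 536, 537}
_SBO_ACTIVATOR = {21, 459, 461, 462}

_IDENTIFIERS_RE = re.compile(
    r"(?:urn:miriam:(?P<coll_urn>[^:]+):(?P<id_urn>.+)"
    r"|https?://identifiers\.org/(?P<coll_uri>[^/]+)/(?P<id_uri>.+))$"
)


class SBMLParseError(NetworkError):
    """Malformed SBML document."""


def _xrefs_from_sbase(sbase: libsbml.SBase) -> dict[str, str]:
    xrefs: dict[str, str] = {}
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for k in range(term.getNumResources()):
            uri = term.getResourceURI(k)
            m = _IDENTIFIERS_RE.match(uri)
            if not m:
                continue
            coll = (m.group("coll_urn") or m.group("coll_uri")).lower()
            ident = m.group("id_urn") or m.group("id_uri")
            ns = _COLLECTION_MAP.get(coll, coll.replace(".", "_").replace("-", "_"))
            xrefs.setdefault(ns, ident)
    return xrefs


def read_sbml(path: str) -> Network:
    """Parse an SBML L2/L3 file into a :class:`Network`.

    Species with ``boundaryCondition="true"`` become boundary metabolites;
    missing initial concentrations stay ``None`` (absent, not zero); initial
    amounts are divided by the compartment volume. Modifier species become
    regulation edges, with SBO terms deciding activator vs inhibitor
    (default: activator, with a warning).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"SBML parse failure at line {err.getLine()}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError("document contains no model")

    net = Network()
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        vol = comp.getVolume() if comp.isSetVolume() else 1.0
        net.add_compartment(Compartment(id=comp.getId(), volume=vol))
    if not net.compartments:
        net.add_compartment(Compartment("c"))

    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        conc: Optional[float] = None
        if sp.isSetInitialConcentration():
            conc = sp.getInitialConcentration()
        elif sp.isSetInitialAmount():
            comp = net.compartments.get(sp.getCompartment())
            vol = comp.volume if comp is not None else 1.0
            conc = sp.getInitialAmount() / vol
        net.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment_id=sp.getCompartment() or next(iter(net.compartments)),
                initial_concentration=conc,
                is_boundary=bool(sp.getBoundaryCondition()),
                xrefs=_xrefs_from_sbase(sp),
            )
        )

    dangling: list[str] = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            if ref.getSpecies() not in net.metabolites:
                dangling.append(f"{rxn.getId()}:{ref.getSpecies()}")
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            )
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            if ref.getSpecies() not in net.metabolites:
                dangling.append(f"{rxn.getId()}:{ref.getSpecies()}")
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            )
        reversible = bool(rxn.getReversible()) if rxn.isSetReversible() else True
        regulators: list[Regulation] = []
        for k in range(rxn.getNumModifiers()):
            mod = rxn.getModifier(k)
            if mod.getSpecies() not in net.metabolites:
                dangling.append(f"{rxn.getId()}:{mod.getSpecies()}")
                continue
            sbo = mod.getSBOTerm()
            if sbo in _SBO_INHIBITOR:
                mode = INHIBITOR
            elif sbo in _SBO_ACTIVATOR:
                mode = ACTIVATOR
            else:
                mode = ACTIVATOR
                if sbo < 0:
                    log.warning(
                        "modifier %s of %s has no SBO term; defaulting to activator",
                        mod.getSpecies(), rxn.getId(),
                    )
            regulators.append(Regulation(mod.getSpecies(), mode, rxn.getId()))
        bounds = None
        fbc = rxn.getPlugin("fbc")
        if fbc is not None:
            lo_p = model.getParameter(fbc.getLowerFluxBound() or "")
            hi_p = model.getParameter(fbc.getUpperFluxBound() or "")
            if lo_p is not None and hi_p is not None:
                bounds = (lo_p.getValue(), hi_p.getValue())
        if bounds is None and not reversible:
            bounds = (0.0, 1000.0)
        net.add_reaction(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or rxn.getId(),
                stoichiometry=stoich,
                reversible=reversible,
                regulators=regulators,
                xrefs=_xrefs_from_sbase(rxn),
                flux_bounds=bounds,
            )
        )
    if dangling:
        raise SBMLParseError(f"dangling species references: {', '.join(sorted(dangling))}")

    mplug = model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            net.objective_reaction_id = obj.getFluxObjective(0).getReaction()
    return net


def _rate_law_formula(rxn: Reaction, params) -> str:
    """Infix expression of the common modular rate law for one reaction."""
    def prod(terms: list[str]) -> str:
        return " * ".join(terms) if terms else "1"

    num_f, num_r, den_f, den_r = [], [], [], []
    for met, alpha in rxn.substrates:
        t = f"({met} / kM_{met})"
        num_f.append(f"{t}^{alpha:g}")
        den_f.append(f"(1 + {met} / kM_{met})^{alpha:g}")
    for met, beta in rxn.products:
        t = f"({met} / kM_{met})"
        num_r.append(f"{t}^{beta:g}")
        den_r.append(f"(1 + {met} / kM_{met})^{beta:g}")
    fwd = f"kcatf * {prod(num_f)}" if rxn.substrates else "0"
    rev = f"kcatr * {prod(num_r)}" if rxn.products else "0"
    f_reg, d_reg = [], []
    for reg in rxn.regulators:
        x, km = reg.metabolite_id, f"kM_{reg.metabolite_id}"
        if reg.mode == ACTIVATOR:
            f_reg.append(f"(({x} / {km}) / (1 + {x} / {km}))")
            d_reg.append(f"({km} / {x})")
        else:
            f_reg.append(f"(1 / (1 + {x} / {km}))")
            d_reg.append(f"({x} / {km})")
    den = f"{prod(den_f)} + {prod(den_r)} - 1"
    if d_reg:
        den += " + " + " + ".join(d_reg)
    u = params.u if params.u is not None else 1.0
    expr = f"{u:.12g} * ({fwd} - {rev}) / ({den})"
    if f_reg:
        expr = f"{u:.12g} * {prod(f_reg)} * ({fwd} - {rev}) / ({den})"
    return expr


def write_sbml(
    network: Network,
    path: str,
    kinetics: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a Level 3 Version 1 document.

    ``kinetics`` optionally maps reaction id to rate-law parameters (objects
    with ``kcat_f``, ``kcat_r``, ``kM`` mapping, ``u``); each such reaction
    gets a kineticLaw with local parameters kcatf, kcatr and one kM per
    participant and regulator.
    """
    use_fbc = network.objective_reaction_id is not None or any(
        r.flux_bounds is not None for r in network.reactions.values())
    if use_fbc:
        ns = libsbml.SBMLNamespaces(3, 1)
        ns.addPackageNamespace("fbc", 2)
        doc = libsbml.SBMLDocument(ns)
        doc.setPackageRequired("fbc", False)
    else:
        doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("dynmet_model")
    if use_fbc:
        mplug = model.getPlugin("fbc")
        mplug.setStrict(False)
    for comp in network.compartments.values():
        c = model.createCompartment()
        c.setId(comp.id)
        c.setSize(comp.volume)
        c.setConstant(True)
    for met in network.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment_id)
        sp.setBoundaryCondition(met.is_boundary)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.initial_concentration is not None:
            sp.setInitialConcentration(met.initial_concentration)
    for rxn in network.reactions.values():
        r = model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        if use_fbc and rxn.flux_bounds is not None:
            lo, hi = rxn.flux_bounds
            for tag, value in (("lb", lo), ("ub", hi)):
                p = model.createParameter()
                p.setId(f"{rxn.id}_{tag}")
                p.setValue(value)
                p.setConstant(True)
            rplug = r.getPlugin("fbc")
            rplug.setLowerFluxBound(f"{rxn.id}_lb")
            rplug.setUpperFluxBound(f"{rxn.id}_ub")
        for met, alpha in rxn.substrates:
            ref = r.createReactant()
            ref.setSpecies(met)
            ref.setStoichiometry(alpha)
            ref.setConstant(True)
        for met, beta in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(beta)
            ref.setConstant(True)
        for reg in rxn.regulators:
            mod = r.createModifier()
            mod.setSpecies(reg.metabolite_id)
            mod.setSBOTerm(459 if reg.mode == ACTIVATOR else 20)
        params = kinetics.get(rxn.id) if kinetics else None
        if params is not None:
            law = r.createKineticLaw()
            ast = libsbml.parseL3Formula(_rate_law_formula(rxn, params))
            if ast is None:
                raise NetworkError(f"could not build rate law for {rxn.id!r}")
            law.setMath(ast)
            for name, value in [("kcatf", params.kcat_f), ("kcatr", params.kcat_r)]:
                p = law.createLocalParameter()
                p.setId(name)
                p.setValue(float(value))
            kms = dict(params.kM)
            kms.update(getattr(params, "kM_reg", {}))
            for met in list(rxn.stoichiometry) + [
                g.metabolite_id for g in rxn.regulators
                if g.metabolite_id not in rxn.stoichiometry
            ]:
                p = law.createLocalParameter()
                p.setId(f"kM_{met}")
                p.setValue(float(kms[met]))
    if use_fbc and network.objective_reaction_id is not None:
        mplug = model.getPlugin("fbc")
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fo = objective.createFluxObjective()
        fo.setReaction(network.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")
    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path!r}")
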