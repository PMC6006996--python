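"""Random mass-balanced test networks with ground truth and fixture databases.

This module makes the whole pipeline testable offline: it generates a
random reaction network, draws a thermodynamically consistent ground-truth
parameter set for it, and writes fixture database tables (identifier
translations plus quantity lookups) with controllable coverage and noise,
so the search → balance → simulate chain can run end to end with no
external service.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .balancing import BalancingConfig, build_quantity_system
from .network import (
    ACTIVATOR,
    INHIBITOR,
    Compartment,
    Metabolite,
    Network,
    Reaction,
    Regulation,
)
from .search import ParameterRecord

__all__ = ["NetworkSpec", "random_network", "draw_true_parameters",
           "make_fixture_databases"]

#: spread of true standard chemical potentials, kJ·mol⁻¹. Typical reaction
#: standard free energies span tens of kJ/mol; this keeps true equilibrium
#: constants within a physically plausible range (the inference pseudo-prior
#: for μ° stays deliberately much wider).
MU0_TRUTH_STD = 10.0

_UNITS = {"kM": "mM", "kV": "1/s", "u": "mM", "c": "mM", "mu0": "kJ/mol",
          "kcat_forward": "1/s", "kcat_reverse": "1/s", "keq": "dimensionless"}


@dataclass
class NetworkSpec:
    n_metabolites: int = 10
    n_reactions: int = 10
    max_substrates: int = 2
    max_products: int = 2
    max_coefficient: int = 1
    p_reversible: float = 0.8
    p_regulation: float = 0.05
    n_compartments: int = 1
    n_exchange: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reactions < self.n_metabolites / 2:
            raise ValueError("need n_reactions >= n_metabolites / 2")
        for p in (self.p_reversible, self.p_regulation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_exchange < 2:
            raise ValueError("need at least 2 exchange reactions")
        cover = self.max_substrates + self.max_products
        if self.n_reactions < math.ceil(self.n_metabolites / cover):
            raise ValueError("too few reactions to cover all metabolites")


def random_network(spec: NetworkSpec) -> Network:
    """Generate a connected, simulable random metabolic network.

    Construction: metabolites are assigned to compartments round-robin; a
    spanning pass guarantees every metabolite participates in a reaction;
    the remaining reaction budget connects uniformly random disjoint
    substrate/product sets; one-sided exchange reactions open the boundary;
    a repair pass then adds reactions (beyond the budget if necessary)
    until every metabolite has both a producer and a consumer. Fully
    deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    net = Network()
    for c in range(spec.n_compartments):
        net.add_compartment(Compartment(f"c{c}", volume=1.0))
    mets = [f"M{i}" for i in range(spec.n_metabolites)]
    for i, mid in enumerate(mets):
        net.add_metabolite(Metabolite(
            id=mid, name=f"metabolite {i}",
            compartment_id=f"c{i % spec.n_compartments}"))

    def coef() -> float:
        return float(rng.integers(1, spec.max_coefficient + 1))

    counter = 0

    def add_rxn(subs: list[str], prods: list[str],
                reversible: Optional[bool] = None) -> str:
        nonlocal counter
        rid = f"R{counter}"
        counter += 1
        if reversible is None:
            reversible = bool(rng.random() < spec.p_reversible)
        stoich: dict[str, float] = {}
        for m in subs:
            stoich[m] = stoich.get(m, 0.0) - coef()
        for m in prods:
            stoich[m] = stoich.get(m, 0.0) + coef()
        net.add_reaction(Reaction(
            id=rid, name=f"reaction {rid}", stoichiometry=stoich,
            reversible=reversible,
            flux_bounds=(0.0, 1000.0) if not reversible else None))
        return rid

    # spanning pass: cover all metabolites with disjoint substrate/product sets
    order = list(rng.permutation(mets))
    while order:
        ns = int(rng.integers(1, spec.max_substrates + 1))
        np_ = int(rng.integers(1, spec.max_products + 1))
        chunk = order[: ns + np_]
        order = order[ns + np_:]
        if len(chunk) == 1:
            # connect the straggler to an already-covered metabolite
            other = str(rng.choice([m for m in mets if m != chunk[0]]))
            add_rxn([other], chunk)
        else:
            k = min(ns, len(chunk) - 1)
            add_rxn(chunk[:k], chunk[k:])

    # random connections with the remaining reaction budget
    while counter < spec.n_reactions:
        ns = int(rng.integers(1, spec.max_substrates + 1))
        np_ = int(rng.integers(1, spec.max_products + 1))
        chosen = list(rng.choice(mets, size=min(ns + np_, len(mets)),
                                 replace=False))
        if len(chosen) < 2:
            continue
        k = min(ns, len(chosen) - 1)
        add_rxn(chosen[:k], chosen[k:])

    # one-sided exchange reactions open the boundary
    exch_mets = list(rng.choice(mets, size=min(spec.n_exchange, len(mets)),
                                replace=False))
    exchange_ids = []
    for k, m in enumerate(exch_mets):
        rid = f"EX_{m}"
        if k < len(exch_mets) // 2:
            stoich = {m: 1.0}   # uptake: external pool → m
        else:
            stoich = {m: -1.0}  # export: m → external pool
        net.add_reaction(Reaction(id=rid, name=f"exchange {m}",
                                  stoichiometry=stoich, reversible=True))
        exchange_ids.append(rid)
    net.objective_reaction_id = exchange_ids[-1]

    # repair: every metabolite needs a producer and a consumer
    def producers(mid: str) -> int:
        return sum(1 for r in net.reactions.values()
                   if r.stoichiometry.get(mid, 0) > 0
                   or (r.reversible and r.stoichiometry.get(mid, 0) < 0))

    def consumers(mid: str) -> int:
        return sum(1 for r in net.reactions.values()
                   if r.stoichiometry.get(mid, 0) < 0
                   or (r.reversible and r.stoichiometry.get(mid, 0) > 0))

    for mid in mets:
        if producers(mid) == 0:
            other = str(rng.choice([m for m in mets if m != mid]))
            add_rxn([other], [mid], reversible=False)
        if consumers(mid) == 0:
            other = str(rng.choice([m for m in mets if m != mid]))
            add_rxn([mid], [other], reversible=False)

    # regulation edges
    for rid, rxn in list(net.reactions.items()):
        if rid.startswith("EX_"):
            continue
        for mid in mets:
            if mid in rxn.stoichiometry:
                continue
            if rng.random() < spec.p_regulation:
                mode = ACTIVATOR if rng.random() < 0.5 else INHIBITOR
                rxn.regulators.append(Regulation(mid, mode, rid))
    return net


def draw_true_parameters(
    network: Network,
    seed: int = 0,
    config: Optional[BalancingConfig] = None,
) -> list[ParameterRecord]:
    """Complete, thermodynamically consistent ground-truth record set.

    One value per basic quantity: μ° and c per metabolite, kM per
    (reaction, participant-or-regulator), u per reaction, and — in place of
    the unobservable geometric-mean rate kV — the forward catalytic rate
    kcat⁺ derived through the dependency rows, so the emitted set satisfies
    the Haldane and Wegscheider identities exactly. Multiplicative
    quantities are drawn from the pseudo-prior spreads; μ° from a
    physically plausible ±10 kJ·mol⁻¹ scale.
    """
    cfg = config or BalancingConfig()
    system = build_quantity_system(network, cfg)
    rng = np.random.default_rng(seed)
    q = np.zeros(system.dim)
    for k in range(system.dim):
        quantity, _, _ = system.basic_kind(k)
        median, std = cfg.pseudo_priors[quantity]
        if quantity == "mu0":
            q[k] = rng.normal(0.0, MU0_TRUTH_STD)
        else:
            q[k] = rng.normal(math.log(median), std)
    records: list[ParameterRecord] = []

    def rec(qt: str, value: float, rid=None, mid=None) -> None:
        records.append(ParameterRecord(
            quantity_type=qt, value=value, unit=_UNITS[qt],
            reaction_id=rid, metabolite_id=mid, source="truth",
            provenance=["truth"]))

    for mid in system.metabolite_ids:
        rec("mu0", float(q[system.index("mu0", metabolite_id=mid)]), mid=mid)
    for rid, mid in system.km_pairs:
        rec("kM", math.exp(q[system.index("kM", rid, mid)]), rid=rid, mid=mid)
    for rid in system.reaction_ids:
        rec("kcat_forward",
            math.exp(float(system.row("kcat_forward", reaction_id=rid) @ q)),
            rid=rid)
        rec("u", math.exp(q[system.index("u", reaction_id=rid)]), rid=rid)
    for mid in system.metabolite_ids:
        rec("c", math.exp(q[system.index("c", metabolite_id=mid)]), mid=mid)
    return records


def make_fixture_databases(
    network: Network,
    truth: list[ParameterRecord],
    out_dir: str,
    coverage: float = 1.0,
    noise_log_std: float = 0.0,
    seed: int = 0,
    n_adapters: int = 2,
    n_hops: int = 2,
) -> Path:
    """Write fixture adapter tables holding a noisy subset of the truth.

    Model identifiers are chained through ``n_hops`` synthetic namespaces
    (db0, db1, …) via translator adapters, so the path search is genuinely
    exercised; quantity records are spread round-robin over ``n_adapters``
    quantity databases under the terminal namespace. A ``planted.tsv``
    bookkeeping table lists exactly what was stored, for coverage oracles.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    if n_hops < 2:
        raise ValueError("need at least 2 translation hops")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = list(network.reactions) + list(network.metabolites)

    def syn_id(level: int, model_id: str) -> str:
        return f"X{level}_{model_id}"

    namespaces = ["model_id"] + [f"db{i}" for i in range(n_hops)]
    for hop in range(n_hops):
        adir = out / f"xlat{hop}"
        adir.mkdir(exist_ok=True)
        rows = []
        for sid in subjects:
            frm = sid if hop == 0 else syn_id(hop - 1, sid)
            rows.append({"from_namespace": namespaces[hop], "from_id": frm,
                         "to_namespace": namespaces[hop + 1],
                         "to_id": syn_id(hop, sid)})
        pd.DataFrame(rows).to_csv(adir / "translations.tsv", sep="\t",
                                  index=False)

    n_store = int(round(coverage * len(truth)))
    chosen = sorted(rng.choice(len(truth), size=n_store, replace=False))
    terminal = namespaces[-1]
    cfg = BalancingConfig()
    qrows: list[list[dict]] = [[] for _ in range(n_adapters)]
    planted = []
    for slot, idx in enumerate(chosen):
        rec = truth[idx]
        if rec.quantity_type == "mu0":
            value = rec.value + rng.normal(0.0, noise_log_std * cfg.RT)
        else:
            value = rec.value * math.exp(rng.normal(0.0, noise_log_std))
        subject = rec.reaction_id or rec.metabolite_id
        qrows[slot % n_adapters].append({
            "namespace": terminal,
            "id": syn_id(n_hops - 1, subject),
            "quantity_type": rec.quantity_type,
            "value": value,
            "unit": rec.unit,
            "compound_id": rec.metabolite_id or "",
            "ph": "", "temperature_k": "", "organism": "synthetic",
            "reference": f"fixture:{idx}",
        })
        planted.append({
            "QuantityType": rec.quantity_type,
            "ReactionID": rec.reaction_id or "",
            "CompoundID": rec.metabolite_id or "",
            "Value": value,
            "Adapter": f"kinetics{slot % n_adapters}",
        })
    for a in range(n_adapters):
        adir = out / f"kinetics{a}"
        adir.mkdir(exist_ok=True)
        pd.DataFrame(
            qrows[a],
            columns=["namespace", "id", "quantity_type", "value", "unit",
                     "compound_id", "ph", "temperature_k", "organism",
                     "reference"],
        ).to_csv(adir / "quantities.tsv", sep="\t", index=False)
    pd.DataFrame(
        planted,
        columns=["QuantityType", "ReactionID", "CompoundID", "Value", "Adapter"],
    ).to_csv(out / "planted.tsv", sep="\t", index=False)
    return out
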