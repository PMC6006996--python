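"""Exhaustive, provenance-tracked kinetic-parameter search.

Databases are *registered* as adapters that declare which identifier
translations (e.g. name → metacyc, metacyc → rhea) and which quantity
lookups (e.g. kegg_reaction → keq) they offer. For every task — one wanted
quantity for one reaction or metabolite — the search enumerates all simple
identifier-translation paths from the namespaces the model annotates to an
adapter that holds the wanted quantity, then executes every path to
exhaustion, saving full provenance and literature references with each
found value.

Only offline fixture adapters (TSV-table backed) ship here; the adapter
interface is a synchronous query-by-identifier so live database backends
can be added without touching the search itself.

Fixture directory layout (one subdirectory per adapter)::

    <dir>/<adapter>/translations.tsv   from_namespace  from_id  to_namespace  to_id
    <dir>/<adapter>/quantities.tsv     namespace  id  quantity_type  value  unit
                                       compound_id  ph  temperature_k  organism  reference

``compound_id`` qualifies kM entries with the compound they refer to; it is
empty for reaction-level quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .network import Network

__all__ = [
    "QUANTITY_TYPES",
    "DEFAULT_WANTED",
    "EXPECTED_UNITS",
    "AdapterDescriptor",
    "Adapter",
    "FixtureAdapter",
    "AdapterRegistry",
    "Task",
    "PathStep",
    "QuantityStep",
    "DataPath",
    "ParameterRecord",
    "enumerate_tasks",
    "find_paths",
    "execute_search",
    "write_balancing_table",
    "read_balancing_table",
]

log = logging.getLogger(__name__)

QUANTITY_TYPES = ("kM", "kcat_forward", "kcat_reverse", "keq", "c", "u",
                  "vmax_forward", "vmax_reverse", "mu0", "kV")
DEFAULT_WANTED = ("kM", "kcat_forward", "keq")
EXPECTED_UNITS = {
    "kM": {"mM"},
    "kcat_forward": {"1/s", "s^-1"},
    "kcat_reverse": {"1/s", "s^-1"},
    "kV": {"1/s", "s^-1"},
    "keq": {"dimensionless", ""},
    "c": {"mM"},
    "u": {"mM"},
    "vmax_forward": {"mmol/s", "mM/s"},
    "vmax_reverse": {"mmol/s", "mM/s"},
    "mu0": {"kJ/mol"},
}
#: quantities that live on metabolites rather than reactions
_COMPOUND_QUANTITIES = {"c", "mu0"}


@dataclass(frozen=True)
class AdapterDescriptor:
    name: str
    translations: frozenset  # of (from_namespace, to_namespace)
    quantities: frozenset    # of (namespace, quantity_type)


@dataclass
class QuantityHit:
    value: float
    unit: str = ""
    compound_id: str = ""
    ph: Optional[float] = None
    temperature_k: Optional[float] = None
    organism: str = ""
    reference: str = ""
    log_std: Optional[float] = None


class Adapter:
    """Database adapter: identifier translation plus quantity lookup."""

    descriptor: AdapterDescriptor

    def translate(self, from_namespace: str, identifier: str,
                  to_namespace: str) -> list[str]:
        raise NotImplementedError

    def query(self, namespace: str, identifier: str,
              quantity_type: str) -> list[QuantityHit]:
        raise NotImplementedError


class MappingAdapter(Adapter):
    """In-memory adapter built from plain dictionaries (handy in tests).

    ``translations`` maps (from_ns, from_id, to_ns) → list of to_ids;
    ``quantities`` maps (ns, id, quantity_type) → list of QuantityHit/float.
    """

    def __init__(self, name: str,
                 translations: Optional[dict] = None,
                 quantities: Optional[dict] = None):
        translations = translations or {}
        quantities = quantities or {}
        self._translations = {k: list(v) if isinstance(v, (list, tuple)) else [v]
                              for k, v in translations.items()}
        self._quantities = {}
        for k, hits in quantities.items():
            hits = hits if isinstance(hits, (list, tuple)) else [hits]
            self._quantities[k] = [
                h if isinstance(h, QuantityHit) else QuantityHit(value=float(h))
                for h in hits
            ]
        self.descriptor = AdapterDescriptor(
            name=name,
            translations=frozenset((f, t) for f, _, t in self._translations),
            quantities=frozenset((ns, q) for ns, _, q in self._quantities),
        )

    def translate(self, from_namespace, identifier, to_namespace):
        return list(self._translations.get(
            (from_namespace, identifier, to_namespace), []))

    def query(self, namespace, identifier, quantity_type):
        return list(self._quantities.get(
            (namespace, identifier, quantity_type), []))


class FixtureAdapter(MappingAdapter):
    """Adapter reading the TSV fixture layout from ``directory/name``."""

    def __init__(self, name: str, directory: str):
        base = Path(directory) / name
        translations: dict = {}
        tfile = base / "translations.tsv"
        if tfile.exists():
            df = pd.read_csv(tfile, sep="\t", dtype=str).fillna("")
            for row in df.itertuples(index=False):
                translations.setdefault(
                    (row.from_namespace, row.from_id, row.to_namespace), []
                ).append(row.to_id)
        quantities: dict = {}
        qfile = base / "quantities.tsv"
        if qfile.exists():
            df = pd.read_csv(qfile, sep="\t", dtype=str).fillna("")
            for row in df.itertuples(index=False):
                hit = QuantityHit(
                    value=float(row.value),
                    unit=row.unit,
                    compound_id=getattr(row, "compound_id", ""),
                    ph=float(row.ph) if row.ph else None,
                    temperature_k=float(row.temperature_k)
                    if row.temperature_k else None,
                    organism=getattr(row, "organism", ""),
                    reference=getattr(row, "reference", ""),
                )
                quantities.setdefault(
                    (row.namespace, row.id, row.quantity_type), []).append(hit)
        super().__init__(name, translations, quantities)


class AdapterRegistry:
    """Registered adapters plus the induced identifier-translation graph."""

    def __init__(self) -> None:
        self.adapters: dict[str, Adapter] = {}
        self.graph = nx.MultiDiGraph()
        self._offers: dict[tuple[str, str], list[str]] = {}

    def register(self, adapter: Adapter) -> "AdapterRegistry":
        name = adapter.descriptor.name
        if name in self.adapters:
            raise ValueError(f"adapter {name!r} already registered")
        if not adapter.descriptor.translations and not adapter.descriptor.quantities:
            raise ValueError(f"adapter {name!r} declares no capabilities")
        self.adapters[name] = adapter
        for f, t in sorted(adapter.descriptor.translations):
            self.graph.add_edge(f, t, key=name)
        for ns, q in sorted(adapter.descriptor.quantities):
            self._offers.setdefault((ns, q), []).append(name)
            self.graph.add_node(ns)
        for key in self._offers:
            self._offers[key].sort()
        return self

    def offers(self, namespace: str, quantity_type: str) -> list[str]:
        return list(self._offers.get((namespace, quantity_type), []))

    def quantity_namespaces(self, quantity_type: str) -> list[str]:
        return sorted({ns for (ns, q) in self._offers if q == quantity_type})

    @classmethod
    def from_fixture_directory(cls, directory: str) -> "AdapterRegistry":
        reg = cls()
        for sub in sorted(Path(directory).iterdir()):
            if sub.is_dir():
                reg.register(FixtureAdapter(sub.name, directory))
        return reg


@dataclass(frozen=True)
class Task:
    subject: str               # reaction or metabolite id
    subject_kind: str          # "reaction" | "compound"
    wanted: str                # quantity type
    metabolite_id: Optional[str] = None  # participant, for kM tasks

    def __post_init__(self) -> None:
        if self.wanted not in QUANTITY_TYPES:
            raise ValueError(f"unknown quantity type {self.wanted!r}")
        if self.subject_kind not in ("reaction", "compound"):
            raise ValueError(f"bad subject kind {self.subject_kind!r}")


@dataclass(frozen=True)
class PathStep:
    adapter: str
    from_namespace: str
    to_namespace: str


@dataclass(frozen=True)
class QuantityStep:
    adapter: str
    namespace: str
    quantity_type: str


@dataclass(frozen=True)
class DataPath:
    steps: tuple[PathStep, ...]
    lookup: QuantityStep

    @property
    def length(self) -> int:
        return len(self.steps) + 1

    @property
    def start_namespace(self) -> str:
        return self.steps[0].from_namespace if self.steps else self.lookup.namespace

    def adapter_names(self) -> tuple[str, ...]:
        return tuple(s.adapter for s in self.steps) + (self.lookup.adapter,)


@dataclass
class ParameterRecord:
    quantity_type: str
    value: float
    unit: str
    reaction_id: Optional[str] = None
    metabolite_id: Optional[str] = None
    uncertainty: Optional[float] = None   # log-scale std (mult. quantities)
    source: str = ""
    provenance: list[str] = field(default_factory=list)
    reference: str = ""
    ph: Optional[float] = None
    temperature_k: Optional[float] = None
    organism: str = ""

    def __post_init__(self) -> None:
        if self.quantity_type not in QUANTITY_TYPES:
            raise ValueError(f"unknown quantity type {self.quantity_type!r}")
        if self.quantity_type != "mu0" and not self.value > 0:
            raise ValueError(
                f"{self.quantity_type} must be positive, got {self.value}")
        if self.quantity_type == "kM" and self.metabolite_id is None:
            raise ValueError("kM record needs a metabolite_id")


def enumerate_tasks(network: Network,
                    wanted_types: Iterable[str] = DEFAULT_WANTED) -> list[Task]:
    """One task per (reaction, quantity) and (reaction-participant, kM).

    Compound quantities (c) yield one task per metabolite. Order is
    deterministic: network insertion order, kM tasks following their
    reaction's stoichiometry order.
    """
    wanted = [q for q in QUANTITY_TYPES if q in set(wanted_types)]
    tasks: list[Task] = []
    for rid, rxn in network.reactions.items():
        if rxn.xrefs.get("synthetic") == "lumped":
            continue  # lumped reactions are not physical; nothing to search
        for q in wanted:
            if q in _COMPOUND_QUANTITIES:
                continue
            if q == "kM":
                for met in rxn.stoichiometry:
                    tasks.append(Task(rid, "reaction", "kM", metabolite_id=met))
            else:
                tasks.append(Task(rid, "reaction", q))
    for q in wanted:
        if q in _COMPOUND_QUANTITIES:
            for mid in network.metabolites:
                tasks.append(Task(mid, "compound", q))
    return tasks


def _start_identifiers(network: Network, task: Task) -> dict[str, str]:
    """Namespace → identifier pairs the subject is known under."""
    if task.subject_kind == "reaction":
        obj = network.reactions[task.subject]
    else:
        obj = network.metabolites[task.subject]
    ids = {"model_id": obj.id}
    if obj.name:
        ids["name"] = obj.name
    ids.update(obj.xrefs)
    return ids


def find_paths(task: Task, registry: AdapterRegistry, network: Network,
               max_depth: int = 6) -> list[DataPath]:
    """All simple identifier paths from the subject to the wanted quantity.

    A path is a chain of translation steps ending in a quantity lookup; its
    length (steps + lookup) is capped at ``max_depth`` and no namespace is
    visited twice. Returned shortest first, ties broken lexicographically
    by the adapter names along the path.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    starts = _start_identifiers(network, task)
    goals = registry.quantity_namespaces(task.wanted)
    paths: list[DataPath] = []
    for start_ns in sorted(starts):
        if start_ns in goals:
            for adapter in registry.offers(start_ns, task.wanted):
                paths.append(DataPath((), QuantityStep(adapter, start_ns,
                                                       task.wanted)))
        if start_ns not in registry.graph:
            continue
        for goal in goals:
            if goal == start_ns or goal not in registry.graph:
                continue
            for edge_path in nx.all_simple_edge_paths(
                    registry.graph, start_ns, goal, cutoff=max_depth - 1):
                steps = tuple(PathStep(key, f, t) for f, t, key in edge_path)
                for adapter in registry.offers(goal, task.wanted):
                    paths.append(DataPath(steps,
                                          QuantityStep(adapter, goal, task.wanted)))
    paths.sort(key=lambda p: (p.length, p.adapter_names(),
                              tuple(s.from_namespace for s in p.steps)))
    return paths


def _matches_subject(task: Task, hit: QuantityHit) -> bool:
    if task.wanted != "kM":
        return True
    if not hit.compound_id:
        return False
    return hit.compound_id == task.metabolite_id


def execute_search(
    network: Network,
    registry: AdapterRegistry,
    wanted_types: Iterable[str] = DEFAULT_WANTED,
    max_depth: int = 6,
    condition_filter: Optional[Callable[[QuantityHit], bool]] = None,
) -> list[ParameterRecord]:
    """Run every task's paths to exhaustion and collect parameter records.

    Values found more than once for the same rate from the same source (via
    different paths) collapse to a single record; genuinely distinct values
    are all kept — the balancer consumes every measurement. Adapter
    failures are logged and the search continues.
    """
    if not registry.adapters:
        raise ValueError("registry has no adapters")
    records: list[ParameterRecord] = []
    seen: set = set()
    for task in enumerate_tasks(network, wanted_types):
        starts = _start_identifiers(network, task)
        for path in find_paths(task, registry, network, max_depth):
            start_id = starts.get(path.start_namespace)
            if start_id is None:
                continue
            frontier: list[tuple[str, list[str]]] = [
                (start_id, [f"{path.start_namespace}:{start_id}"])]
            for step in path.steps:
                adapter = registry.adapters[step.adapter]
                nxt: list[tuple[str, list[str]]] = []
                for ident, prov in frontier:
                    try:
                        targets = adapter.translate(
                            step.from_namespace, ident, step.to_namespace)
                    except Exception as exc:  # noqa: BLE001 - adapter fault
                        log.warning("adapter %s failed translating %s: %s",
                                    step.adapter, ident, exc)
                        targets = []
                    for t in targets:
                        nxt.append((t, prov + [
                            f"{step.adapter}:{step.to_namespace}:{t}"]))
                frontier = nxt
                if not frontier:
                    break
            adapter = registry.adapters[path.lookup.adapter]
            for ident, prov in frontier:
                try:
                    hits = adapter.query(path.lookup.namespace, ident,
                                         task.wanted)
                except Exception as exc:  # noqa: BLE001
                    log.warning("adapter %s failed querying %s: %s",
                                path.lookup.adapter, ident, exc)
                    continue
                for hit in hits:
                    if not _matches_subject(task, hit):
                        continue
                    if condition_filter is not None and not condition_filter(hit):
                        continue
                    rid = task.subject if task.subject_kind == "reaction" else None
                    mid = (task.metabolite_id if task.wanted == "kM"
                           else task.subject if task.subject_kind == "compound"
                           else None)
                    key = (task.wanted, rid, mid, path.lookup.adapter, hit.value)
                    if key in seen:
                        continue
                    seen.add(key)
                    records.append(ParameterRecord(
                        quantity_type=task.wanted,
                        value=hit.value,
                        unit=hit.unit or next(iter(EXPECTED_UNITS[task.wanted])),
                        reaction_id=rid,
                        metabolite_id=mid,
                        uncertainty=hit.log_std,
                        source=path.lookup.adapter,
                        provenance=prov + [
                            f"{path.lookup.adapter}:{task.wanted}:{hit.value:g}"],
                        reference=hit.reference,
                        ph=hit.ph,
                        temperature_k=hit.temperature_k,
                        organism=hit.organism,
                    ))
    return records


_COLUMNS = ["QuantityType", "ReactionID", "CompoundID", "Value", "Unit",
            "LogStd", "Source", "Provenance", "Reference", "pH", "TemperatureK"]


def write_balancing_table(records: Sequence[ParameterRecord], path: str) -> None:
    """TSV table of found values, the input to the balancing stage."""
    problems = []
    rows = []
    for i, rec in enumerate(records):
        allowed = EXPECTED_UNITS.get(rec.quantity_type, set())
        if allowed and rec.unit not in allowed:
            problems.append(f"row {i}: {rec.quantity_type} in {rec.unit!r}")
        rows.append({
            "QuantityType": rec.quantity_type,
            "ReactionID": rec.reaction_id or "",
            "CompoundID": rec.metabolite_id or "",
            "Value": rec.value,
            "Unit": rec.unit,
            "LogStd": "" if rec.uncertainty is None else rec.uncertainty,
            "Source": rec.source,
            "Provenance": " > ".join(rec.provenance),
            "Reference": rec.reference,
            "pH": "" if rec.ph is None else rec.ph,
            "TemperatureK": "" if rec.temperature_k is None else rec.temperature_k,
        })
    if problems:
        raise ValueError("unit inconsistencies: " + "; ".join(problems))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


_SBTAB_ALIASES = {
    "!QuantityType": "QuantityType", "!Reaction": "ReactionID",
    "!Compound": "CompoundID", "!Value": "Value", "!Unit": "Unit",
    "!Mean": "Value", "!Std": "LogStd",
}


def read_balancing_table(path: str) -> list[ParameterRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df = df.rename(columns=_SBTAB_ALIASES)
    records = []
    for row in df.itertuples(index=False):
        records.append(ParameterRecord(
            quantity_type=row.QuantityType,
            value=float(row.Value),
            unit=row.Unit,
            reaction_id=row.ReactionID or None,
            metabolite_id=row.CompoundID or None,
            uncertainty=float(row.LogStd) if row.LogStd else None,
            source=getattr(row, "Source", ""),
            provenance=[p for p in getattr(row, "Provenance", "").split(" > ") if p],
            reference=getattr(row, "Reference", ""),
            ph=float(row.pH) if getattr(row, "pH", "") else None,
            temperature_k=float(row.TemperatureK)
            if getattr(row, "TemperatureK", "") else None,
        ))
    return records
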