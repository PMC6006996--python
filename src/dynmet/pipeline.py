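"""End-to-end pipeline orchestration with artifact persistence.

Stage order: (optional flux-based reduction) → parse → parameter search →
balancing → model build → simulation → (optional robustness sweep). Every
run writes its artifacts plus a manifest carrying content hashes, the
master seed and the configuration hash, so a rerun with an unchanged
configuration reproduces byte-identical deterministic artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import balancing as bal
from . import kinetics as kin
from . import reduction as red
from . import robustness as rob
from . import search as srch
from .network import Network
from .sbml import read_sbml, write_sbml

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

REDUCTION_MODES = ("none", "prune", "compress")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    model_path: str
    database_dir: Optional[str] = None
    out_dir: str = "dynmet_out"
    seed: int = 0
    wanted: tuple[str, ...] = srch.DEFAULT_WANTED
    max_depth: int = 6
    temperature: float = 300.0
    reduction_mode: str = "none"
    protected_reactions: tuple[str, ...] = ()
    protected_metabolites: tuple[str, ...] = ()
    growth_tolerance: float = 0.01
    t_end: float = 400.0
    n_points: int = 401
    pulse: Optional[str] = None  # "<species>:<time>:<factor>"
    robustness_fractions: tuple[float, ...] = ()
    robustness_widths: tuple[float, ...] = (1.0,)
    robustness_repetitions: int = 5

    def __post_init__(self) -> None:
        if self.reduction_mode not in REDUCTION_MODES:
            raise ValueError(f"reduction mode must be one of {REDUCTION_MODES}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("wanted", "protected_reactions", "protected_metabolites",
                    "robustness_fractions", "robustness_widths"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def schedule(self, network: Network) -> kin.SimulationSchedule:
        pulses = []
        if self.pulse:
            species, t, factor = self.pulse.split(":")
            pulses = [kin.Pulse(float(t), species, "multiply", float(factor))]
        return kin.SimulationSchedule(t_end=self.t_end, n_points=self.n_points,
                                      pulses=pulses)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "artifacts": {}, "stages": []}
    artifacts = manifest["artifacts"]

    def record(name: str, path: Path) -> None:
        artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "parse"
    try:
        network = read_sbml(config.model_path)
    except Exception as exc:
        finish_stage(f"{stage}:failed")
        raise PipelineError(stage, str(exc)) from exc
    finish_stage(stage)

    if config.reduction_mode != "none":
        stage = "reduce"
        try:
            spec = red.ReductionSpec(
                objective_reaction_id=network.objective_reaction_id,
                protected_reactions=set(config.protected_reactions),
                protected_metabolites=set(config.protected_metabolites),
                growth_tolerance=config.growth_tolerance,
            )
            network, prune_log = red.prune(network, spec)
            logs = list(prune_log)
            if config.reduction_mode == "compress":
                network, compress_log = red.compress(network, spec)
                logs += compress_log
            import pandas as pd
            pd.DataFrame(logs).to_csv(out / "reduction_log.tsv", sep="\t",
                                      index=False)
            record("reduction_log", out / "reduction_log.tsv")
        except Exception as exc:
            finish_stage(f"{stage}:failed")
            raise PipelineError(stage, str(exc)) from exc
        finish_stage(stage)

    stage = "search"
    records: list = []
    try:
        if config.database_dir:
            registry = srch.AdapterRegistry.from_fixture_directory(
                config.database_dir)
            records = srch.execute_search(network, registry,
                                          wanted_types=config.wanted,
                                          max_depth=config.max_depth)
        srch.write_balancing_table(records, out / "balancing_table.tsv")
        record("balancing_table", out / "balancing_table.tsv")
    except Exception as exc:
        finish_stage(f"{stage}:failed")
        raise PipelineError(stage, str(exc)) from exc
    finish_stage(stage)

    stage = "balance"
    try:
        cfg = bal.BalancingConfig(T=config.temperature)
        system = bal.build_quantity_system(network, cfg)
        prior = bal.assemble_priors(system, cfg)
        meas = bal.assemble_measurements(system, records)
        posterior = bal.balance(prior, meas)
        balanced = bal.derive_all_quantities(system, posterior)
        bal.write_balanced_table(balanced, out / "balanced_parameters.tsv")
        record("balanced_parameters", out / "balanced_parameters.tsv")
    except Exception as exc:
        finish_stage(f"{stage}:failed")
        raise PipelineError(stage, str(exc)) from exc
    finish_stage(stage)

    stage = "build"
    try:
        laws = kin.rate_laws_from_balanced(network, balanced)
        model = kin.KineticModel(network, laws)
        for mid, c in balanced.concentrations().items():
            network.metabolites[mid].initial_concentration = c
        write_sbml(network, out / "kinetic_model.xml", kinetics=laws)
        record("kinetic_model", out / "kinetic_model.xml")
    except Exception as exc:
        finish_stage(f"{stage}:failed")
        raise PipelineError(stage, str(exc)) from exc
    finish_stage(stage)

    stage = "simulate"
    try:
        schedule = config.schedule(network)
        if not schedule.pulses:
            internal = network.internal_metabolite_ids()
            if internal:
                schedule = kin.SimulationSchedule(
                    t_end=config.t_end, n_points=config.n_points,
                    pulses=[kin.Pulse(config.t_end / 2.0, internal[0])])
        traj = kin.simulate(model, schedule,
                            initial=balanced.concentrations())
        traj.to_frame().to_csv(out / "trajectory.csv", index=False)
        record("trajectory", out / "trajectory.csv")
    except Exception as exc:
        finish_stage(f"{stage}:failed")
        raise PipelineError(stage, str(exc)) from exc
    finish_stage(stage)

    if config.robustness_fractions:
        stage = "robustness"
        try:
            gold = rob.make_gold_standard(network, records, seed=config.seed,
                                          config=cfg, schedule=schedule)
            table = rob.sweep(gold, config.robustness_fractions,
                              config.robustness_widths,
                              repetitions=config.robustness_repetitions,
                              seed=config.seed)
            table.to_csv(out / "scores.tsv", sep="\t", index=False)
            record("scores", out / "scores.tsv")
        except Exception as exc:
            finish_stage(f"{stage}:failed")
            raise PipelineError(stage, str(exc)) from exc
        finish_stage(stage)

    finish_stage("done")
    return manifest
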