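"""Run configuration: YAML/JSON loading, strict validation, and echoing.

A run configuration is a plain document with sections ``network``,
``schedule``, ``signals`` (a list), ``integrator``, ``classification``,
``simulation``, plus top-level ``seed`` and ``outdir``.  Keys map exactly
onto the corresponding dataclass fields; unknown keys are an error, and
validation failures name the offending field.  Every command echoes the
resolved configuration (including a generated seed when none was given)
next to its outputs so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .dynamics import IntegratorSettings
from .network import (
    CouplingSchedule,
    NetworkError,
    NetworkSpec,
    SignalProtocol,
    build_network,
)
from .regimes import ClassifierThresholds

__all__ = ["RunConfig", "ConfigError", "load_config", "load_run_config"]


class ConfigError(ValueError):
    pass


_SCHEDULE_KEYS = {"kind", "g_start", "g_end", "t_start", "t_end", "points"}
_SIGNAL_KEYS = {"target_gene", "amplitude", "t_on", "t_off"}
_INTEGRATOR_KEYS = {"rtol", "atol", "method", "n_points", "max_step"}
_CLASSIFICATION_KEYS = {
    "osc_rel_amp",
    "steady_rel_amp",
    "multipotent_tol",
    "dominance_ratio",
    "hysteresis",
    "min_peaks",
    "transient_fraction",
}
_SIMULATION_KEYS = {"t_end", "ic_scale"}
_TOP_KEYS = {
    "network",
    "schedule",
    "signals",
    "integrator",
    "classification",
    "simulation",
    "seed",
    "outdir",
}


def _check_keys(section: Mapping, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


@dataclass(frozen=True)
class RunConfig:
    spec: NetworkSpec
    schedule: CouplingSchedule
    signals: tuple[SignalProtocol, ...] = ()
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    t_end: float = 600.0
    ic_scale: float = 0.01
    seed: int | None = None
    outdir: str | None = None
    raw: dict = field(default_factory=dict)

    def echo(self) -> dict:
        """The resolved configuration as a serialisable document."""
        doc = json.loads(json.dumps(self.raw, default=float))
        doc.setdefault("simulation", {})
        doc["simulation"]["t_end"] = self.t_end
        doc["simulation"]["ic_scale"] = self.ic_scale
        doc["seed"] = self.seed
        return doc


def load_config(path) -> dict:
    """Read a YAML or JSON configuration document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return dict(doc)


def parse_run_config(doc: Mapping) -> RunConfig:
    _check_keys(doc, _TOP_KEYS, "config")
    if "network" not in doc:
        raise ConfigError("config requires a 'network' section")
    try:
        spec = build_network(doc["network"])
    except NetworkError as err:
        raise ConfigError(f"network: {err}") from err

    sched_doc = dict(doc.get("schedule", {"kind": "constant", "g_start": 1.0}))
    _check_keys(sched_doc, _SCHEDULE_KEYS, "schedule")
    if sched_doc.get("points") is not None:
        sched_doc["points"] = [tuple(p) for p in sched_doc["points"]]
    try:
        schedule = CouplingSchedule(**sched_doc)
    except (NetworkError, TypeError) as err:
        raise ConfigError(f"schedule: {err}") from err

    signals = []
    for k, sig_doc in enumerate(doc.get("signals", []) or []):
        _check_keys(sig_doc, _SIGNAL_KEYS, f"signals[{k}]")
        try:
            signals.append(SignalProtocol(**sig_doc))
        except (NetworkError, TypeError) as err:
            raise ConfigError(f"signals[{k}]: {err}") from err

    integ_doc = dict(doc.get("integrator", {}))
    _check_keys(integ_doc, _INTEGRATOR_KEYS, "integrator")
    integrator = IntegratorSettings(**integ_doc)
    if integrator.rtol <= 0 or integrator.atol <= 0:
        raise ConfigError("integrator: rtol and atol must be > 0")

    cls_doc = dict(doc.get("classification", {}))
    _check_keys(cls_doc, _CLASSIFICATION_KEYS, "classification")
    thresholds = ClassifierThresholds(**cls_doc)

    sim_doc = dict(doc.get("simulation", {}))
    _check_keys(sim_doc, _SIMULATION_KEYS, "simulation")
    t_end = float(sim_doc.get("t_end", 600.0))
    if t_end <= 0:
        raise ConfigError("simulation: t_end must be > 0")

    return RunConfig(
        spec=spec,
        schedule=schedule,
        signals=tuple(signals),
        integrator=integrator,
        thresholds=thresholds,
        t_end=t_end,
        ic_scale=float(sim_doc.get("ic_scale", 0.01)),
        seed=doc.get("seed"),
        outdir=doc.get("outdir"),
        raw=dict(doc),
    )


def load_run_config(path) -> RunConfig:
    return parse_run_config(load_config(path))
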