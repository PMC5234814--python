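"""Run configuration: structured YAML in, validated RunConfig out.

A config file holds at most these top-level keys (all optional except
``experiment``):

.. code-block:: yaml

    experiment: loss          # steady | loss | sequential | competitor |
                              # scan | sample | approx
    params:                   # circuit rates; omitted fields keep defaults
      alpha_m: 1.0
      beta_c: 0.1
    competitor:               # competitor rates (competitor experiment/scan)
      alpha_2: 4.0
    schedule:
      t_event: 150.0          # loss / induction time [min]
      copy_sequence: [6, 3, 0]   # sequential experiment only
      step_times: [150, 170, 190]
    integrator:
      dt: 1.0e-4
      t_end: 300.0
      record_every: 0.01
    scan:
      parameter: beta_c
      values: [0.05, 0.1, 0.2]
    sample:
      n: 100
    seed: 1
    out: results/run          # output path prefix

Unknown keys anywhere raise an error listing them; invariant violations
name the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .params import CircuitParams, CompetitorParams

__all__ = ["RunConfig", "load_config", "config_to_yaml"]

EXPERIMENTS = ("steady", "loss", "sequential", "competitor", "scan", "sample", "approx")


@dataclass
class IntegratorSettings:
    dt: float = 1e-4
    t_end: float = 300.0
    record_every: float = 0.01

    def __post_init__(self):
        for name in ("dt", "t_end", "record_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"integrator.{name} must be positive")


@dataclass
class ScheduleSettings:
    t_event: float = 150.0
    copy_sequence: tuple = ()
    step_times: tuple = ()

    def __post_init__(self):
        self.copy_sequence = tuple(float(v) for v in self.copy_sequence)
        self.step_times = tuple(float(v) for v in self.step_times)
        if self.t_event <= 0:
            raise ValueError("schedule.t_event must be positive")
        if len(self.copy_sequence) != len(self.step_times):
            raise ValueError("schedule.copy_sequence and step_times must match in length")


@dataclass
class ScanSettings:
    parameter: str = "g"
    values: tuple = ()

    def __post_init__(self):
        self.values = tuple(float(v) for v in self.values)


@dataclass
class SampleSettings:
    n: int = 100

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("sample.n must be positive")


@dataclass
class RunConfig:
    """Fully validated description of one computational experiment."""

    experiment: str = "loss"
    params: CircuitParams = field(default_factory=CircuitParams)
    competitor: Optional[CompetitorParams] = None
    schedule: ScheduleSettings = field(default_factory=ScheduleSettings)
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    scan: ScanSettings = field(default_factory=ScanSettings)
    sample: SampleSettings = field(default_factory=SampleSettings)
    seed: int = 0
    out: str = "tasim_out"

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        if self.experiment == "competitor" and self.competitor is None:
            self.competitor = CompetitorParams()


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {where}: {exc}") from exc


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, cls in (("params", CircuitParams), ("competitor", CompetitorParams),
                     ("schedule", ScheduleSettings), ("integrator", IntegratorSettings),
                     ("scan", ScanSettings), ("sample", SampleSettings)):
        if key in raw and raw[key] is not None:
            section = raw.pop(key)
            if not isinstance(section, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(cls, section, key)
        else:
            raw.pop(key, None)
    kwargs.update(raw)
    return _build(RunConfig, kwargs, "config")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(raw)


def config_to_yaml(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through load_config)."""
    doc = {
        "experiment": cfg.experiment,
        "params": dataclasses.asdict(cfg.params),
        "schedule": dataclasses.asdict(cfg.schedule),
        "integrator": dataclasses.asdict(cfg.integrator),
        "scan": dataclasses.asdict(cfg.scan),
        "sample": dataclasses.asdict(cfg.sample),
        "seed": cfg.seed,
        "out": cfg.out,
    }
    if cfg.competitor is not None:
        doc["competitor"] = dataclasses.asdict(cfg.competitor)
    doc["schedule"]["copy_sequence"] = list(cfg.schedule.copy_sequence)
    doc["schedule"]["step_times"] = list(cfg.schedule.step_times)
    doc["scan"]["values"] = list(cfg.scan.values)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
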