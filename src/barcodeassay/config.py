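"""Run configuration: serializable parameter blocks for reproducible runs.

A run is fully determined by (inputs, config, seed): the YAML/JSON
config carries the physical layout, the render scenario, the decoder
tuning, the sampling plan and the calibration model, and every block
round-trips through ``to_dict``/``from_dict`` so a dumped config
reproduces its outputs bit-for-bit for deterministic commands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .decode import DecodeConfig
from .densitometry import LuminosityModel, SamplingPlan
from .render import AssayLayout, RenderScenario

__all__ = ["RunConfig", "load_config", "dump_config"]


def _as_dict(obj: Any) -> dict:
    d = dataclasses.asdict(obj)
    # YAML-friendly: tuples → lists, mapping keys → plain ints
    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        return v
    return {k: clean(v) for k, v in d.items()}


def _build(cls, data: dict | None, tuple_fields: tuple[str, ...] = ()):
    if data is None:
        return cls()
    kwargs = dict(data)
    for f in tuple_fields:
        if f in kwargs and isinstance(kwargs[f], list):
            kwargs[f] = tuple(kwargs[f])
    if "strip_odrs" in kwargs and kwargs["strip_odrs"] is not None:
        kwargs["strip_odrs"] = {int(k): float(v)
                                for k, v in kwargs["strip_odrs"].items()}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) for {cls.__name__}: {', '.join(sorted(unknown))}"
        )
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Everything a command needs besides its input files."""

    layout: AssayLayout = field(default_factory=AssayLayout)
    scenario: RenderScenario = field(default_factory=RenderScenario)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    sampling: SamplingPlan = field(default_factory=SamplingPlan)
    luminosity: LuminosityModel = field(default_factory=LuminosityModel)
    calibration_model: str = "4pl"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "layout": _as_dict(self.layout),
            "scenario": _as_dict(self.scenario),
            "decode": _as_dict(self.decode),
            "sampling": _as_dict(self.sampling),
            "luminosity": _as_dict(self.luminosity),
            "calibration_model": self.calibration_model,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = data or {}
        known = {"layout", "scenario", "decode", "sampling", "luminosity",
                 "calibration_model", "seed", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
        scen = dict(data.get("scenario") or {})
        if "lighting" in scen and isinstance(scen["lighting"], list):
            scen["lighting"] = (scen["lighting"][0], float(scen["lighting"][1]))
        return cls(
            layout=_build(AssayLayout, data.get("layout"), ("character_pair",)),
            scenario=_build(RenderScenario, scen or None),
            decode=_build(DecodeConfig, data.get("decode")),
            sampling=_build(SamplingPlan, data.get("sampling")),
            luminosity=_build(LuminosityModel, data.get("luminosity"), ("weights",)),
            calibration_model=data.get("calibration_model", "4pl"),
            seed=int(data.get("seed", 0)),
            log_level=data.get("log_level", "INFO"),
        )


def load_config(path: str | None) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) config file."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig | None = None, path: str | None = None) -> str:
    """Serialize a config (defaults if none given) to YAML."""
    text = yaml.safe_dump((config or RunConfig()).to_dict(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
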