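"""Run configuration: YAML schema, validation, defaults.

A run analyses either a pair of recorded movies (``inputs``) or a synthetic
pair generated on the fly (``simulation``) — exactly one of the two must be
given.  All analysis stages are switchable; calibration from file sidecars
can be overridden here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .simulate import SimulationParams
from .wavelet import DetectionParams


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisSwitches:
    overlap: bool = True
    spatial_ccf: bool = True
    temporal_ccf: bool = True
    density: bool = True
    shock: bool = False


@dataclass
class RunConfig:
    input_a: Optional[str] = None
    input_b: Optional[str] = None
    simulation: Optional[SimulationParams] = None
    pixel_size_um: Optional[float] = None  # calibration overrides for file inputs
    frame_interval_s: Optional[float] = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    switches: AnalysisSwitches = field(default_factory=AnalysisSwitches)
    max_shift_px: int = 20
    max_lag_frames: int = 10
    t_shock_s: Optional[float] = None
    pre_window_s: float = 30.0
    post_window_s: float = 90.0
    out_dir: str = "punctakit_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_inputs = self.input_a is not None or self.input_b is not None
        if has_inputs and (self.input_a is None or self.input_b is None):
            raise ConfigError("both input_a and input_b are required for file input")
        if has_inputs and self.simulation is not None:
            raise ConfigError("give either input paths or simulation params, not both")
        if not has_inputs and self.simulation is None:
            raise ConfigError("one of input paths or simulation params is required")
        if self.switches.shock and self.t_shock_s is None:
            raise ConfigError("shock analysis requires t_shock_s")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        d["detection"] = dataclasses.asdict(self.detection)
        d["detection"]["detection_scales"] = sorted(self.detection.detection_scales)
        d["switches"] = dataclasses.asdict(self.switches)
        return d


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    sim = data.pop("simulation", None)
    det = data.pop("detection", None) or {}
    sw = data.pop("switches", None) or {}
    if det.get("detection_scales") is not None:
        det["detection_scales"] = frozenset(det["detection_scales"])
    kwargs: dict = {}
    if sim is not None:
        kwargs["simulation"] = _build_section(SimulationParams, sim, "simulation")
    kwargs["detection"] = _build_section(DetectionParams, det, "detection")
    kwargs["switches"] = _build_section(AnalysisSwitches, sw, "switches")
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return config_from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
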