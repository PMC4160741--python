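"""Run configuration with lossless YAML/JSON round-trip.

A :class:`RunConfig` bundles everything a pipeline run needs: system
properties, active parameters, protocols, detector tolerances, sweep/scan
settings and the task to dispatch.  Configurations serialise to plain nested
dicts, so they round-trip through YAML or JSON without loss.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cable_core import SystemProperties
from .dynamics import ActiveParameters, RampProtocol, VClampProtocol
from .firing_analysis import DetectionConfig

__all__ = ["RunConfig", "TASKS"]

TASKS = (
    "invert",
    "simulate_ramp",
    "simulate_vclamp",
    "classify",
    "sweep",
    "distance_scan",
    "robustness",
)


@dataclass
class RunConfig:
    """Complete, serialisable description of one pipeline run."""

    task: str = "classify"
    system: SystemProperties = field(default_factory=SystemProperties)
    active: ActiveParameters = field(default_factory=ActiveParameters)
    ramp: RampProtocol = field(default_factory=RampProtocol)
    vclamp: VClampProtocol = field(default_factory=VClampProtocol)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    # VA triple for single-point tasks (invert / simulate / classify)
    va: tuple[float, float, float] | None = None
    sweep_resolution: int = 21
    distance_step: float = 5.0
    distance_max: float = 2000.0
    neuromod_mode: str = "single_gca"
    neuromod_deltas: tuple[float, ...] = (-0.2, 0.0, 0.2)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.sweep_resolution < 2:
            raise ValueError("sweep_resolution must be at least 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["va"] = list(self.va) if self.va is not None else None
        d["neuromod_deltas"] = list(self.neuromod_deltas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("system", SystemProperties),
            ("active", ActiveParameters),
            ("ramp", RampProtocol),
            ("vclamp", VClampProtocol),
            ("detection", DetectionConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if d.get("va") is not None:
            d["va"] = tuple(d["va"])
        if "neuromod_deltas" in d:
            d["neuromod_deltas"] = tuple(d["neuromod_deltas"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def parameter_hash(self) -> str:
        """Deterministic digest of the full configuration (provenance key)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
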