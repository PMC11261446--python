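"""Run configuration: one YAML file driving every pipeline stage.

Sections map directly onto the library's dataclasses (physics
constants, scene and probe simulation, segmentation windows, tracking,
analysis, uncertainty, paths). Unknown keys anywhere are rejected up
front so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imaging import SegmentationParams
from .physics import AmbientState, PhysicalConstants
from .synthetic import ProbeSimConfig, SceneConfig

__all__ = ["RunConfig", "SegmentationWindow", "load_config"]


@dataclass
class SegmentationWindow:
    """One time window with its own segmentation parameters."""

    start_s: float = 0.0
    end_s: float = float("inf")
    params: SegmentationParams = field(default_factory=SegmentationParams)


@dataclass
class SimulationSpec:
    """What the `simulate` stage should produce."""

    kind: str = "two_mode"  # "dropwise" | "filmwise" | "two_mode"
    h_m_dropwise: float = 0.012  # m·s⁻¹
    h_m_filmwise: float = 0.004
    flux_noise_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("dropwise", "filmwise", "two_mode"):
            raise ValueError(f"unknown simulation kind {self.kind!r}")


@dataclass
class TrackingSpec:
    min_frames: int = 3
    cluster_radius_mm: float = 0.3
    moving_average_s: float = 60.0


@dataclass
class AnalysisSpec:
    surface_temperature_c: float = 34.0
    ambient_temperature_c: float = 24.0
    ambient_relative_humidity: float = 0.30
    total_area_cm2: float = 1.93
    # pass the optically-measured wet fraction through the probe chain's
    # first-order response before slope fits, so both fit variables see
    # the same measurement dynamics
    filter_omega_with_probe_response: bool = True
    # mode label -> [start_s, end_s] over the experiment time base
    mode_windows: dict = field(default_factory=dict)

    @property
    def ambient(self) -> AmbientState:
        return AmbientState(self.ambient_temperature_c, self.ambient_relative_humidity)


@dataclass
class UncertaintySpec:
    n_replicates: int = 3
    confidence: float = 0.95
    u_cout_gm3: float = 0.18
    flow_full_scale_lpm: float = 1.0


@dataclass
class RunConfig:
    """Validated top-level configuration for a pipeline run."""

    seed: int = 0
    output_dir: str = "run_output"
    physics: PhysicalConstants = field(default_factory=PhysicalConstants)
    scene: SceneConfig = field(default_factory=SceneConfig)
    probe: ProbeSimConfig = field(default_factory=ProbeSimConfig)
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    segmentation: list = field(default_factory=lambda: [SegmentationWindow()])
    tracking: TrackingSpec = field(default_factory=TrackingSpec)
    analysis: AnalysisSpec = field(default_factory=AnalysisSpec)
    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec)

    def config_hash(self) -> str:
        """Stable hash of the fully resolved configuration."""
        payload = json.dumps(_as_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def window_params(self, time_s: float) -> SegmentationParams:
        """Segmentation parameters in effect at a given time."""
        for win in self.segmentation:
            if win.start_s <= time_s < win.end_s:
                return win.params
        return self.segmentation[-1].params


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj


def _build(cls, data: dict, where: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise TypeError(f"section '{where}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"unknown key(s) in '{where}': {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


_SECTIONS = {
    "physics": PhysicalConstants,
    "scene": SceneConfig,
    "probe": ProbeSimConfig,
    "simulation": SimulationSpec,
    "tracking": TrackingSpec,
    "analysis": AnalysisSpec,
    "uncertainty": UncertaintySpec,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known_top = set(_SECTIONS) | {"seed", "output_dir", "segmentation"}
    unknown = set(raw) - known_top
    if unknown:
        raise KeyError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            data = dict(raw[name])
            if name == "probe" and "flow_schedule" in data:
                data["flow_schedule"] = tuple(
                    (float(t), float(q)) for t, q in data["flow_schedule"]
                )
            if name == "analysis" and "mode_windows" in data:
                data["mode_windows"] = {
                    k: [float(v[0]), float(v[1])]
                    for k, v in data["mode_windows"].items()
                }
            kwargs[name] = _build(cls, data, name)
    if "segmentation" in raw:
        windows = []
        for i, win in enumerate(raw["segmentation"]):
            win = dict(win)
            start = float(win.pop("start_s", 0.0))
            end = float(win.pop("end_s", float("inf")))
            params = _build(SegmentationParams, win, f"segmentation[{i}]")
            windows.append(SegmentationWindow(start, end, params))
        kwargs["segmentation"] = windows
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return RunConfig(**kwargs)
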