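"""Readers and writers for frame stacks, masks and probe tables.

Frame stacks travel as multi-page TIFF (or a directory of numbered PNG
frames) with a JSON metadata sidecar carrying the pixel pitch, frame
rate and free-form acquisition metadata; probe records and derived
tables are plain CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .imaging import FrameStack, WetSeries

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_masks",
    "read_masks",
    "read_probe_csv",
    "write_wet_series",
    "write_events",
]

_REQUIRED_META = ("pixel_pitch_um", "frame_rate")


def write_frame_stack(stack: FrameStack, path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames)
    meta = {
        "pixel_pitch_um": stack.pixel_pitch_um,
        "frame_rate": stack.frame_rate,
        **stack.metadata,
    }
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_frame_stack(path) -> FrameStack:
    """Read a multi-page TIFF or numbered-PNG directory with sidecar.

    The sidecar (``<stack>.tif.meta.json`` next to a TIFF, or
    ``metadata.json`` inside a frame directory) must define
    ``pixel_pitch_um`` and ``frame_rate``.
    """
    path = Path(path)
    if path.is_dir():
        sidecar = path / "metadata.json"
        frame_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not frame_files:
            raise FileNotFoundError(f"no frame images found in {path}")
        frames = np.stack([iio.imread(p) for p in frame_files])
    else:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise KeyError(f"metadata sidecar {sidecar} is missing key '{key}'")
    pitch = meta.pop("pixel_pitch_um")
    rate = meta.pop("frame_rate")
    if frames.ndim != 3 or len({f.shape for f in frames}) != 1:
        raise ValueError("inconsistent frame shapes in stack")
    return FrameStack(frames, frame_rate=rate, pixel_pitch_um=pitch, metadata=meta)


def write_masks(masks: np.ndarray, path, pixel_pitch_um: float, frame_rate: float) -> Path:
    """Write binary masks as 8-bit (0/255) multi-page TIFF + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.asarray(masks, dtype=bool) * np.uint8(255),
        photometric="minisblack",
    )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"pixel_pitch_um": pixel_pitch_um, "frame_rate": frame_rate})
    )
    return path


def read_masks(path):
    """Read a 0/255 mask TIFF; returns (bool array, metadata dict)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data > 0, meta


def read_probe_csv(path) -> tuple[pd.DataFrame, dict]:
    """Parse a capsule probe/flow CSV.

    Required columns: time_s, flow_lpm, cout_gm3; optional cin_gm3.
    Time must be strictly increasing. Unknown extra columns are
    preserved in the returned metadata dict.
    """
    df = pd.read_csv(path)
    required = ("time_s", "flow_lpm", "cout_gm3")
    for col in required:
        if col not in df.columns:
            raise KeyError(f"probe CSV {path} is missing column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"probe CSV {path}: time_s must be strictly increasing")
    known = set(required) | {"cin_gm3"}
    extra = {c: df[c].to_numpy() for c in df.columns if c not in known}
    core = df[[c for c in df.columns if c in known]]
    return core, extra


_FLOAT_FMT = "%.6g"


def write_wet_series(series: WetSeries, path) -> Path:
    """Export the per-frame wet-area series as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = series.wet_area_cm2.size
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / series.frame_rate,
            "wet_area_cm2": series.wet_area_cm2,
            "omega": series.omega,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_events(events_df: pd.DataFrame, path) -> Path:
    """Export a droplet-event table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events_df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
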