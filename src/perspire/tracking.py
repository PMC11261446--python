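"""Spatiotemporal droplet-event extraction and statistics.

A droplet "event" is one connected wet component in the (x, y, time)
volume of the binary mask stack — the 3D (time-as-z) object-counting
view of the video. Events shorter than three frames are treated as
noise and filtered out; the survivors yield the droplet statistics that
characterize cyclic dropwise sweating: active-pore counts over time,
the wet-area-per-droplet regression, maximum-diameter and duration
distributions, and per-pore cycle periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DropletEvent",
    "EventSummary",
    "label_events",
    "filter_short_events",
    "event_metrics",
    "events_to_frame",
    "active_count_series",
    "moving_average",
    "fit_area_vs_count",
    "distribution_summary",
    "cycle_period_estimate",
]

#: 26-connectivity in (t, y, x) — the 3D object counter's default.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DropletEvent:
    """One spatiotemporally connected wet event."""

    id: int
    start_frame: int
    end_frame: int
    duration_s: float
    max_area_mm2: float
    max_equivalent_diameter_mm: float
    centroid_mm: tuple  # (x, y) from the top-left corner
    area_trace_mm2: np.ndarray  # per-frame area over [start, end]

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class EventSummary:
    """Aggregate droplet statistics for one scene."""

    n_events: int
    max_diameter_mm: np.ndarray  # sorted
    duration_s: np.ndarray  # sorted

    def cdf(self, which: str = "max_diameter"):
        """Empirical CDF (values, cumulative probabilities)."""
        values = (
            self.max_diameter_mm if which == "max_diameter" else self.duration_s
        )
        probs = np.arange(1, values.size + 1) / values.size
        return values, probs

    def percentile(self, p: float, which: str = "max_diameter") -> float:
        """Order-statistic percentile, p in [0, 100]."""
        values = (
            self.max_diameter_mm if which == "max_diameter" else self.duration_s
        )
        return float(np.percentile(values, p))


@dataclass
class _RawEvent:
    """Label-map event before unit conversion (pixel/frame units)."""

    label: int
    start_frame: int
    end_frame: int
    pixel_counts: np.ndarray  # per frame over [start, end]
    centroid_px: tuple  # (y, x)


def label_events(mask_stack: np.ndarray, structure: np.ndarray = STRUCT_26):
    """Connected components of the binary (t, y, x) volume.

    Returns (raw_events, labeled_stack). Each component — 26-connected
    by default — is one droplet event; its per-frame slice sizes give
    the area trace.
    """
    m = np.asarray(mask_stack, dtype=bool)
    if m.ndim != 3:
        raise ValueError("mask_stack must be (time, y, x)")
    labeled, n = ndimage.label(m, structure=structure)
    if n == 0:
        return [], labeled
    tt, yy, xx = np.nonzero(labeled)
    labels = labeled[tt, yy, xx]
    events = []
    order = np.argsort(labels, kind="stable")
    labels, tt, yy, xx = labels[order], tt[order], yy[order], xx[order]
    bounds = np.searchsorted(labels, np.arange(1, n + 2))
    for lab in range(1, n + 1):
        lo, hi = bounds[lab - 1], bounds[lab]
        t_l, y_l, x_l = tt[lo:hi], yy[lo:hi], xx[lo:hi]
        t0, t1 = int(t_l.min()), int(t_l.max())
        counts = np.bincount(t_l - t0, minlength=t1 - t0 + 1)
        events.append(
            _RawEvent(
                label=lab,
                start_frame=t0,
                end_frame=t1,
                pixel_counts=counts,
                centroid_px=(float(y_l.mean()), float(x_l.mean())),
            )
        )
    return events, labeled


def filter_short_events(events, min_frames: int = 3):
    """Drop noise events spanning fewer than ``min_frames`` frames.

    The default removes events lasting only one or two slices, which
    in real recordings are dominated by residual noise.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [
        ev
        for ev in events
        if (ev.end_frame - ev.start_frame + 1) >= min_frames
    ]


def event_metrics(
    raw: _RawEvent, pixel_pitch_um: float, frame_rate: float
) -> DropletEvent:
    """Convert a raw labeled event to physical units.

    Max area is the largest per-frame slice; the equivalent diameter is
    that of the circle of equal area, √(4A/π).
    """
    if raw.pixel_counts.sum() == 0:
        raise ValueError("empty event")
    pitch_mm = pixel_pitch_um / 1000.0
    area_trace = raw.pixel_counts * pitch_mm**2
    max_area = float(area_trace.max())
    return DropletEvent(
        id=raw.label,
        start_frame=raw.start_frame,
        end_frame=raw.end_frame,
        duration_s=(raw.end_frame - raw.start_frame + 1) / frame_rate,
        max_area_mm2=max_area,
        max_equivalent_diameter_mm=float(np.sqrt(4.0 * max_area / np.pi)),
        centroid_mm=(raw.centroid_px[1] * pitch_mm, raw.centroid_px[0] * pitch_mm),
        area_trace_mm2=area_trace,
    )


def extract_events(
    mask_stack: np.ndarray,
    pixel_pitch_um: float,
    frame_rate: float,
    min_frames: int = 3,
):
    """label → filter → metrics convenience pipeline."""
    raw, _ = label_events(mask_stack)
    kept = filter_short_events(raw, min_frames=min_frames)
    return [event_metrics(ev, pixel_pitch_um, frame_rate) for ev in kept]


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate events, one row each, in export units."""
    rows = [
        {
            "id": ev.id,
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame,
            "duration_s": ev.duration_s,
            "max_area_mm2": ev.max_area_mm2,
            "max_diam_mm": ev.max_equivalent_diameter_mm,
            "x_mm": ev.centroid_mm[0],
            "y_mm": ev.centroid_mm[1],
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "start_frame",
            "end_frame",
            "duration_s",
            "max_area_mm2",
            "max_diam_mm",
            "x_mm",
            "y_mm",
        ],
    )


def active_count_series(events, n_frames: int) -> np.ndarray:
    """Number of events overlapping each frame (active droplets/pores)."""
    counts = np.zeros(n_frames, dtype=int)
    for ev in events:
        counts[ev.start_frame : ev.end_frame + 1] += 1
    return counts


def moving_average(series, window_s: float = 60.0, frame_rate: float = 10.0):
    """Centered moving average with truncated (shrinking) edges."""
    x = np.asarray(series, dtype=float)
    half = max(int(round(window_s * frame_rate / 2)), 0)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def fit_area_vs_count(wet_area_mm2, counts):
    """OLS of per-frame wet area on active-droplet count.

    The slope is the average wet area contributed per active droplet
    (mm²·droplet⁻¹); the circle of that area gives the "average
    droplet" diameter.
    """
    area = np.asarray(wet_area_mm2, dtype=float)
    cnt = np.asarray(counts, dtype=float)
    if np.unique(cnt).size < 2:
        raise ValueError("counts are constant; area-vs-count fit is degenerate")
    res = stats.linregress(cnt, area)
    return float(res.slope), float(res.intercept)


def distribution_summary(events) -> EventSummary:
    """Sorted max-diameter / duration samples with CDF and percentiles."""
    if not events:
        raise ValueError("no events to summarize")
    diam = np.sort([ev.max_equivalent_diameter_mm for ev in events])
    dur = np.sort([ev.duration_s for ev in events])
    return EventSummary(n_events=len(events), max_diameter_mm=diam, duration_s=dur)


def cluster_pores(events, cluster_radius_mm: float = 0.3):
    """Greedily assign events to pores by centroid proximity.

    Events are scanned in start order; an event joins the first pore
    whose running-mean centroid lies within ``cluster_radius_mm``,
    otherwise it founds a new pore. Returns a list of event lists.
    """
    pores: list[list] = []
    centers: list[np.ndarray] = []
    sizes: list[int] = []
    for ev in sorted(events, key=lambda e: e.start_frame):
        c = np.array(ev.centroid_mm)
        assigned = False
        for i, ctr in enumerate(centers):
            if np.hypot(*(c - ctr)) <= cluster_radius_mm:
                pores[i].append(ev)
                centers[i] = (ctr * sizes[i] + c) / (sizes[i] + 1)
                sizes[i] += 1
                assigned = True
                break
        if not assigned:
            pores.append([ev])
            centers.append(c)
            sizes.append(1)
    return pores


def cycle_period_estimate(
    events, frame_rate: float, cluster_radius_mm: float = 0.3
):
    """Per-pore firing periods from inter-event onset intervals.

    Pores with fewer than two events contribute no periods. Returns a
    dict with the pooled periods plus mean and range summaries.
    """
    pores = cluster_pores(events, cluster_radius_mm)
    periods = []
    per_pore = []
    for pore_events in pores:
        onsets = np.sort([ev.start_frame for ev in pore_events]) / frame_rate
        if onsets.size < 2:
            per_pore.append(np.array([]))
            continue
        gaps = np.diff(onsets)
        per_pore.append(gaps)
        periods.extend(gaps.tolist())
    periods = np.asarray(periods)
    return {
        "n_pores": len(pores),
        "periods_s": periods,
        "per_pore_periods_s": per_pore,
        "mean_period_s": float(periods.mean()) if periods.size else np.nan,
        "period_range_s": (
            (float(periods.min()), float(periods.max())) if periods.size else (np.nan, np.nan)
        ),
    }
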