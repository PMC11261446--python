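"""MWIR frame-stack processing: stabilization, wet/dry segmentation.

Sweat is colder than the surrounding skin in the mid-wave infrared
(water absorbs strongly near 3 μm and the evaporating surface is
evaporatively cooled), so liquid shows up dark. The segmentation
convention throughout is therefore *wet = below the local threshold*.

Two local auto-threshold methods are provided, matching the two
sweating modes:

* Phansalkar (mean/variance based, tuned for low-contrast bright-field
  style images) for the small near-circular droplets of cyclic
  dropwise sweating, window radius 15–25 px;
* mid-grey (mean of local extrema) with a larger 35 px radius for the
  wide, shallow puddles of filmwise sweating.

Both operate on square windows of side 2·radius+1 with mirror padding;
the brute-force windowed oracle in the test suite defines the contract
and the production path matches it exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameStack",
    "WetSeries",
    "SegmentationParams",
    "stabilize_stack",
    "phansalkar_threshold",
    "midgrey_threshold",
    "refine_mask",
    "wet_area_series",
    "segment_stack",
    "normalize_stack",
]


@dataclass
class FrameStack:
    """A calibrated grayscale IR video.

    ``frames`` has shape (n_frames, height, width); ``pixel_pitch_um``
    is the on-skin size of one pixel and ``frame_rate`` the acquisition
    rate in Hz.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, y, x) array")
        if self.frame_rate <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("frame_rate and pixel_pitch_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class WetSeries:
    """Binary wet masks plus the wet-area/wet-fraction time series."""

    masks: np.ndarray  # bool (time, y, x)
    wet_area_cm2: np.ndarray
    omega: np.ndarray
    total_area_cm2: float
    pixel_pitch_um: float
    frame_rate: float


@dataclass
class SegmentationParams:
    """Configuration of the mode-dependent segmentation pipeline."""

    mode: str = "dropwise"  # "dropwise" | "filmwise"
    method: str = "phansalkar"  # "phansalkar" | "midgrey"
    radius: int = 20
    phansalkar_k: float = 0.25
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    phansalkar_r: float = 0.5
    midgrey_open_px: int = 0
    midgrey_min_contrast: float = 0.0
    morphology: tuple = ("close", "dilate")
    blur_radius: float = 2.0
    rethreshold_level: float = 0.5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.method not in ("phansalkar", "midgrey"):
            raise ValueError(f"unknown threshold method {self.method!r}")

    @classmethod
    def dropwise(cls, radius: int = 20) -> "SegmentationParams":
        """Calibrated dropwise preset (Phansalkar + close/dilate).

        The 0.7 re-threshold after the blur pulls the dilated boundary
        back to the true droplet edge (validated against synthetic
        truth masks).
        """
        return cls(
            mode="dropwise", method="phansalkar", radius=radius,
            rethreshold_level=0.7,
        )

    @classmethod
    def filmwise(cls, radius: int = 35) -> "SegmentationParams":
        """Filmwise preset: mid-grey + close/dilate/fill_holes.

        Mid-grey only fires where a window straddles the puddle edge,
        so interiors wider than the window are recovered by the
        hole-filling step.
        """
        return cls(
            mode="filmwise",
            method="midgrey",
            radius=radius,
            midgrey_open_px=2,
            midgrey_min_contrast=0.15,
            morphology=("close", "dilate", "dilate", "fill_holes"),
            rethreshold_level=0.5,
        )


def normalize_stack(frames: np.ndarray) -> np.ndarray:
    """Scale a stack linearly to [0, 1] using its global min/max."""
    f = np.asarray(frames, dtype=float)
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def stabilize_stack(
    stack: FrameStack,
    reference: int | str = "coldest",
    upsample: int = 20,
    exclude_wet_px: int = 8,
    smooth_window: int = 9,
):
    """Remove frame-to-frame translation (breathing shake) from a stack.

    Each frame is registered to the reference frame by the
    cross-correlation peak (subpixel via Fourier upsampling) and shifted
    back with linear interpolation, edge-replicated borders.

    Registration deliberately ignores the sweat itself: wet features
    appear, grow and vanish, so correlating on them tracks sweat motion
    instead of camera motion. Each frame is clipped below its median
    (sweat is dark), pixels within ``exclude_wet_px`` of any
    below-median pixel are zeroed, and the remainder is band-pass
    filtered (1-5 px) so sharp static skin structure dominates the
    correlation; a Tukey taper suppresses the non-periodic edges.
    ``reference="coldest"`` picks the lowest-mean (most sweat-covered)
    frame, whose surviving dry anchors are visible in every other frame.

    Returns
    -------
    (FrameStack, offsets) where ``offsets[i]`` is the (dy, dx) detected
    displacement of frame i relative to the reference; the correction
    applied is its negation.
    """
    frames = np.asarray(stack.frames, dtype=float)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to stabilize")
    if reference == "coldest":
        reference = int(np.argmin(frames.mean(axis=(1, 2))))
    ref = frames[reference]
    offsets = np.zeros((n, 2))
    out = np.empty_like(frames)
    if np.ptp(ref) == 0:
        warnings.warn("reference frame is constant; stabilization skipped")
        return (
            FrameStack(frames.copy(), stack.frame_rate, stack.pixel_pitch_um,
                       dict(stack.metadata)),
            offsets,
        )
    from scipy.signal.windows import tukey

    window = np.outer(tukey(ref.shape[0], 0.25), tukey(ref.shape[1], 0.25))

    def _prep(image: np.ndarray) -> np.ndarray:
        med = np.median(image)
        clipped = np.maximum(image, med)
        if exclude_wet_px > 0:
            keep = ~ndimage.binary_dilation(
                image < med, iterations=exclude_wet_px
            )
            if keep.mean() < 0.1:  # degenerate: nearly everything wet
                keep = np.ones_like(keep)
        else:
            keep = np.ones(image.shape, dtype=bool)
        band = ndimage.gaussian_filter(clipped, 1.0) - ndimage.gaussian_filter(
            clipped, 5.0
        )
        return band * keep * window

    ref_w = _prep(ref)
    for i in range(n):
        if i == reference:
            continue
        shift, _, _ = phase_cross_correlation(
            ref_w, _prep(frames[i]), upsample_factor=upsample, normalization=None
        )
        # the returned shift registers frame i onto the reference, i.e.
        # minus the frame's apparent displacement
        offsets[i] = -shift

    # Second pass: camera shake is temporally smooth, so an offset far
    # from the median-filtered trajectory is a registration outlier
    # (a spurious correlation peak). Re-register those frames after
    # pre-aligning at the smooth prediction, where the residual peak is
    # unambiguous.
    if n >= 5:
        smooth = np.column_stack(
            [ndimage.median_filter(offsets[:, k], size=7, mode="nearest")
             for k in range(2)]
        )
        outliers = np.flatnonzero(
            np.hypot(*(offsets - smooth).T) > 1.0
        )
        for i in outliers:
            if i == reference:
                continue
            pred = smooth[i]
            aligned = ndimage.shift(frames[i], -pred, order=1, mode="nearest")
            resid, _, _ = phase_cross_correlation(
                ref_w, _prep(aligned), upsample_factor=upsample,
                normalization=None,
            )
            if np.hypot(*resid) < np.hypot(*(offsets[i] - pred)):
                offsets[i] = pred - resid

    # Breathing shake is smooth at the frame rate, so a short quadratic
    # Savitzky-Golay filter on the offset trajectory suppresses the
    # random per-frame registration error without biasing the motion.
    # Set smooth_window to 0 for raw per-frame offsets.
    if smooth_window >= 5 and n >= smooth_window:
        from scipy.signal import savgol_filter

        offsets = savgol_filter(offsets, smooth_window, 2, axis=0)
        offsets[reference] = 0.0

    for i in range(n):
        out[i] = (
            frames[i]
            if i == reference
            else ndimage.shift(frames[i], -offsets[i], order=1, mode="nearest")
        )
    stabilized = FrameStack(
        out, stack.frame_rate, stack.pixel_pitch_um, dict(stack.metadata)
    )
    return stabilized, offsets


def _window_mean_std(image: np.ndarray, radius: int):
    """Local mean and population std over square windows, mirror padded."""
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(image, size=size, mode="mirror")
    mean_sq = ndimage.uniform_filter(image * image, size=size, mode="mirror")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, np.sqrt(var)


def phansalkar_threshold(
    image: np.ndarray,
    radius: int = 20,
    k: float = 0.25,
    p: float = 2.0,
    q: float = 10.0,
    r: float = 0.5,
) -> np.ndarray:
    """Phansalkar local threshold; wet (cold/dark) = value < threshold.

    Per-pixel threshold over the (2·radius+1)² mirror-padded window with
    local mean m and standard deviation s:

        t = m · (1 + p·exp(−q·m) + k·(s/r − 1))

    The image must be normalized to [0, 1] (the exponential term is
    scale-dependent).
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(
            "phansalkar_threshold expects an image normalized to [0, 1]; "
            "use normalize_stack() first"
        )
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mean, std = _window_mean_std(img, radius)
    thresh = mean * (1.0 + p * np.exp(-q * mean) + k * (std / r - 1.0))
    return img < thresh


def midgrey_threshold(
    image: np.ndarray,
    radius: int = 35,
    open_px: int = 0,
    min_contrast: float = 0.0,
) -> np.ndarray:
    """Mid-grey local threshold: t = (local max + local min)/2.

    Wet = value strictly below t, square window, mirror padding. On a
    locally uniform region max = min = value and nothing is detected;
    detection relies on windows that straddle a wet/dry boundary, which
    is why filmwise segmentation pairs this with a large radius and a
    hole-filling refine step.

    Two optional robustness knobs (both off by default, leaving the
    plain mean-of-extrema operator): ``open_px`` > 0 applies a
    grey-scale opening with a (2·open_px+1)² element before windowing,
    flattening bright structures thinner than the element (warm crevice
    lines) that would otherwise inflate the local midrange; and windows
    whose max-min range is below ``min_contrast`` are classified dry,
    suppressing detections driven by shallow skin-texture variation.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(image, dtype=float)
    if open_px > 0:
        size_open = 2 * open_px + 1
        img = ndimage.grey_opening(img, size=(size_open, size_open), mode="mirror")
    size = 2 * radius + 1
    local_max = ndimage.maximum_filter(img, size=size, mode="mirror")
    local_min = ndimage.minimum_filter(img, size=size, mode="mirror")
    wet = img < (local_max + local_min) / 2.0
    if min_contrast > 0.0:
        # the guard measures structural contrast, so it is evaluated on
        # a noise-suppressed copy: the raw windowed range is dominated
        # by single-pixel noise extremes over thousands of samples
        smooth = ndimage.gaussian_filter(img, 2.0, mode="mirror")
        s_range = ndimage.maximum_filter(
            smooth, size=size, mode="mirror"
        ) - ndimage.minimum_filter(smooth, size=size, mode="mirror")
        wet &= s_range >= min_contrast
    return wet


_STRUCT3 = np.ones((3, 3), dtype=bool)


def refine_mask(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Clean a binary wet mask: close, dilate, blur + rethreshold.

    The ordered ``params.morphology`` ops ("close", "dilate",
    "fill_holes", any subset/order) run first with 3×3 structuring
    elements, then the 0/1 mask is Gaussian blurred with
    ``params.blur_radius`` and re-thresholded at
    ``params.rethreshold_level`` to return to binary. Isolated
    single-pixel detections do not survive the blur; 1-px holes inside
    droplets are closed. Set ``blur_radius`` to 0 to skip the blur.
    """
    m = np.asarray(mask, dtype=bool)
    for op in params.morphology:
        if op == "close":
            m = ndimage.binary_closing(m, structure=_STRUCT3)
        elif op == "dilate":
            m = ndimage.binary_dilation(m, structure=_STRUCT3)
        elif op == "erode":
            m = ndimage.binary_erosion(m, structure=_STRUCT3)
        elif op == "fill_holes":
            m = ndimage.binary_fill_holes(m)
        else:
            raise ValueError(f"unknown morphology op {op!r}")
    if params.blur_radius > 0:
        blurred = ndimage.gaussian_filter(m.astype(float), sigma=params.blur_radius)
        m = blurred > params.rethreshold_level
    return m


def wet_area_series(
    masks: np.ndarray,
    pixel_pitch_um: float,
    total_area_cm2: float = 1.93,
    frame_rate: float = 10.0,
) -> WetSeries:
    """Per-frame wet area (cm²) and wet fraction ω from binary masks."""
    if total_area_cm2 <= 0:
        raise ValueError("total_area_cm2 must be strictly positive")
    m = np.asarray(masks, dtype=bool)
    if m.ndim == 2:
        m = m[None]
    pitch_cm = pixel_pitch_um * 1e-4
    counts = m.reshape(m.shape[0], -1).sum(axis=1)
    area = counts * pitch_cm**2
    return WetSeries(
        masks=m,
        wet_area_cm2=area,
        omega=area / total_area_cm2,
        total_area_cm2=total_area_cm2,
        pixel_pitch_um=pixel_pitch_um,
        frame_rate=frame_rate,
    )


def segment_frame(image01: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Threshold + refine a single normalized frame."""
    if params.method == "phansalkar":
        raw = phansalkar_threshold(
            image01,
            radius=params.radius,
            k=params.phansalkar_k,
            p=params.phansalkar_p,
            q=params.phansalkar_q,
            r=params.phansalkar_r,
        )
    else:
        raw = midgrey_threshold(
            image01,
            radius=params.radius,
            open_px=params.midgrey_open_px,
            min_contrast=params.midgrey_min_contrast,
        )
    return refine_mask(raw, params)


def segment_stack(
    stack: FrameStack,
    params: SegmentationParams,
    total_area_cm2: float | None = None,
    overrides=None,
) -> WetSeries:
    """Segment every frame of a stack into wet/dry and build a WetSeries.

    ``total_area_cm2`` defaults to the imaged field of view. ``overrides``
    is an optional list of manual region edits (see
    :func:`apply_overrides`) replacing the hand edits of an interactive
    workflow with a scriptable record.
    """
    frames01 = normalize_stack(stack.frames)
    masks = np.empty(stack.frames.shape, dtype=bool)
    for i in range(stack.n_frames):
        masks[i] = segment_frame(frames01[i], params)
    if overrides:
        masks = apply_overrides(masks, overrides)
    if total_area_cm2 is None:
        h, w = stack.frames.shape[1:]
        pitch_cm = stack.pixel_pitch_um * 1e-4
        total_area_cm2 = h * w * pitch_cm**2
    return wet_area_series(
        masks, stack.pixel_pitch_um, total_area_cm2, stack.frame_rate
    )


def apply_overrides(masks: np.ndarray, overrides) -> np.ndarray:
    """Apply scripted per-frame rectangular mask edits.

    Each override is a mapping with keys ``frames`` (inclusive
    [start, end]), ``rect`` ([y0, y1, x0, x1], inclusive-exclusive) and
    ``action`` ("add" or "remove"). A warning is emitted per edit so
    runs remain auditable.
    """
    out = np.array(masks, dtype=bool, copy=True)
    for ov in overrides:
        f0, f1 = ov["frames"]
        y0, y1, x0, x1 = ov["rect"]
        value = ov["action"] == "add"
        if ov["action"] not in ("add", "remove"):
            raise ValueError(f"unknown override action {ov['action']!r}")
        warnings.warn(
            f"mask override applied: {ov['action']} rect {ov['rect']} "
            f"on frames {f0}-{f1}"
        )
        out[f0 : f1 + 1, y0:y1, x0:x1] = value
    return out
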