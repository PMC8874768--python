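"""Core domain types and coordinate conventions.

Conventions used throughout the package:

* Arrays are row-major; image coordinates are 0-based ``(row, col)``.
* Pixel ``(i, j)`` has its *center* at ``(i + 0.5, j + 0.5)`` in continuous
  coordinates.  Polygon rasterization includes a pixel iff its center lies
  inside the polygon under the even-odd rule, with boundary ties resolved by
  a fixed half-open convention (top/left edges in), so masks are
  deterministic.
* Time is seconds from the first recorded frame, stored as float.
* Fluorescence intensity is in relative intensity units ("i"); no
  radiometric calibration is attempted, so slopes carry units i/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MUSCLE = "muscle"
CONTROL = "control"
ROI_ROLES = (MUSCLE, CONTROL)


@dataclass
class FrameStack:
    """A T x H x W grayscale fluorescence video with per-frame timestamps.

    Parameters
    ----------
    frames
        Non-negative intensity array of shape ``(T, H, W)``.
    timestamps
        Strictly increasing acquisition times in seconds from recording
        start, length ``T``.
    meta
        Free-form recording metadata (e.g. camera distance in cm, ICG dose
        in mg).  Carried through, never computed upon.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("insufficient frames: a recording needs at least 2 frames")
        if self.timestamps.ndim != 1 or len(self.timestamps) != self.frames.shape[0]:
            raise ValueError(
                f"timestamp count {self.timestamps.shape} does not match "
                f"{self.frames.shape[0]} frames"
            )
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("timestamps must be finite")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Record length in seconds (last minus first timestamp)."""
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class Roi:
    """A labeled region of interest, given as a polygon or an explicit mask.

    Muscle ROIs are labeled "1".."10" from the proximal base towards the
    distal tip; the positive-control region on surrounding skin is labeled
    "skin" with role ``control``.
    """

    label: str
    role: str
    polygon: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROI_ROLES}")
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("exactly one of polygon or mask must be given")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
                raise ValueError("polygon must be an (N, 2) array of (row, col) vertices")
            if self.polygon.shape[0] < 3:
                raise ValueError("degenerate polygon: at least 3 vertices required")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("mask must be 2-D")


def _muscle_sort_key(roi: Roi):
    try:
        return (0, int(roi.label))
    except ValueError:
        return (1, roi.label)


@dataclass
class RoiSet:
    """An ordered collection of ROIs tied to a frame shape.

    Muscle ROIs are kept in numeric label order (proximal to distal);
    control ROIs follow.
    """

    rois: list[Roi]
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate label(s): {sorted(dupes)}")
        muscle = sorted((r for r in self.rois if r.role == MUSCLE), key=_muscle_sort_key)
        control = [r for r in self.rois if r.role == CONTROL]
        self.rois = muscle + control
        self.frame_shape = (int(self.frame_shape[0]), int(self.frame_shape[1]))

    @property
    def muscle_rois(self) -> list[Roi]:
        return [r for r in self.rois if r.role == MUSCLE]

    @property
    def control_rois(self) -> list[Roi]:
        return [r for r in self.rois if r.role == CONTROL]

    def get(self, label: str) -> Roi:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass
class PerfusionCurve:
    """Fluorescence intensity over time for one ROI.

    ``baseline_mean``/``baseline_sd`` summarize the pre-signal baseline
    window (the first ``baseline_n`` samples); they are carried with the
    curve so that downstream detection thresholds are reproducible.
    """

    times: np.ndarray
    intensities: np.ndarray
    roi_label: str = ""
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    baseline_n: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class CurveFeatures:
    """Scalar indicators extracted from one perfusion curve.

    ``slope_max`` is the maximum slope of the (smoothed) curve in i/s — the
    principal objective perfusion indicator; ``time_to_signal`` is the
    latency from recording start to first sustained supra-baseline signal,
    or ``None`` if the signal never appears.
    """

    slope_max: float
    t_slope_max: float
    time_to_signal: Optional[float]
    peak_intensity: float
    t_peak: float
    has_ingress: bool
    has_egress: bool
    plateau_flag: bool = False
    roi_label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_max):
            raise ValueError("slope_max must be finite")
        if self.has_egress and not self.has_ingress:
            raise ValueError("has_egress requires has_ingress")
        if self.has_ingress and self.t_slope_max > self.t_peak:
            raise ValueError("t_slope_max must not exceed t_peak for an ingress curve")


@dataclass
class SlopeMap:
    """Per-pixel slope_max parametric image.

    ``values`` holds slope_max in i/s (NaN outside ``analyzed_mask``);
    ``no_slope_mask`` marks analyzed pixels whose maximum slope falls below
    the no-slope threshold ("no slope across the perfusion curve").
    """

    values: np.ndarray
    no_slope_mask: np.ndarray
    analyzed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.no_slope_mask = np.asarray(self.no_slope_mask, dtype=bool)
        self.analyzed_mask = np.asarray(self.analyzed_mask, dtype=bool)
        if not (self.values.shape == self.no_slope_mask.shape == self.analyzed_mask.shape):
            raise ValueError("values and masks must share one H x W shape")
        if np.any(self.no_slope_mask & ~self.analyzed_mask):
            raise ValueError("no_slope_mask must be a subset of analyzed_mask")
        if not np.all(np.isfinite(self.values[self.analyzed_mask])):
            raise ValueError("values must be finite on the analyzed mask")


def rasterize_polygon(polygon: Sequence[Sequence[float]], frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by the even-odd rule.

    A pixel is included iff its center ``(row + 0.5, col + 0.5)`` lies
    inside the polygon.  Edges are treated half-open (a center exactly on a
    boundary belongs to the region on its top/left side), so adjacent
    polygons sharing an edge rasterize to disjoint masks.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("degenerate polygon: at least 3 (row, col) vertices required")
    h, w = int(frame_shape[0]), int(frame_shape[1])
    yc = np.arange(h)[:, None] + 0.5  # (H, 1) row coordinate of centers
    xc = np.arange(w)[None, :] + 0.5  # (1, W) col coordinate of centers
    inside = np.zeros((h, w), dtype=bool)
    n = poly.shape[0]
    for k in range(n):
        r1, c1 = poly[k]
        r2, c2 = poly[(k + 1) % n]
        if r1 == r2:
            continue  # horizontal edge never crosses a scan ray
        crosses = (r1 > yc) != (r2 > yc)  # (H, 1)
        x_int = (c2 - c1) * (yc - r1) / (r2 - r1) + c1  # (H, 1)
        inside ^= crosses & (xc < x_int)
    return inside


def rasterize_roi(roi: Roi, frame_shape: tuple[int, int]) -> np.ndarray:
    """Return the boolean pixel mask of an ROI on a frame of given shape."""
    h, w = int(frame_shape[0]), int(frame_shape[1])
    if roi.mask is not None:
        if roi.mask.shape != (h, w):
            raise ValueError(
                f"mask shape {roi.mask.shape} does not match frame shape {(h, w)}"
            )
        mask = roi.mask
    else:
        mask = rasterize_polygon(roi.polygon, (h, w))
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} rasterizes to an empty mask")
    return mask
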