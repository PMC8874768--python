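"""Automated pixel-to-pixel analysis: per-pixel slope_max parametric maps.

Every analyzed pixel's time series is pushed through *exactly* the ROI
curve pipeline (same smoothing, same sliding-window least-squares slope,
same baseline and ingress-threshold rules), run column-wise over all
pixels at once.  A single-pixel ROI therefore yields bit-identical numbers
on both paths — the equivalence is structural, not approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .core import FrameStack, SlopeMap
from .curves import (
    baseline_split,
    baseline_stats,
    ingress_threshold,
    max_with_earliest_tie,
    moving_average_series,
    noise_slope_floor,
    slope_series,
)

# Fixed blue -> red lookup table shipped with the package so rendered maps
# are reproducible byte-for-byte.  Anchors: dark blue, blue, cyan, green,
# yellow, red; 256 linearly interpolated entries.
_ANCHORS = np.array(
    [
        [0.0, 0, 0, 139],
        [0.2, 0, 0, 255],
        [0.4, 0, 255, 255],
        [0.6, 0, 255, 0],
        [0.8, 255, 255, 0],
        [1.0, 255, 0, 0],
    ]
)


def _build_lut() -> np.ndarray:
    x = np.linspace(0.0, 1.0, 256)
    lut = np.stack(
        [np.interp(x, _ANCHORS[:, 0], _ANCHORS[:, 1 + c]) for c in range(3)], axis=1
    )
    return np.round(lut).astype(np.uint8)


SLOPE_LUT = _build_lut()


def compute_slope_map(
    stack: FrameStack,
    analyzed_mask: Optional[np.ndarray] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SlopeMap:
    """slope_max of every analyzed pixel's time series, as an H x W map.

    ``no_slope_mask`` marks pixels whose slope_max stays at or below the
    no-slope threshold: ``config.theta_pixel`` when set, otherwise the same
    per-series ingress threshold the ROI pipeline derives (noise-slope
    floor and dynamic-range terms).
    """
    h, w = stack.frame_shape
    if analyzed_mask is None:
        analyzed_mask = np.ones((h, w), dtype=bool)
    analyzed_mask = np.asarray(analyzed_mask, dtype=bool)
    if analyzed_mask.shape != (h, w):
        raise ValueError("analyzed_mask shape does not match the frames")
    if not analyzed_mask.any():
        raise ValueError("analyzed_mask is empty")

    t = stack.timestamps
    y = stack.frames[:, analyzed_mask].astype(float)  # (T, P)
    smoothed = moving_average_series(t, y, config.smoothing_window_s)
    slopes = slope_series(t, smoothed, config.slope_window_s)
    smax, _, _ = max_with_earliest_tie(slopes, t)

    if config.theta_pixel is not None:
        theta = np.full(smax.shape, float(config.theta_pixel))
    else:
        n_base = baseline_split(t, y, config)
        _, sd = baseline_stats(y, n_base)
        floor = noise_slope_floor(t, slopes, n_base, sd, config)
        theta = ingress_threshold(t, smoothed, floor, config)

    values = np.full((h, w), np.nan)
    values[analyzed_mask] = smax
    no_slope = np.zeros((h, w), dtype=bool)
    no_slope[analyzed_mask] = smax <= theta
    return SlopeMap(values=values, no_slope_mask=no_slope, analyzed_mask=analyzed_mask)


@dataclass
class RenderedMap:
    """An RGB rendering of a slope map plus its color-scale anchoring."""

    rgb: np.ndarray  # H x W x 3 uint8
    lo: float
    hi: float
    scale: str


def render_slope_map(
    slope_map: SlopeMap, scale: Union[str, tuple[float, float]] = "min_max"
) -> RenderedMap:
    """Color-code a slope map with the package's fixed blue->red table.

    ``scale`` is ``"min_max"`` (anchor to the analyzed values of this map)
    or an explicit ``(lo, hi)`` in i/s.  No-slope pixels are forced to the
    darkest blue regardless of value; non-analyzed pixels render black.
    A degenerate constant map under min_max renders mid-scale with a
    warning.
    """
    vals = slope_map.values
    analyzed = slope_map.analyzed_mask
    if isinstance(scale, str):
        if scale != "min_max":
            raise ValueError(f"unknown scale {scale!r}")
        lo = float(np.nanmin(vals[analyzed]))
        hi = float(np.nanmax(vals[analyzed]))
        scale_name = "min_max"
    else:
        lo, hi = float(scale[0]), float(scale[1])
        if lo >= hi:
            raise ValueError("fixed scale requires lo < hi")
        scale_name = "fixed"

    h, w = vals.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    if hi > lo:
        norm = np.clip((vals[analyzed] - lo) / (hi - lo), 0.0, 1.0)
        idx = np.round(norm * 255).astype(int)
    else:
        warnings.warn("degenerate min-max scale (constant map); rendering mid-color")
        idx = np.full(int(analyzed.sum()), 128)
    rgb[analyzed] = SLOPE_LUT[idx]
    rgb[slope_map.no_slope_mask] = SLOPE_LUT[0]  # darkest blue
    return RenderedMap(rgb=rgb, lo=lo, hi=hi, scale=scale_name)
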