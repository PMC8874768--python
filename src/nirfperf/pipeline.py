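"""End-to-end in-memory orchestration: stack + ROIs + zones -> assessment.

This is the library-level counterpart of ``nirfperf analyze``; the CLI is a
thin file-I/O wrapper around :func:`analyze_recording`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .core import CurveFeatures, FrameStack, PerfusionCurve, RoiSet, SlopeMap, rasterize_roi
from .curves import curve_features, extract_roi_curve
from .indicators import PerfusionAssessment, assess_perfusion
from .pixelmap import compute_slope_map
from .zones import Zone, ZoneStats, define_zones, zone_statistics


@dataclass
class AnalysisResult:
    curves: list[PerfusionCurve]
    features: list[CurveFeatures]
    slope_map: SlopeMap
    zones: list[Zone]
    zone_stats: list[ZoneStats]
    assessment: PerfusionAssessment


def muscle_union_mask(roi_set: RoiSet) -> np.ndarray:
    """Union of all rasterized muscle ROI masks."""
    h, w = roi_set.frame_shape
    mask = np.zeros((h, w), dtype=bool)
    for roi in roi_set.muscle_rois:
        mask |= rasterize_roi(roi, (h, w))
    return mask


def analyze_recording(
    stack: FrameStack,
    roi_set: RoiSet,
    zone_axis: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
    zones: Optional[list[Zone]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> AnalysisResult:
    """Run the full assessment on one recording.

    Zones come either from explicit masks or from a base/tip axis
    (``config.n_zones`` equal-length divisions over the muscle union mask);
    with neither, zone statistics are skipped.
    """
    curves = [extract_roi_curve(stack, roi, config) for roi in roi_set.rois]
    features = [curve_features(c, config) for c in curves]

    muscle_mask = muscle_union_mask(roi_set) if roi_set.muscle_rois else None
    slope_map = compute_slope_map(stack, muscle_mask, config)

    zone_list: list[Zone] = []
    zstats: list[ZoneStats] = []
    if zones is not None:
        zone_list = zones
    elif zone_axis is not None and muscle_mask is not None:
        zone_list = define_zones(muscle_mask, zone_axis[0], zone_axis[1], config.n_zones)
    if zone_list:
        zstats = zone_statistics(slope_map, zone_list, config)

    assessment = assess_perfusion(features, zstats, config)
    return AnalysisResult(
        curves=curves,
        features=features,
        slope_map=slope_map,
        zones=zone_list,
        zone_stats=zstats,
        assessment=assessment,
    )
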