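"""Aggregate perfusion indicators and the structured assessment.

The assessment freezes the qualitative impaired-perfusion pattern into
explicit boolean rules with configurable thresholds:

* ``egress_absent_any_roi`` — some muscle ROI fills (ingress) but never
  washes out (no egress): venous outflow impairment.
* ``ingress_absent_distal`` — some distal ROI (labels >=
  ``distal_start_label``) never fills: arterial inflow does not reach the
  tip.
* ``low_range`` — the most distal zone's slope_max range collapses below a
  fraction of the proximal zone's range; a narrow range in poorly perfused
  tissue lacks even the scattered high-slope vessels seen in viable flaps.

The summary reads ``impaired_perfusion_pattern`` iff at least one flag is
set; it deliberately describes a pattern, not an outcome prediction.  The
skin control ROI must itself show an ingress, otherwise the visualization
failed and the whole assessment is marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .core import CurveFeatures
from .zones import ZoneStats

ADEQUATE = "consistent_with_adequate_perfusion"
IMPAIRED = "impaired_perfusion_pattern"


@dataclass
class SlopeSummary:
    """Mean/max/min/SD of slope_max over muscle ROIs plus the proximal-to-
    distal distribution profile."""

    mean: float
    max: float
    min: float
    sd: float
    profile: list[tuple[str, float]]  # (label, slope_max), ROI order 1..10


@dataclass
class PerfusionAssessment:
    per_roi: list[CurveFeatures]
    slope_summary: SlopeSummary
    zone_stats: list[ZoneStats]
    flags: dict = field(default_factory=dict)
    summary: str = ADEQUATE
    valid: bool = True
    control_label: Optional[str] = None
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "summary": self.summary,
            "flags": dict(self.flags),
            "slope_max": {
                "mean": self.slope_summary.mean,
                "max": self.slope_summary.max,
                "min": self.slope_summary.min,
                "sd": self.slope_summary.sd,
                "profile": [[l, v] for l, v in self.slope_summary.profile],
            },
            "zones": [
                {
                    "zone": z.zone_index,
                    "max": z.max_slope,
                    "min": z.min_slope,
                    "mean": z.mean_slope,
                    "sd": z.sd_slope,
                    "range": z.range_slope,
                    "n_pixels": z.n_pixels,
                }
                for z in self.zone_stats
            ],
            "per_roi": [
                {
                    "label": f.roi_label,
                    "slope_max": f.slope_max,
                    "t_slope_max": f.t_slope_max,
                    "time_to_signal": f.time_to_signal,
                    "peak_intensity": f.peak_intensity,
                    "t_peak": f.t_peak,
                    "has_ingress": f.has_ingress,
                    "has_egress": f.has_egress,
                    "plateau_flag": f.plateau_flag,
                }
                for f in self.per_roi
            ],
            "thresholds": dict(self.thresholds),
        }


def _is_muscle_label(label: str) -> bool:
    try:
        int(label)
        return True
    except ValueError:
        return False


def summarize_roi_slopes(
    features: Sequence[CurveFeatures],
) -> SlopeSummary:
    """Population summary of slope_max over muscle ROIs, profile in
    proximal-to-distal label order."""
    muscle = sorted(
        (f for f in features if _is_muscle_label(f.roi_label)),
        key=lambda f: int(f.roi_label),
    )
    if not muscle:
        raise ValueError("no muscle ROIs to summarize")
    slopes = np.array([f.slope_max for f in muscle])
    return SlopeSummary(
        mean=float(slopes.mean()),
        max=float(slopes.max()),
        min=float(slopes.min()),
        sd=float(slopes.std()),  # population SD
        profile=[(f.roi_label, float(f.slope_max)) for f in muscle],
    )


def assess_perfusion(
    features: Sequence[CurveFeatures] | Mapping[str, CurveFeatures],
    zone_stats: Sequence[ZoneStats] = (),
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> PerfusionAssessment:
    """Combine curve features and zone statistics into the assessment.

    ``features`` covers all ROIs (muscle labels "1".."10" and the control);
    ``zone_stats`` is ordered proximal to distal.  Raises when the control
    ROI is missing while ``config.require_control`` is set.
    """
    if isinstance(features, Mapping):
        feats = list(features.values())
    else:
        feats = list(features)
    muscle = sorted(
        (f for f in feats if _is_muscle_label(f.roi_label)), key=lambda f: int(f.roi_label)
    )
    control = next((f for f in feats if f.roi_label == config.control_label), None)
    if control is None and config.require_control:
        raise ValueError(
            f"control ROI {config.control_label!r} missing and control checking is enabled"
        )

    summary_stats = summarize_roi_slopes(muscle)
    zone_stats = list(zone_stats)

    egress_absent = any(f.has_ingress and not f.has_egress for f in muscle)
    ingress_absent_distal = any(
        not f.has_ingress for f in muscle if int(f.roi_label) >= config.distal_start_label
    )
    low_range = False
    if len(zone_stats) >= 2:
        low_range = zone_stats[-1].range_slope < config.r_min_frac * zone_stats[0].range_slope

    flags = {
        "egress_absent_any_roi": bool(egress_absent),
        "ingress_absent_distal": bool(ingress_absent_distal),
        "low_range": bool(low_range),
    }
    valid = True if control is None else bool(control.has_ingress)
    return PerfusionAssessment(
        per_roi=muscle + ([control] if control is not None else []),
        slope_summary=summary_stats,
        zone_stats=zone_stats,
        flags=flags,
        summary=IMPAIRED if any(flags.values()) else ADEQUATE,
        valid=valid,
        control_label=None if control is None else control.roi_label,
        thresholds={
            "distal_start_label": config.distal_start_label,
            "r_min_frac": config.r_min_frac,
            "f_egress": config.f_egress,
            "d_egress_s": config.d_egress_s,
            "noise_floor_mult": config.noise_floor_mult,
            "range_rate_mult": config.range_rate_mult,
        },
    )
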