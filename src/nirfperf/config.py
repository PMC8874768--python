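"""Analysis configuration: every threshold in the pipeline, in one place.

All curve-, pixel- and assessment-level thresholds are named here with
units, so an analysis is fully specified by (recording, ROIs, zones,
AnalysisConfig).  ``config_hash`` is embedded in every report for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field


class AnalysisConfig(BaseModel):
    """Tunable parameters of the perfusion analysis.

    The defaults target bolus recordings sampled at ~2 Hz over ~2 min;
    every field is plain data so configs round-trip through YAML.
    """

    # -- curve preprocessing
    smoothing_window_s: float = Field(1.0, ge=0.0, description="centered moving-average window (s) applied before slope estimation")
    slope_window_s: float = Field(2.0, gt=0.0, description="sliding least-squares line-fit window (s) for the slope series")

    # -- baseline estimation
    baseline_min_samples: int = Field(5, ge=2, description="minimum number of baseline samples")
    baseline_onset_fraction: float = Field(0.05, gt=0.0, lt=1.0, description="provisional-onset threshold as a fraction of the curve's dynamic range")
    baseline_guard_s: float = Field(2.0, ge=0.0, description="guard interval subtracted before the provisional onset so the early rise cannot leak into the baseline")
    baseline_fallback_fraction: float = Field(0.10, gt=0.0, le=1.0, description="fallback baseline length as a fraction of the record when onset detection fails")

    # -- time to fluorescence signal
    k_sd: float = Field(3.0, gt=0.0, description="signal threshold in baseline SDs above baseline mean")
    min_consecutive: int = Field(3, ge=1, description="consecutive supra-threshold samples required to call a signal")

    # -- ingress / egress segmentation
    noise_floor_mult: float = Field(3.0, gt=0.0, description="ingress threshold multiplier on the empirical baseline noise-slope floor")
    range_rate_mult: float = Field(2.0, ge=0.0, description="ingress threshold multiplier on dynamic-range/duration (i/s)")
    f_egress: float = Field(0.1, gt=0.0, description="egress requires slope <= -f_egress * slope_max")
    d_egress_s: float = Field(5.0, gt=0.0, description="minimum sustained duration (s) of the egress slope condition")

    # -- pixel map
    theta_pixel: Optional[float] = Field(None, description="fixed no-slope threshold (i/s); None derives it per pixel exactly like the ROI ingress threshold")

    # -- zones and assessment
    n_zones: int = Field(4, ge=1, description="number of perfusion zones along the base-to-tip axis")
    include_no_slope_in_zones: bool = Field(True, description="include sub-threshold pixels in zone statistics")
    distal_start_label: int = Field(6, ge=1, description="first ROI label counted as distal")
    r_min_frac: float = Field(0.1, ge=0.0, description="low-range flag: most-distal zone range below this fraction of zone-1 range")
    control_label: str = Field("skin", description="label of the positive-control ROI")
    require_control: bool = Field(True, description="fail the assessment's validity when the control ROI shows no ingress")

    @property
    def config_hash(self) -> str:
        """Short stable hash of the full parameter set."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**(data or {}))


DEFAULT_CONFIG = AnalysisConfig()
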