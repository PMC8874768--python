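"""Per-ROI perfusion curves and curve-level perfusion indicators.

The pipeline for one ROI is: average the fluorescence over the ROI mask per
frame (perfusion curve), estimate a baseline window before bolus arrival,
smooth with a centered moving average, estimate the slope series by sliding
least-squares line fits, and from it derive slope_max, the ingress/egress
segmentation and the time to fluorescence signal.

All numerical kernels operate column-wise on a ``(T, P)`` array of P
parallel intensity series; the ROI path is the ``P = 1`` case of exactly
the code the per-pixel parametric map uses, so ROI/pixel agreement is
structural rather than numerical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .core import CurveFeatures, FrameStack, PerfusionCurve, Roi, rasterize_roi


@dataclass
class PhaseSegmentation:
    """Ingress/egress intervals of one curve (absent phases are None).

    ``plateau_flag`` marks curves that rise and then flatten without a
    sustained negative slope — the accumulation pattern of impaired venous
    outflow.
    """

    ingress_interval: Optional[tuple[float, float]]
    egress_interval: Optional[tuple[float, float]]
    plateau_flag: bool


# ---------------------------------------------------------------------------
# Column-wise numerical kernels (shared by ROI curves and the pixel map)


def _window_bounds(times: np.ndarray, half_width: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(times, times - half_width, side="left")
    hi = np.searchsorted(times, times + half_width, side="right")
    return lo, hi


def _padded_cumsum(y: np.ndarray) -> np.ndarray:
    out = np.zeros((y.shape[0] + 1,) + y.shape[1:], dtype=float)
    np.cumsum(y, axis=0, out=out[1:])
    return out


def moving_average_series(times: np.ndarray, y: np.ndarray, window_s: float) -> np.ndarray:
    """Centered moving average over a time window, column-wise on (T, P).

    Endpoints use truncated windows; ``window_s = 0`` is the identity.
    """
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    if window_s == 0:
        return y.astype(float, copy=True)
    if window_s > times[-1] - times[0]:
        raise ValueError("smoothing window longer than the record")
    lo, hi = _window_bounds(times, window_s / 2.0)
    s = _padded_cumsum(y)
    n = (hi - lo).astype(float)
    return (s[hi] - s[lo]) / n[(...,) + (None,) * (y.ndim - 1)]


def slope_series(times: np.ndarray, y: np.ndarray, window_s: float) -> np.ndarray:
    """Sliding-window least-squares slope at each sample, column-wise.

    At each sample the slope of the LS line through all samples within
    ``window_s / 2`` seconds of its time is returned (truncated at the
    record ends).  Centers whose window holds fewer than two samples yield
    NaN.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if window_s > times[-1] - times[0]:
        raise ValueError("curve shorter than the slope window")
    t = times - times[0]
    lo, hi = _window_bounds(times, window_s / 2.0)
    n = (hi - lo).astype(float)
    st = _padded_cumsum(t)
    stt = _padded_cumsum(t * t)
    sy = _padded_cumsum(y)
    sty = _padded_cumsum(t[(...,) + (None,) * (y.ndim - 1)] * y)
    ex = (...,) + (None,) * (y.ndim - 1)
    num = n[ex] * (sty[hi] - sty[lo]) - (st[hi] - st[lo])[ex] * (sy[hi] - sy[lo])
    den = n * (stt[hi] - stt[lo]) - (st[hi] - st[lo]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den[ex]
    out[(n < 2) | (den <= 0)] = np.nan
    return out


def max_with_earliest_tie(slopes: np.ndarray, times: np.ndarray):
    """(max slope, its time, its index) per column, NaN-aware, earliest tie wins."""
    filled = np.where(np.isnan(slopes), -np.inf, slopes)
    idx = np.argmax(filled, axis=0)  # argmax returns the first maximum
    smax = np.take_along_axis(filled, idx[None], axis=0)[0]
    return smax, times[idx], idx


def baseline_split(times: np.ndarray, y: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    """Number of baseline samples per column of a (T, P) series.

    The provisional bolus onset is the first sample above
    ``min + baseline_onset_fraction * range``; the baseline ends a guard
    interval before it so the early rise cannot inflate the baseline SD.
    When that leaves fewer than ``baseline_min_samples`` samples (late
    recording start, pure noise, constant curves) the fallback is the
    larger of the minimum and ``baseline_fallback_fraction`` of the record.
    """
    T = y.shape[0]
    ymin = y.min(axis=0)
    rng = y.max(axis=0) - ymin
    thresh = ymin + config.baseline_onset_fraction * rng
    above = y > thresh
    has_onset = above.any(axis=0) & (rng > 0)
    onset_idx = np.argmax(above, axis=0)
    t_end = times[onset_idx] - config.baseline_guard_s
    n_base = np.searchsorted(times, t_end, side="left").astype(int)
    fallback = max(
        config.baseline_min_samples, int(np.ceil(config.baseline_fallback_fraction * T))
    )
    fallback = min(fallback, T)
    n_base = np.where(has_onset & (n_base >= config.baseline_min_samples), n_base, fallback)
    return np.minimum(n_base, T)


def baseline_stats(y: np.ndarray, n_base: np.ndarray):
    """Population mean/SD of the first ``n_base`` samples per column."""
    s1 = _padded_cumsum(y)
    s2 = _padded_cumsum(y * y)
    n = n_base.astype(float)
    take = lambda s: np.take_along_axis(s, n_base[None], axis=0)[0] if y.ndim > 1 else s[n_base]
    m = take(s1) / n
    var = np.maximum(take(s2) / n - m * m, 0.0)
    return m, np.sqrt(var)


def noise_slope_floor(
    times: np.ndarray,
    slopes: np.ndarray,
    n_base: np.ndarray,
    baseline_sd: np.ndarray,
    config: AnalysisConfig,
) -> np.ndarray:
    """Empirical noise floor of the slope series, per column.

    The largest |slope| among slope centers whose window lies entirely
    inside the baseline; when no center qualifies, falls back to
    ``baseline_sd / slope_window_s``.
    """
    t_base_end = times[np.maximum(n_base - 1, 0)]
    ok = times[:, None] <= (t_base_end - config.slope_window_s / 2.0)[None, :]
    ok &= ~np.isnan(slopes)
    absl = np.where(ok, np.abs(slopes), -np.inf)
    floor = absl.max(axis=0)
    fallback = baseline_sd / config.slope_window_s
    return np.where(np.isfinite(floor), floor, fallback)


def ingress_threshold(
    times: np.ndarray,
    y: np.ndarray,
    floor: np.ndarray,
    config: AnalysisConfig,
) -> np.ndarray:
    """theta_in: minimum slope_max (i/s) for a credible ingress.

    The larger of ``noise_floor_mult`` times the empirical noise-slope
    floor and ``range_rate_mult`` times dynamic-range/duration.
    """
    duration = times[-1] - times[0]
    rate = (y.max(axis=0) - y.min(axis=0)) / duration
    return np.maximum(config.noise_floor_mult * floor, config.range_rate_mult * rate)


# ---------------------------------------------------------------------------
# Public per-curve operations


def extract_roi_curve(
    stack: FrameStack, roi: Roi, config: AnalysisConfig = DEFAULT_CONFIG
) -> PerfusionCurve:
    """Mean fluorescence over the ROI per frame, with baseline statistics."""
    mask = rasterize_roi(roi, stack.frame_shape)
    y = stack.frames[:, mask].mean(axis=1).astype(float)
    n_base = baseline_split(stack.timestamps, y[:, None], config)[0]
    m, sd = baseline_stats(y[:, None], np.array([n_base]))
    return PerfusionCurve(
        times=stack.timestamps.copy(),
        intensities=y,
        roi_label=roi.label,
        baseline_mean=float(m[0]),
        baseline_sd=float(sd[0]),
        baseline_n=int(n_base),
    )


def smooth_curve(curve: PerfusionCurve, window_s: float) -> PerfusionCurve:
    """Centered moving average of the curve over a time window.

    Times and baseline statistics (computed from the raw curve) are
    unchanged; ``window_s = 0`` returns an identical copy.
    """
    y = moving_average_series(curve.times, curve.intensities[:, None], window_s)[:, 0]
    return PerfusionCurve(
        times=curve.times.copy(),
        intensities=y,
        roi_label=curve.roi_label,
        baseline_mean=curve.baseline_mean,
        baseline_sd=curve.baseline_sd,
        baseline_n=curve.baseline_n,
    )


def time_to_signal(
    curve: PerfusionCurve, config: AnalysisConfig = DEFAULT_CONFIG
) -> Optional[float]:
    """Earliest time with ``min_consecutive`` samples above
    ``baseline_mean + k_sd * baseline_sd``; None if the signal never appears.
    """
    if curve.baseline_n < 2:
        raise ValueError("degenerate baseline: need >= 2 baseline samples")
    thresh = curve.baseline_mean + config.k_sd * curve.baseline_sd
    above = curve.intensities > thresh
    m = config.min_consecutive
    if m <= 1:
        hits = np.flatnonzero(above)
    else:
        run = np.convolve(above.astype(int), np.ones(m, dtype=int), mode="valid")
        hits = np.flatnonzero(run == m)
    if hits.size == 0:
        return None
    return float(curve.times[hits[0]])


def compute_slope_max(
    curve: PerfusionCurve, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[float, float]:
    """Maximum sliding-window least-squares slope of the curve and its time.

    The caller controls smoothing: the curve is differentiated as given.
    Ties in the maximum resolve to the earliest time.  Curves with no
    positive slope return their (<= 0) maximum so callers can threshold.
    """
    slopes = slope_series(curve.times, curve.intensities[:, None], config.slope_window_s)
    smax, tmax, _ = max_with_earliest_tie(slopes, curve.times)
    return float(smax[0]), float(tmax[0])


def _segment(curve: PerfusionCurve, config: AnalysisConfig):
    """Shared phase-segmentation core on an (already smoothed) curve."""
    t = curve.times
    y = curve.intensities
    slopes = slope_series(t, y[:, None], config.slope_window_s)[:, 0]
    smax_a, tmax_a, imax_a = max_with_earliest_tie(slopes[:, None], t)
    smax, t_smax, i_smax = float(smax_a[0]), float(tmax_a[0]), int(imax_a[0])

    floor = noise_slope_floor(
        t, slopes[:, None], np.array([curve.baseline_n]),
        np.array([curve.baseline_sd]), config,
    )[0]
    theta = float(ingress_threshold(t, y[:, None], np.array([floor]), config)[0])
    has_ingress = smax > theta

    seg = PhaseSegmentation(None, None, False)
    has_egress = False
    i_peak = int(np.argmax(y))
    if has_ingress:
        # walk back from the steepest point to where the slope first rose above theta
        i_start = i_smax
        while i_start > 0 and not np.isnan(slopes[i_start - 1]) and slopes[i_start - 1] > theta:
            i_start -= 1
        i_peak = i_start + int(np.argmax(y[i_start:]))
        seg.ingress_interval = (float(t[i_start]), float(t[i_peak]))

        post = slopes[i_peak:]
        neg = post <= -config.f_egress * smax
        # sustained: a consecutive run of qualifying samples spanning >= d_egress_s
        run_start = None
        for i, flag in enumerate(neg):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                if t[i_peak + i - 1] - t[i_peak + run_start] >= config.d_egress_s:
                    has_egress = True
                    break
                run_start = None
        if run_start is not None and not has_egress:
            if t[-1] - t[i_peak + run_start] >= config.d_egress_s:
                has_egress = True
        if has_egress:
            i_end = i_peak + int(np.flatnonzero(neg)[-1])
            seg.egress_interval = (float(t[i_peak]), float(t[i_end]))
        else:
            post_valid = post[~np.isnan(post)]
            sustained = t[-1] - t[i_peak] >= config.d_egress_s
            if sustained and post_valid.size and np.mean(np.abs(post_valid)) < config.f_egress * smax:
                seg.plateau_flag = True
    return seg, smax, t_smax, has_ingress, has_egress, theta, i_peak


def segment_phases(
    curve: PerfusionCurve, config: AnalysisConfig = DEFAULT_CONFIG
) -> PhaseSegmentation:
    """Ingress/egress segmentation of an (already smoothed) curve.

    Ingress is present iff slope_max exceeds theta_in; the peak is the
    global intensity maximum after ingress start; egress requires a
    sustained post-peak slope below ``-f_egress * slope_max`` for at least
    ``d_egress_s`` seconds.  Degenerate curves yield an all-absent
    segmentation.
    """
    return _segment(curve, config)[0]


def curve_features(
    curve: PerfusionCurve, config: AnalysisConfig = DEFAULT_CONFIG
) -> CurveFeatures:
    """Full indicator record for one raw ROI curve.

    Smoothing (``smoothing_window_s``) is applied before slope estimation
    and segmentation; the time to signal is detected on the raw curve
    against the baseline statistics.
    """
    smoothed = smooth_curve(curve, config.smoothing_window_s)
    seg, smax, t_smax, has_in, has_eg, _theta, i_peak = _segment(smoothed, config)
    tts = time_to_signal(curve, config)
    return CurveFeatures(
        slope_max=smax,
        t_slope_max=t_smax,
        time_to_signal=tts,
        peak_intensity=float(smoothed.intensities[i_peak]),
        t_peak=float(smoothed.times[i_peak]),
        has_ingress=bool(has_in),
        has_egress=bool(has_eg),
        plateau_flag=seg.plateau_flag,
        roi_label=curve.roi_label,
    )
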