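# Methods

## The measurement problem

Indocyanine green (ICG) binds plasma proteins after intravenous injection,
so its near-infrared fluorescence (NIRF) signal tracks blood. When a bolus
passes through tissue, the fluorescence intensity of a region rises steeply
(ingress, arterial inflow), peaks, and falls again as the dye washes out
(egress, venous outflow). A recording of a mobilized muscle flap therefore
contains, per region, a bolus-shaped *perfusion curve* — intensity in
relative units ("i") against time in seconds — whose shape and maximal
upslope carry information about perfusion that a single intensity snapshot
does not.

`nirfperf` quantifies such recordings at three spatial levels:

1. **ROI curves** — mean intensity per frame over each labeled region of
   interest (muscle ROIs "1".."10" ordered proximal base → distal tip, plus
   a "skin" positive control), with ingress/egress segmentation,
   `slope_max` (maximum upslope, i/s) and time to fluorescence signal.
2. **Pixel map** — `slope_max` of every pixel's time series, rendered with
   a fixed blue→red lookup table; pixels whose maximum slope stays below a
   noise-derived threshold are flagged "no slope".
3. **Zones** — the muscle mask partitioned into K (default 4) equal-length
   segments along the base→tip vascular axis, with per-zone
   max/min/mean/SD/range of the pixel `slope_max` values.

These feed a structured assessment with three boolean impaired-perfusion
flags (absent egress in any filling ROI, absent ingress distally, collapsed
distal slope range) and a summary label.

## Slope estimation

The slope series is obtained by a sliding-window least-squares line fit:
at each sample, all samples within `slope_window_s / 2` (default 2 s
windows) of its timestamp are fit by ordinary least squares and the fitted
slope is assigned to the center. This is robust to frame noise, exact for
straight lines regardless of window length, and its bias on smooth curves
is second order in the window width. Before differentiation the curve is
smoothed with a centered moving average (`smoothing_window_s`, default
1 s); endpoints use truncated windows. `slope_max` is the maximum of the
slope series; ties resolve to the earliest time.

The windowed estimator effectively convolves the true derivative with a
parabolic kernel, so its bias at the derivative's maximum is
`≈ (μ₂/2)·I'''(t*)/I'(t*)` with `μ₂ = window²/20` — under 1.5% of the true
maximum slope for the bolus shapes the simulator produces at its default
windows. This bound is verified, not assumed: see the oracle tests below.

All kernels (moving average, slope series, baseline statistics, thresholds)
operate column-wise on a `(T, P)` array of P parallel series using
prefix-sum identities. The ROI path is literally the `P = 1` case of the
code the pixel map runs over all pixels at once, so a one-pixel ROI and the
pixel map agree *bit-for-bit* — this structural identity is asserted over a
full 32×32×100 stack in the acceptance tests.

## Baseline, time to signal, phase segmentation

**Baseline.** Recording starts before injection, so the first part of every
curve is baseline. A provisional onset is the first sample above
`min + 5%` of the curve's dynamic range; the baseline window ends a 2 s
guard before that onset (so the early rise cannot inflate the baseline SD),
with a minimum of 5 samples and a fallback to the first 10% of the record
when detection fails (constant or pure-noise curves). Baseline mean and
population SD are stored on the curve.

**Time to fluorescence signal** is the earliest time at which the *raw*
curve exceeds `baseline_mean + k_sd·baseline_sd` (default k = 3) for at
least 3 consecutive samples; absent if it never does.

**Ingress** is declared when `slope_max` exceeds
`θ_in = max(3·noise_floor, 2·dynamic_range/duration)`, where the noise
floor is the largest |slope| observed at slope centers whose window lies
entirely inside the baseline (an empirical, per-curve noise measurement;
fallback `baseline_sd/slope_window` when the baseline holds no full
window). The dynamic-range term guards against declaring an ingress on a
curve whose total excursion is too small to matter.

**Egress** requires, after the peak (global intensity maximum following
ingress start), a slope ≤ `−0.1·slope_max` sustained over at least 5 s.
A curve with ingress, no egress, and small post-peak |slope| sets the
plateau flag — the accumulation pattern of impaired venous outflow. All
four constants (`θ_in` multipliers, `f_egress = 0.1`, `d_egress = 5 s`) are
config fields; the phases are only qualitatively defined in the clinical
literature, so these cutoffs are explicit package decisions surfaced in
every report.

## The assessment rules

- `egress_absent_any_roi` — some muscle ROI fills but never washes out.
- `ingress_absent_distal` — some ROI with label ≥ 6 (configurable) never
  fills.
- `low_range` — the most distal zone's `slope_max` range falls below 10%
  (configurable) of zone 1's range. Viable but poorly vascularized regions
  still contain scattered vessels that stretch the per-pixel range; its
  collapse is treated as an additional impairment signal.

`summary = impaired_perfusion_pattern` iff at least one flag is set. The
label deliberately names a *pattern*, not a predicted outcome: the rules
operationalize qualitative observations, and no calibrated diagnostic
threshold is claimed. The skin control must itself show ingress; otherwise
the visualization failed (dye never arrived, camera/occlusion problem) and
the whole assessment is marked invalid rather than interpreted.

## The simulator and its ground truth

The kinetic model is a gamma-variate first-pass bolus blended with a
retention term:

    I(t) = b + A·g(τ),                 τ = (t − t0)/tp ≤ 1
    I(t) = b + A·(w·g(τ) + 1 − w),     τ > 1
    g(τ) = τ^α · exp(α(1 − τ)),        g(1) = 1

flat at baseline `b` until arrival `t0`, peaking at `b + A` at `t0 + tp`,
decaying to `b + (1 − w)·A`. On the rising limb the maximum slope has the
closed form `(A/tp)·α·τ*^(α−1)(1 − τ*)·exp(α(1 − τ*))` at
`τ* = 1 − 1/√α`, which requires `α > 1` (at α = 1 the steepest point sits
exactly at arrival, below 1 it diverges — not physiological first-pass
shapes), so `KineticParams` enforces `alpha > 1`. The washout fraction `w`
never affects `slope_max`: the steepest slope lies before the peak.

Defaults: `t0 = 30 s` (within the clinically observed 28–55 s
time-to-signal span), `tp = 20 s`, `α = 2`, `A = 100 i`, `b = 5 i`,
`noise_sd = 1 i` (1% of peak amplitude), 48×64 frames at 2 Hz for 120 s.
These are plausible bolus kinetics, exposed in the config — not claims
about any clinical recording.

Spatial structure: a rectangular muscle band whose amplitude (hence slope)
is multiplied by a profile linear in the projection on the base→tip axis,
1.0 at the base → 0.4 at the tip, emulating decreasing vascularization
towards the tip; an independent skin patch (steeper, brighter kinetics) as
positive control; a static background; additive Gaussian sensor noise
clipped at zero, from a seeded generator (no global randomness). Video
synthesis evaluates one curve per unique parameter tuple through the same
scalar code path as `pixel_curve` and scatters it, so the noiseless video
reproduces `pixel_curve` exactly and generation stays fast.

Presets freeze the two phenotypes of interest: `successful_gmi` (gradient,
full washout, control present), `failed_gmi` (no egress anywhere in the
muscle, no ingress in the distal half — ≥ 40% of muscle pixels with true
`slope_max = 0`), and `control_only`. A second-bolus superposition exists
in `pixel_curve` for double-ingress curves but no preset uses it, since
the clinical cause of that shape is unexplained.

**What the simulator does not model:** tissue optics (depth-dependent
scattering/absorption), camera vignetting, motion, recirculation peaks,
Poisson photon statistics, and irregular ROI shapes drawn by hand. Passing
tests therefore demonstrate that the *estimators recover known kinetics
under additive noise and the stated geometry* — not that the pipeline is
validated on clinical recordings.

## Numerical and degenerate-input choices

- Pixel (i, j) has center (i+0.5, j+0.5); polygons rasterize by the
  even-odd rule on pixel centers with a fixed half-open boundary
  convention, so adjacent ROIs sharing an edge get disjoint masks.
- Slope LS sums use prefix sums on times rebased to the record start;
  windows with < 2 samples or zero time spread yield NaN and are ignored
  in the maximum.
- Constant curves: no onset → baseline falls back to the record head;
  `slope_max = 0`, no ingress (strict inequality against θ_in ≥ 0), no
  signal time, all phases absent.
- Zone statistics use population SD (divisor n) and *include* no-slope
  pixels by default — their low values carry the impairment signal that
  drives the range flag; `include_no_slope_in_zones = False` excludes them.
- Rendering: fixed 256-entry blue→red LUT shipped in code; no-slope pixels
  forced to the darkest blue, non-analyzed pixels black; a constant map
  under min-max anchoring renders mid-scale with a warning.
- Reports contain no wall-clock timestamps; identical inputs and config
  give byte-identical JSON/CSV/TIFF/PNG outputs (verified in tests).

## Problem sizes used in the verification suite

The shipped tests and `scripts/acceptance.py` run at the preset recording
size (48×64 px, 240 frames), 50–100 seeded replicates per recovery study,
50 randomized kinetic parameter draws against the finite-difference oracle
(10⁴-point grids), and a 32×32×100 stack for the exhaustive pixel↔ROI
identity — sizes chosen so the whole verification runs on a laptop-class
single core in a few minutes while keeping every statistical criterion at
its stated replicate count.

## Known limitations

- Thresholds (θ_in multipliers, egress constants, low-range fraction) are
  package decisions; clinical sources define the phases only qualitatively.
  They are all config-exposed and echoed in every report.
- Zone geometry is an equal-length axis-projection partition; hand-drawn
  anatomic zones can be supplied as explicit masks instead.
- No motion correction: the pipeline assumes a static field of view.
- The assessment is a pattern detector, not an outcome classifier; no
  diagnostic performance is claimed or claimable from synthetic data.
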