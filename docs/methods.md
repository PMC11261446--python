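# Methods

This note records the models the package implements, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Physical model

**Capsule mass balance.** With dry supply air (C_in = 0) the
evaporation rate is ṁe = Q̇·C_out. Units follow physiology practice —
Q̇ in L·min⁻¹, concentrations in g·m⁻³, rates in mg·min⁻¹ — because
the conversion factors cancel exactly; all internal SI math happens at
module boundaries. Negative rates (C_out < C_in) are reported and
flagged, never clipped: condensation is physically meaningful.

**Isothermal-film mass transfer.** When a fraction ω of the exposed
area A_total is wet, ṁe″ = ω·h_m·(C_sat(T_sur) − C∞). The regional
slope dṁe″/dω = h_m·C_sat(T_sur) is the mode separator: fitted over a
user-specified dropwise window and a filmwise window, the slope ratio
is the ratio of mass transfer coefficients. Mode windows are explicit
configuration, not auto-detected — mode boundaries are evident to an
analyst from the video but not robustly classifiable from the area
series alone. T_sur defaults to 34 °C, the average film surface
temperature observed in MWIR; the same value is used for both modes.

**Saturation concentration.** Arden Buck's correlation over liquid
water divided by R_v·T (R_v = 461.52 J·kg⁻¹·K⁻¹). Buck and
Magnus agree within 1% over 0–50 °C (unit-tested); either is far more
accurate than the ±2% the analysis needs. Valid range −20…60 °C,
enforced.

**Latent heat and thermal circuit.** Mass flux converts to heat flux
with h_fg = 2430 kJ·kg⁻¹ (near 30 °C, configurable); 2 mg·min⁻¹·cm⁻²
is 810 W·m⁻². A film of thickness L carrying that flux sustains
ΔT = q″·L/k with k = 0.60 W·m⁻¹·K⁻¹ for water near skin temperature:
2.7 °C across 2 mm, 0.081 °C across 60 μm (the latter is sometimes
quoted rounded down to ~0.07 °C; the formula value is used here).
This is why puddle thickness maps onto MWIR surface-temperature
contrast.

**Lewis analogy and equivalent winds.** h̄_m = 0.00091·h̄_t links the
mass and heat transfer coefficients; with the head-averaged
correlation h̄_t = 6.1·V^0.5 the film model inverts to
V = [ṁe″/(ω·0.00091·6.1·ΔC)]². The flat-plate counterpart inverts
Nu = 0.664·Re^(1/2)·Pr^(1/3) with air properties at a ~30 °C film
temperature (k = 0.026 W·m⁻¹·K⁻¹, ν = 1.6×10⁻⁵ m²·s⁻¹, Pr = 0.71,
configurable): the same h̄_t ≈ 17.8 W·m⁻²·K⁻¹ that means an 8.5 m·s⁻¹
head wind corresponds to only ~0.3 m·s⁻¹ over a 1.5 cm plate, because
boundary layers over the short exposed patch are thin.

**Uncertainty.** U_sys = √(Q̇²·U_C² + C_out²·U_Q̇²) with instrument
defaults U_C = 0.18 g·m⁻³ (probe spec) and
U_Q̇ = max(0.1% full scale, 0.6% reading) (controller spec);
U_rand = t_{(1+c)/2, n−1}·σ computed from the Student-t quantile, not
a table (4.303 emerges for n = 3 at 95%); U_total is the
root-sum-square.

## Imaging pipeline

**Stabilization.** Translation-only registration by the
cross-correlation peak, subpixel via Fourier upsampling (factor 20).
Three preprocessing steps make it robust on sweating skin, where the
wet features move, grow and vanish while the camera shakes: (i) each
frame is clipped below its median — sweat is dark, so this strips the
moving features while keeping bright static structure; pixels within
8 px of any below-median pixel are zeroed as well, because the wet
*boundary* is itself a moving edge; (ii) a 1–5 px band-pass leaves the
sharp static skin lines whose narrow autocorrelation pins the peak at
the true displacement regardless of which subset remains visible;
(iii) a Tukey(0.25) taper suppresses wrap-around edge bias, and plain
(magnitude-weighted) rather than phase-normalized correlation keeps
broadband sensor noise from dominating. The reference frame defaults
to the coldest (most wet-covered) frame: its surviving dry anchors are
visible in every other frame. Two refinements exploit that breathing
shake is temporally smooth: offsets far (>1 px) from the
median-filtered trajectory are re-registered after pre-alignment at
the smooth prediction, and the final trajectory is Savitzky–Golay
smoothed (window 9, order 2; disable with `smooth_window=0`).
Validated to <0.5 px RMS against injected ±3 px sinusoidal shake.

**Thresholding.** Wet = cold = dark = strictly below the local
threshold, everywhere. Phansalkar:
t = m·(1 + p·e^(−q·m) + k·(s/r − 1)) with the reference defaults
k = 0.25, r = 0.5, p = 2, q = 10 over a square (2·radius+1)² window,
mirror padded; images must be normalized to [0, 1] (the exponential
term is scale-dependent, and it also means a low-contrast feature is
only detectable against a dark background — the normalization
convention puts sweat at the bottom of the range). Mid-grey:
t = (local max + local min)/2. Square windows are the contract; a
brute-force per-pixel windowed oracle in the test suite defines both
operators exactly and the production path (uniform/extrema filters)
must match it bit for bit.

Two opt-in robustness knobs extend mid-grey for textured scenes, both
off by default so the plain operator remains the contract: a greyscale
opening that flattens bright structures thinner than its element
(warm crevice lines otherwise inflate the local midrange), and a
minimum-contrast guard evaluated on a noise-suppressed (σ = 2) copy —
the raw windowed range over ~5000 pixels is dominated by single-pixel
noise extremes, so the guard must measure structural contrast.

**Refinement.** Ordered morphological ops (any of close, dilate,
erode, fill_holes; 3×3 elements) then a Gaussian blur of the 0/1 mask
(radius 2 px) followed by a single global re-threshold back to binary.
Isolated single-pixel detections do not survive the blur; 1-px holes
close. The calibrated presets are `dropwise` (Phansalkar r20,
close + dilate, re-threshold 0.70) and `filmwise` (mid-grey r35,
opening 2 px, contrast guard 0.15, close + dilate×2 + fill_holes,
re-threshold 0.5). The re-threshold levels were calibrated once
against synthetic truth masks so that the dilation used for smoothing
does not bias the recovered wet area; hole-filling substitutes for
the manual interior edits an interactive workflow needs where the
mid-grey window cannot see a puddle interior. Scriptable per-frame
rectangular mask overrides (each one logged) replace any remaining
manual edits so runs stay reproducible.

**Wet series.** A_wet = wet-pixel count × pitch²; ω = A_wet/A_total.
A_total defaults to the imaged field of view, or the 1.93 cm² capsule
window when configured.

## Event tracking

Events are 26-connected components of the binary (x, y, t) volume
(time as the third axis); per-frame 2D analysis uses 8-connectivity.
Events spanning ≤ 2 frames are noise-filtered (configurable), which on
synthetic scenes changes the per-frame wet area by well under 2%.
Metrics: maximum per-frame area, equivalent diameter √(4A/π), duration
from the frame span. Pore identity is greedy centroid clustering
(radius 0.3 mm default, configurable) — adequate because real pores
repel and rarely sit closer than ~0.45 mm; per-pore cycle periods are
inter-onset intervals, pooled. The area-vs-count regression is plain
OLS; the moving average of active counts is centered with truncated
edges.

## Synthetic generator

The generator defines the conditions every recovery test runs under.

* **Geometry/camera:** 26.7 μm/px, 10 Hz, 16-bit gray; defaults
  640×512 px (tests use smaller patches). Temperature maps linearly to
  gray at 20 levels/°C (0.05 °C per level; no radiometric calibration
  is claimed). Optical blur σ = 0.8 px reflects the ~15 μm optical
  resolution relative to the pixel pitch. Additive Gaussian noise
  (σ = 2 gray) and optional sinusoidal two-axis frame shake with the
  injected offsets recorded in the truth.
* **Skin background:** a static smooth random field (σ = 5 gray,
  correlation scale 200 px — a broad temperature gradient) plus ~40
  bright 2-px crevice lines (+10 gray). The lines are the stationary
  anchors stabilization needs and, being warm, cannot masquerade as
  sweat. The smooth-field scale is deliberately larger than the
  threshold windows: a cold skin patch at the window scale is
  physically indistinguishable from a thin film for a local-threshold
  method (the situation hand edits addressed in interactive practice),
  so it is not part of the default test conditions.
* **Dropwise dynamics:** pores at 185 cm⁻² (Poisson with a 0.45 mm
  hard core — real pores repel; a bare Poisson scatter produces
  sub-cluster-radius pairs real skin does not show), firing with
  periods 1.5 + 11.5·Beta(2, 2.8935) s (range 1.5–13 s, mean exactly
  6.2 s), maximum diameters log-normal (σ = 0.45, μ set so the 95th
  percentile is 0.7 mm, clipped to 0.08–1.5 mm). Each firing is a flat
  cold disk (contrast 1 °C — the camera sees the 2D projection of the
  cooled cap) whose radius follows a symmetric triangle between
  0.25·peak and peak; no growth law is reported for real droplets, so
  the triangle is a modeling choice, with the analytic
  E[profile²] = 0.4375 feeding the expected area per active droplet
  used by slope-recovery tests. Event durations scale with √diameter
  (larger droplets last longer), capped at 0.9 of the period. An
  optional linear onset ramp activates pores gradually.
* **Filmwise dynamics:** puddles as lobed unions of disks on a
  jittered 1.8 mm grid (so they spread without merging), radii growing
  as √t, one thickness per puddle; the rendered contrast is the
  thermal-circuit ΔT at the configured heat flux, so thick puddles are
  dark and 60-μm films nearly invisible — as in reality. Optional
  crevice polylines (2 px wide) darken at their fill time.
* **Probe chain:** steady outlet concentration flux×area/Q̇ with two
  cascaded first-order lags — capsule mixing (default 90 s, free
  parameter) and probe response (7.5 s, instrument spec 5–10 s) — so
  flow steps relax exponentially with τ ≈ 1.5 min.

Same seed ⇒ bit-identical output (tested). What the generator does
*not* emulate: radiometric IR physics (emissivity, reflections,
absorption by droplet sides), skin micro-texture beyond crevice lines,
droplet coalescence, non-translational camera motion, probe
calibration drift. Passing recovery tests therefore demonstrate the
analysis machinery, under realistic statistics and camera artifacts —
not performance on arbitrary real-world footage, where threshold
parameters and mask overrides need per-dataset judgment exactly as in
interactive practice.

## Validation experiments and problem sizes

The end-to-end check generates a 256×256 px, 120 s dropwise scene and
an equal filmwise scene (≈2400 frames total), renders, stabilizes,
thresholds and extracts ω, pairs it with film-model fluxes at a 3×
true h_m ratio (2% noise), and requires the fitted slope ratio within
15%. Droplet statistics use a 192×192 px, 600 s truth-mask scene
(several thousand events): 95th-percentile diameter and mean period
within 10%, area-per-droplet slope within 15% of the generator's
analytic expectation. These sizes keep the full suite and the
acceptance script within a few minutes on one CPU while leaving
thousands of events for the distributional checks. When the probe
path is part of an analysis (CLI runs), the measured wet fraction is
passed through the same first-order response as the probe signal
before slope fitting — filtering both variables with one linear kernel
preserves their proportionality and removes the lag/attenuation bias
of regressing a slow signal on a fast one; windows also skip a few
lag constants after a mode transition.

## Known limitations

* Mid-grey segmentation cannot see the interior of a uniform puddle
  wider than its window; hole-filling recovers enclosed interiors but
  a puddle merged beyond ~2 window diameters would need overrides.
* The decay fit assumes a single dominant time constant; the cascaded
  capsule+probe response is only approximately single-exponential
  (the fitted τ lands near the slower constant).
* Pore clustering by centroid radius can split a pore whose droplets
  wander farther than the cluster radius, or merge pores closer than
  it; the defaults match the generator's hard-core spacing.
* Stabilization assumes pure translation; rotation or non-rigid skin
  deformation is out of scope.
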