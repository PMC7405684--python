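# Methods

This note documents the models implemented in `retphen`, the defaults
and numerical choices that matter, what the synthetic generators do and
do not emulate, and the known limitations.

## Vessel caliber

### Model of the measurement

A vessel's caliber is estimated from the *ensemble* of brightness
profiles sampled perpendicular to its centerline. The pipeline is, in
order:

1. **Thinning.** The input polyline (manually traced in practice) is
   rasterized to a single-pixel 8-connected chain by sampling the
   polyline at 0.25-px arc steps and rounding each sample to its pixel.
   Every chain pixel therefore lies within √2/2 ≈ 0.707 px of the
   continuous trace. (Rounding polyline vertices first and then drawing
   Bresenham segments — the more obvious construction — can place chain
   pixels up to ~0.75 px away, because vertex rounding and segment
   rasterization errors add.)
2. **Thickening.** The chain is dilated to a mask of all pixels within
   `dilate_radius_px` (default 2× the nominal vessel half-width) so the
   mask generously covers the vessel plus local background.
3. **Brightness normalization.** The histogram (64 bins, lightly
   smoothed with a [¼ ½ ¼] kernel) of under-mask pixels is bimodal:
   lower mode = background, upper mode = vessel. Each mode is refined to
   the mean of the pixels in its bin, and the image is mapped affinely
   so background → 0 and vessel → 1. Plateau ties in the histogram are
   broken toward the extremes. A unimodal histogram ("no vessel
   contrast") is an error. For dark-vessel (bright-field) images a
   config flag inverts polarity first. For Gaussian-like cross sections
   the upper mode exists because the brightness density diverges at the
   profile peak (fold of the smooth maximum), so the same estimator
   serves both profile families.
4. **Tangents.** The chain is resampled uniformly in arc length (1-px
   spacing) and each coordinate is differentiated with a local-quadratic
   Savitzky–Golay filter (half-window 7 px). Arc-length resampling
   matters: diagonal chain steps are √2 long, so index-parametrized
   windows are arc-asymmetric and bias the tangent by several degrees on
   curved vessels. The quadratic fit keeps the estimate accurate at
   chain ends, where the fit window is one-sided. A plain moving-average
   + central-difference scheme was measurably worse (circle-tangent
   error up to 0.09 versus 0.04 in |tangent·radial|).
5. **Perpendicular slices.** Brightness is sampled along the normal
   through every chain pixel at 0.25-px steps over signed offsets
   ±`half_length_px` (default 3× nominal half-width), with bilinear
   interpolation. Profiles whose support leaves the image are dropped.
6. **Reference-circle clipping.** Only slices whose chain point lies
   strictly inside the reference circle are pooled (points exactly on
   the circle are excluded — a measure-zero tie-break). The circle
   diameter follows the age convention (1.72 mm at P6, 2.05 mm at P9).
7. **Ensemble average.** Pointwise mean over the pooled profiles;
   requires at least `min_slices` (default 20). Pooling dilutes the
   effect of side branches that cross individual slices.
8. **Mid-brightness width.** The local background is the mean of the
   outer 20 % of offsets, the peak is the profile maximum, and the
   mid-brightness level is their midpoint. The width is the distance
   between the linearly interpolated crossings of that level flanking
   the lobe containing the global peak (other lobes trigger a warning).
   Width in µm = width in px × pixel scale.

This definition of "mid-brightness" — midpoint of (local background,
peak) of the ensemble — is invariant to affine intensity transforms and
well-defined for both plateau-like and Gaussian cross sections, for
which it reads the FWHM.

**Invariances.** Width in pixels is independent of the µm/px scale;
affine intensity maps (gain > 0, any offset) leave widths unchanged
exactly in real arithmetic. In floating point the histogram bin edges
round differently under a general affine map, so widths agree to
~1e-9 relative; under a power-of-two gain with zero offset the
arithmetic is exactly scaled and the result is bit-identical.

**Accuracy.** On noiseless rectangular-profile vessels of widths 6–24 px
at orientations 0–90°, the absolute error is ≤ 0.13 px; a single
measurement carries a subpixel-phase quantization of up to ~0.2 px
(the ramp of a box-downsampled edge is sampled at 0.25-px steps), which
averages out over vessels placed at random subpixel positions.

### Summaries and auxiliary metrics

Per retina: arithmetic mean width and count per class (arteriole /
venule); a class with no vessels has count 0 and an *absent* mean.
Per mouse: means of retina-level values when two retinas exist.
Tortuosity is arc length over chord length (≥ 1). Fractal dimension is
the least-squares slope of log N(ε) vs log(1/ε) over dyadic box sizes
capped at a quarter of the pattern span — larger boxes are dominated by
boundary quantization and bias the slope (a filled square reads 1.94
instead of 2.00 if half-span boxes are included). Both are standard
formulations and are **not** numerically interchangeable with
commercial graders' (e.g. SIVA's) unpublished definitions.

## ERG analysis

### Feature definitions

All times are measured from flash onset; the baseline is the mean
voltage over the 50 ms before the flash. The A-wave amplitude is
baseline minus the most negative sample in a 5–60 ms search window
(floored at 0 when nothing dips below baseline, with the peak time
reported absent). The B-wave amplitude is the most positive sample
(search to 200 ms) minus the A-trough voltage; for weak flashes without
an A-trough it is measured from baseline — the trough-referenced rule is
undefined there. All windows are configurable (`ErgConfig`).

### Naka–Rushton fit

`V(I) = Vmax·I^n/(I^n + K^n)` is fitted by bounded least squares on
linear intensity to the B-wave amplitudes inside the configured range
(default −3.8 … 1.0 log cd·s/m²; at least 4 points spanning ≥ 2 log
units required). `n` is fixed at 1 unless `nr_free_n`. A 7-point
log-spaced multi-start grid on K over the observed intensity range
guards against local minima; solver tolerances are 1e-12. `K` is
reported in log₁₀ units, and `V(K) = Vmax/2` holds identically for any
fitted `n`. With `n = 1` the small-intensity limit is linear in I,
recovering the classic dim-flash regime. Monte-Carlo recovery at
σ = 10 µV noise on a 17-point grid: median relative error ~0.6 % for
Vmax and ~4 % for K.

### Lamb–Pugh activation fit

The A-wave leading edge is modeled as
`R(t; I) = R_max·(1 − exp(−½·(I/I_ref)·((t − t_d)/t_c)²))` for t > t_d,
0 otherwise, with `I_ref = 1 cd·s/m²`. `R_max` is fixed at the maximal
A-wave amplitude recorded across the usable traces; `t_c` (transduction
time constant) and `t_d` (transduction delay) are free and shared
across intensities (fit traces one at a time for per-intensity
parameters). Each trace contributes samples from onset to 80 % of its
A-trough time (configurable), over the default intensity range
−1.1 … 2.2 log cd·s/m². Multi-start over t_d ∈ {0,3,…,15} ms ×
t_c ∈ {5,20,60} ms; a fitted delay reaching the earliest trough time is
rejected. Noiseless recovery is exact to solver tolerance; at σ = 5 µV
the median delay error is ~0.1 ms.

The exact algebraic form of published "modified" activation models
varies; the form above is isolated in `lamb_pugh_model` so an
alternative parameterization can be swapped in one place.

### Oscillatory potentials

The analysis window runs from flash onset to 50 ms past the B-wave
peak. The windowed segment is mean-subtracted, tapered with a Tukey
window (α = 0.5), transformed with an FFT, bins outside the band
(default 60–235 Hz, configurable; a convention, not a published value)
are zeroed symmetrically, and the inverse transform gives the OP
waveform whose peak-to-peak excursion is the OP magnitude. The taper
fraction matters: the B-wave is still ~⅓ of its peak at the window edge,
and a short taper (α = 0.2) leaks ~9 % of the bump's amplitude into the
band, versus 0.7 % at α = 0.5 — while the packet, centered on the
B-wave rising phase, sits in the taper's flat region and keeps its
amplitude. Pass-band sinusoids are recovered to ~0.5 %; a 40 µV packet
injected into the full composite waveform is recovered within ~4 %.

### Protocol builders

Intensity grids are enumerated inclusively from (start, stop, step).
The dark-adapted range −4.7 … 1.0 log cd·s/m² at 0.3-log steps yields
20 grid points; published protocol descriptions sometimes quote 19 for
this range, so the builder attaches a note rather than silently dropping
a point. Interstimulus intervals follow the two-range rule (0.7 s up to
−2.0, 10 s from −1.7; 10 s throughout photopic).

## OCT layer thickness

Boundaries are inputs (segmented upstream); no image processing is
done. Thickness is the depth difference between a layer's bounding
curves, measured along the A-scan axis (not boundary-normal — the
convention of clinical segmentation tools), with linear interpolation
between lateral grid samples, at ±{100, 200, 300, 400} µm from the
*disc center* (the reference point is named explicitly in the data
model so the convention is auditable). Layer map: total = ILM→RPE,
inner = ILM→OPL, outer = OPL→RPE, RNFGC = ILM→RNFGC/IPL,
IPL = RNFGC/IPL→IPL/INL, INL = IPL/INL→OPL, RNFGC+IPL = ILM→IPL/INL.
Because layers share boundaries, total = inner + outer and
RNFGC+IPL = RNFGC + IPL hold exactly (to float rounding) at every
offset. RNFL and GCL are never separated (their OCT reflectance
boundaries are indistinct); the ELM boundary is carried in the data
model but unused by the seven reported layers. Strict depth ordering
ILM < RNFGC/IPL < IPL/INL < OPL < ELM < RPE is validated at every grid
point on construction.

A small utility converts an axial-length resolution limit to its
refractive-error equivalent (80 µm at 6.5 µm per dioptre ≈ 12 D),
useful for bounding what eye-length differences an MRI protocol could
have detected.

## Synthetic data generators

The generators exist so that every analysis stage has inputs with
analytically known answers; they emulate structure, not realism.

**Vessel images.** Vessels are rendered by 4× supersampled
rasterization (exact point-to-segment distances on the subpixel grid)
followed by box downsampling, so "true width" is meaningful at subpixel
precision. Cross sections are rectangular (sharp-walled) or Gaussian
(FWHM = true width, σ = FWHM/(2√(2 ln 2))). Background is constant plus
an optional linear gradient; noise is white Gaussian. Defaults:
256×256 px at 2 µm/px, background 100, vessel contrast 80 — typical of
fluorescence flat-mount tiles. Not emulated: out-of-focus blur, tile
stitching seams, capillary meshwork, staining inhomogeneity, curved
branching morphology. Passing width-recovery tests therefore shows
correctness of the geometry/brightness pipeline, not robustness to
every flat-mount artifact.

**ERG waveforms.** voltage(t) = −P3(t) + B(t) + OP(t) + noise, with P3
the Lamb–Pugh form above, B a unit-peak log-normal-shaped bump (default
peak 60 ms, width 60 ms) scaled by the Naka–Rushton amplitude at the
flash intensity (defaults R_max 300 µV, t_c 18 ms, t_d 4 ms, Vmax
400 µV, K 0.01 cd·s/m², n 1 — magnitudes typical of dark-adapted mouse
recordings), and OP a Gaussian-windowed 120 Hz sinusoid (σ 10 ms, 40 µV
peak-to-peak) centered at 60 % of the B-peak time, i.e. on the B-wave
rising phase. The B template is chosen for smoothness and spectral
separation from the OP band (its energy lies below ~30 Hz), with no
claim of physiological fidelity. Sampling 2 kHz, 60 ms prestimulus
baseline, 400 ms sweeps, white Gaussian noise per sweep. Two deliberate
simplifications: P3 saturates rather than recovering (so trough-to-peak
B-amplitudes at intermediate intensities are reduced by the still-rising
P3 — as in real recordings — and only match the injected Naka–Rushton
amplitude once P3 saturates before the trough), and the OP packet
amplitude is intensity-independent.

**OCT geometry.** Each boundary depth is a polynomial in lateral
position (relative to the disc, in mm); layer thicknesses at the eight
offsets have closed forms. `random_oct_spec` draws random
strictly-ordered constants and bounds the linear/quadratic perturbation
budget by a fraction of the smallest inter-boundary gap, guaranteeing
non-crossing curves by construction.

All generators are deterministic given (spec, seed); per-intensity ERG
noise streams are derived with `SeedSequence([seed, intensity_index])`.

## Study pipeline

The manifest (CSV) lists one row per (animal, modality, eye/retina).
Eyes/retinas are averaged within animal *before* grouping, so each
animal contributes one value per measure; group cells report n, mean,
and SEM = sd/√n (ddof 1), with SEM absent for n = 1. Outputs are
deterministic given inputs and config, and invariant to manifest row
order. Rows with missing or unparseable files are logged as errors and
skipped; the run continues. The config (YAML) is echoed into `run.log`.
Inferential statistics are intentionally not implemented.

## Known limitations

- Vessel widths below ~4 px are at the edge of what 0.25-px profile
  sampling resolves; the pipeline reports them but the subpixel-phase
  quantization (~0.2 px) becomes a larger relative error.
- The brightness normalizer assumes one vessel population under the
  mask; two vessels of very different brightness under the same mask
  can merge modes.
- The Lamb–Pugh fit requires detectable A-troughs; purely photopic
  series without A-waves return no activation fit (by design).
- Tortuosity and fractal dimension are stand-ins for proprietary
  grader metrics and will not match their absolute values.
- OCT lateral positions are taken at face value; no axial-length
  correction of lateral scaling is applied.
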