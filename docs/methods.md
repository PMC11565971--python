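# Methods

This note documents the models and procedures thalamap implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Coordinate conventions

All interfaces use physical micrometres, never pixels; pixel pitch and
section thickness metadata do the conversion at I/O. Points are
`(ap, dv, ml)` triples: AP increases posteriorly, DV ventrally, ML is
signed with the midline at 0. A cell annotated on section *i* has
`ap = i × section_thickness_um` (40 μm by default, matching the
acquisition protocol the pipeline is built for; cell-counting images are
0.454 μm/px). Atlas voxels sit at `μm = index × voxel_um` (10 μm), with
the ML axis centred on the volume.

## Registration chain

The atlas is mapped onto each experimental brain by six global affine
steps fitted in a fixed order, then a per-slice correction:

1. **Midline affine** — least-squares affine over the four non-SCO
   midline fiducials (corpus callosum anterior/posterior, anterior
   commissure posterior, dentate gyrus anterior). These landmarks vary
   along AP and DV only, so the default fit (`axes_mode="ap_dv"`) is a
   planar affine in the midsagittal plane with ML untouched; four point
   pairs over six parameters leave residual freedom that is reported per
   fit. A literal `axes_mode="ap_ml"` is also provided; with midline
   fiducials its ML column is degenerate and the fit reduces to a 1D
   AP affine, which is handled explicitly rather than erroring.
2. **A–P shear** — `ap' = ap + s·ml`, with `s` the joint least-squares
   solution over both lateral landmark pairs (stria terminalis, lateral
   geniculate posterior); disagreeing pairs are averaged by the normal
   equations. With signed ML the coefficient's sign follows the
   left-negative convention.
3. **SCO anchor** — a translation placing the transformed source SCO at
   the origin; the target SCO is kept aside and restored as the final
   translation, so the scaling steps act in an SCO-centred frame on both
   sides.
4. **A–P scale** — the ratio of the lengths containing 99% of the
   bounding-box volume between the anterior pole and the SCO. The box
   area profile is piecewise constant (each annotated box extruded over
   one section thickness, overlaps split at midpoints), so the
   cumulative volume is piecewise linear and the quantile position is
   solved in closed form rather than on a grid. Whether "99% of the
   volume" means this quantile length or a volume-matching criterion is
   ambiguous; the quantile reading is implemented and flagged here.
5. **M–L scale** and 6. **D–V scale** — ratios of mean box width and
   height over boxes within ±1 mm (AP) of the SCO.
7. **Per-slice drift** — for each annotated section, the (ML, DV)
   translation moving the dorsomedial corner of the transformed
   registration volume at that AP plane onto the annotated box's corner.
   Translation-only by design: the correction targets translational
   drift in serial-section alignment, and a translation preserves
   within-slice geometry. Sections without an annotated box inherit the
   nearest annotated section's correction (drift is smooth); sections
   whose plane misses the transformed volume get zero correction and a
   warning.

Cell transfer to atlas space applies the inverse: undo the per-slice
term for the cell's own section, then invert the composed global map.

Two properties of the fit are worth knowing. First, the four-point
step-1 fit is exact on consistent data, so it absorbs whatever AP/DV
scaling the data carry, leaving steps 4 and 6 near 1; the *composition*
recovers the true map, and `AffineChain.effective_params` reports
scale/shear/translation read off the composed matrix, which is the
meaningful parameterization. Second, a sectioned brain's anterior volume
pole is only known to ±half a section thickness, which bounds AP-scale
accuracy at roughly `(thickness/2) / L` with `L` the anterior-pole-to-
SCO distance — about 0.5–1% at realistic geometry (L ≈ 2–2.5 mm, 40 μm
sections). This is a property of sectioning, not of the fitter; the
residual appears as a small AP offset that per-slice correction (ML/DV
only) cannot remove.

Boxes are carried through chain matrices by mapping their AP and DV
bounds at the midline and their ML bounds through the ML row; this is
exact for the chain family (no DV↔ML mixing, ML→AP coupling only via
the shear, which vanishes on the midline where boxes are anchored).

## Cell mapping

- **Level balancing**: each section is multiplied by one global factor
  bringing its background estimate to the stack mean; the default
  estimator is the mean of the dimmest quartile of pixels
  (scale-equivariant, so ratios are exact). No local adjustment is ever
  made.
- **Intensity**: mean of the brightest `ceil(0.2 × n)` pixels in a
  25 μm circular ROI. ROI behavior at image edges is unspecified
  upstream; partial ROIs are clipped to existing pixels and flagged
  here.
- **Filtering**: per-brain min–max normalization to [0, 1]; cells with
  normalized intensity ≤ 0.05 are excluded (the comparison is ≤,
  matching the stated "<=5%"). If all intensities are equal the
  normalized value is defined as 1 and every cell is retained.
- **Region assignment**: the label of the nearest 10 μm voxel;
  round-half-down on the voxel grid breaks ties deterministically
  (lexicographically smaller index wins). Out-of-volume cells are
  labeled "outside" and counted, not dropped silently.
- **Distributions**: per-brain region percentages, then unweighted mean
  ± SEM across brains; a presentation helper pools regions averaging
  below 1% into "other".
- **Densities**: per-brain percentage of cells per 100 μm bin, then the
  unweighted cross-brain mean. Bin edges are anchored at the atlas
  origin so they coincide across brains.

## Photometry

dF/F follows the isosbestic recipe in this exact order: subtract the
background estimate (mean of the dedicated background channel — the
estimator is unstated upstream and a session mean is the simplest
unbiased choice) from both channels; low-pass both with a 4th-order
Butterworth at 2 Hz; fit `a + b·410` to the 470 channel by least
squares; output `(470 − fit)/fit`. Filtering is zero-phase
(forward–backward), because onset-aligned averaging at 30 Hz cannot
tolerate the ~group-delay of a causal 2 Hz filter and phase handling is
otherwise unspecified. Scale invariance (common gain on all channels
cancels) and exact cancellation of proportional channels are tested
invariants; the first/last 2 s are excluded from edge-sensitive checks.

Trial analysis segments the *raw* channels into 10 s windows around
movement onset and applies the preprocessing within each window (the
isosbestic fit is per-window; a per-session option exists). Each trial
is z-scored against a 700 ms baseline ending at onset (lever) or 500 ms
before onset (locomotion, where forward velocity lags movement).
Early/late grouping averages days 1–3 vs 8–10 for the 10-day lever task
and days 1–2 vs 4–5 for the 5-day locomotion task.

## Integration model

`A·snr + B·dcn + C = thal` by OLS on 135 s intervals sampled uniformly
within sessions (20 per subject by default — unstated upstream; enough
for a stable mean over 15-minute sessions, and configurable). R² is
`1 − SS_res/SS_tot`. The shuffle control draws, per interval,
independent uniform shifts in ±67.5 s for SNr and DCN (continuous,
rounded to whole samples; the uniform-over-the-full-interval reading of
"between 0 and ±67.5 s" is implemented), reads the shifted windows from
the parent session trace, and refits. Windows never wrap across session
boundaries: out-of-range shifts are redrawn (bounded retries) then
clamped, because wrapping would splice discontinuities. Intervals may
overlap. Per-subject means of observed and shuffled R² and their paired
differences are emitted; the significance test itself is left to
standard tools.

## Behavior and electrophysiology

Lever pushes: excursions whose peak exceeds 1 mm strictly; successes
reach the 5 mm reward threshold. Supra-threshold crossings connected
above half the push threshold are merged into one event, making counts
invariant to additive noise below 0.5 mm; the onset is the first sample
of the contiguous run above 10% of the push threshold leading into the
crossing (an onset criterion chosen here — the task rules define
counting thresholds, not onset samples). Movement onsets for photometry
alignment are velocity crossings preceded by ≥ 0.5 s of quiet. Running
bouts use explicit configuration (1 cm/s, ≥ 1 s, 0.5 s merge gap):
bout criteria are not defined by the task description and these defaults
are config, not inferred intent. Wheel velocity converts rotary-encoder
counts via a 16 cm wheel circumference. Optogenetic sessions are scored
in [on−120 s, on], [on+60, on+180], [off+60, off+180]; inclusion rules:
subjects averaging ≥ 10 pushes/session (photometry) and sessions with
≥ 2 baseline pushes/min, keeping the higher-baseline of two silencing
sessions (opto).

Evoked amplitudes subtract the 50 ms pre-onset baseline mean from the
post-onset extremum (sign preserved; inward negative). The peak search
window defaults to 100 ms, chosen to cover both the 1 ms and 50 ms
stimulus protocols. Classification: DCN input iff inward ≥ 25 pA, SNr
input iff outward ≥ 100 pA; four exhaustive classes. The
cross-activation check flags a −70 mV inward current as ChrimsonR
cross-activation when the +10 mV response to the same 450 nm stimulus is
outward above threshold; the threshold reuses the 100 pA outward
criterion, since the comparison is described without a cutoff.
Amplitudes are classified raw, with cross-activation carried as a flag.

## Synthetic data

The generators produce every input class with ground truth:

- **Mini atlas**: disjoint ellipsoidal regions with thalamic-nucleus
  stand-in names in a (600, 100, 101)-voxel label grid at 10 μm —
  region assignment needs a label grid, not anatomy. Fiducials and
  boxes are programmatic; box width/height vary smoothly so the volume
  profile is informative. The 6 mm AP extent gives an anterior-pole-to-
  SCO distance (~2.5 mm) proportioned like a real brain relative to
  40 μm sections, keeping sectioning quantization below 1%.
- **Brains**: the atlas carried through a known chain (translation,
  shear ≤ 0.06, per-axis scales 0.8–1.2 in the validation sweeps).
  Per-slice jitter (normal, SD configurable, clipped at 3 SD) corrupts
  every annotation on a section identically, emulating serial-alignment
  drift. Cells are placed uniformly inside regions; each cell's AP is
  snapped to its section plane and the recorded truth is the exact
  atlas coordinate of the snapped point (resampled if snapping would
  change its region), so zero-jitter recovery is exact by construction.
  Intensities are a bright lognormal bulk plus a 10% dim tail for the
  exclusion filter to act on.
- **Photometry**: SNr and DCN ideal traces are Poisson event trains
  (0.2 events/s) convolved with a 1 s-decay kernel — the
  autocorrelation is what gives the shuffle null traction; thalamus is
  exactly `A·snr + B·dcn + C` plus Gaussian noise (defaults A = 0.5,
  B = 0.3, C = 0.1, noise SD 0.05). Raw channels put the ideal trace on
  a fluorescence baseline, multiplied by a shared exponential bleach
  (τ = 600 s — exactly what isosbestic correction exists to remove) and
  offset by the background level; the 410 channel shares bleach and
  motion but not the transients. The Gaussian-noise/exponential-bleach
  model is a stated assumption, not a fit to recorded noise spectra.
- **Behavior**: piecewise linear-rise/hold/fall excursions at requested
  times and amplitudes; overlapping events are rejected so the event
  list is unambiguous ground truth.

What the generators do **not** emulate: real anatomy (regions are
ellipsoids; no hierarchy), optics (no shot noise, no wavelength
crosstalk), nonlinear indicator dynamics, imaging artifacts beyond
global brightness differences, or correlated annotation errors beyond
per-slice translation. Passing recovery tests therefore demonstrates
the correctness of the computations under the stated models, not
performance on real tissue or recordings.

## Pipeline and reproducibility

`run_all` executes anatomy → photometry → behavior → ephys stages from
one YAML-serializable config whose defaults are the stated analysis
parameters (2 Hz, 135 s, ±67.5 s, 700/500 ms, 1/5 mm, 25/100 pA, 5%,
100 μm, day groupings). Stage seeds are spawned from the master seed;
outputs are plain tables plus a manifest (config hash, seed, version),
and reruns are byte-identical. The shipped default run sizes the study
for desk-scale execution (3 brains × 400 cells, 3 subjects × 2 × 300 s
sessions, 10 intervals each); the validation suite uses 10–20 brains
and 100–200 seeded photometry runs, sizes chosen to make the recovery
statistics stable.

## Known limitations

- The AP-scale step inherits the sectioning quantization of the
  anterior pole (±half thickness); see above.
- The per-slice correction is translational; rotational or nonlinear
  within-slice distortion is out of scope, as is diffeomorphic
  registration generally.
- The isosbestic fit assumes artifacts act multiplicatively and
  identically on both channels; strong channel-specific motion would
  leak into dF/F.
- `fit_integration` is instantaneous and linear; lagged or nonlinear
  coupling between inputs and thalamus is not modeled.
- Real atlas volumes load through the same reader (TIFF label stack +
  JSON region table) but are not shipped.
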