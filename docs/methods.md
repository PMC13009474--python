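# Methods

## The synchronization problem

In axially swept light-sheet microscopy only a narrow band of camera rows
is exposed at any instant (the rolling shutter), and the thin waist of the
illumination sheet must sit on that band as it sweeps the chip.  The
reference instrument modelled here uses a 3200 × 3200-pixel camera with a
6.5 µm pitch behind a 20× objective and a 1.6× magnification changer,
giving a 203.125 nm effective pixel and a 650 µm row extent (quoted as
"200 nm / 640 × 640 µm²" at the usual one-significant-figure rounding —
the package always computes with the exact values).  The shutter is
8 rows ≈ 1.6 µm wide; synchronization must hold to half of that, 0.8 µm,
about 0.13 % of the field.  A frame consists of an acquisition segment
(the sweep) plus a fixed 24 ms flyback, so 26 + 24 ms ↔ 20 fps and
76 + 24 ms ↔ 10 fps.

## The actuator twin

The voice coil and its optics are modelled as a static, strictly monotone
voltage→position map `g(V)` (a cubic polynomial by default) feeding a
unit-DC-gain linear second-order plant

    x'' + 2 ζ ω x' + ω² x = ω² g(V(t)),   ω = 2π f_n.

This is the minimal model that exhibits both behaviours the calibration
exists to fix: a curved static response, and inertia that makes the coil
lag fast commands.  The defaults — `f_n = 800 Hz`, `ζ = 0.7`, `g` spanning
[−40, 690] µm over ±1 V — are plausible stand-ins for a fast focusing
actuator, *not* measurements of any physical device; the package therefore
only makes relative claims (static calibration suffices at low rates, a
naive drive fails at 20 fps, the optimized drive recovers), never
hardware-quantitative ones.  With these defaults the quasi-static tracking
lag at 1 fps is ~0.2 µm (passes the 0.8 µm tolerance) and the lag at
20 fps is ~7 µm (fails by ~9×), which brackets the regime the calibration
narrative needs.

Integration uses a fixed-step classical 4th-order scheme with
`dt = 1/(50 f_n)` (a precondition rejects `dt > 1/(20 f_n)`).  Because the
plant is linear, the RK4 step is an affine recursion with constant
matrices; it is evaluated by diagonalization and an IIR filter, which is
algebraically identical to the step-by-step loop (a loop fallback covers
a defective step matrix, e.g. critical damping).  The step response and
frequency response match their closed forms to a few 10⁻⁴.  Steady state
is reached by discarding 5 settle periods (2 inside the optimizer, where
the transient decays in ~1 ms ≪ one 50 ms period); a `periodic_flag`
records whether the state repeats at the period boundary within 1 nm.

### Flyback shape

The drive waveform is a cubic polynomial over the acquisition segment plus
a return segment.  A triangular (linear) voltage return is implemented but
is *not* the default: a velocity-discontinuous command leaves the coil
roughly `2ζ·v_fly/ω` (≈ 8 µm at a 24 ms flyback) off target at the moment
the next acquisition window opens, at any frame rate — the "sawtooth the
actuator cannot follow" failure.  The default return is an S-curve
quintic with matched end velocities and zero end acceleration, the
standard motion-profile shape that does not excite the resonance; a C¹
Hermite cubic is also available.  Only the acquisition window enters any
error metric; the flyback is dead time.

## Static calibration

The coil is parked at 100 equidistant voltages across its range (parked =
steady state, no dynamics), a focused-spot image is rendered at each, and
the spot position is measured as the brightest pixel (ties: lowest row)
refined by an intensity-weighted centroid over ±12 rows of
background-subtracted row sums.  ±12 rows is ≈ 5σ of the 0.5 µm spot, so
the noise-free measurement is exact to ~10⁻⁹ of the range; at a peak SNR
of 20 the position bias stays below 0.1 row.  Voltages whose spot falls
outside the measurable rows are skipped, mimicking frames with no visible
spot; positions are validated for strict monotonicity (violations raise,
listing the offending indices).

Interpolation is shape-preserving monotone piecewise-cubic (PCHIP,
Fritsch–Carlson-type) in both directions; the inverse is built by the same
construction on swapped axes, so interpolant ∘ inverse is the identity on
the sampled range and no overshoot can occur between samples.  Because the
measurable range stops short of the chip edges (park-grid spacing plus the
centroid window), inverting the curve for the extreme rows extrapolates
the monotone end segment; this is allowed up to the larger of one sample
spacing and 5 % of the row extent, and errors beyond that raise.

## Dynamic calibration

Per frame rate, the four coefficients `(a0..a3)` of the cubic drive
(over normalized acquisition time, for conditioning) are optimized
globally: differential evolution with population 32, bounds centred on
the inverted-static drive's least-squares cubic ± half the voltage range,
the naive cubic itself seeded into the initial population (so the
optimized error can never exceed the naive one), a fixed seed, and a
Nelder–Mead polish, all within a 2000-evaluation budget.  Exhausting the
budget without meeting the tolerance reports `passed=False` rather than
raising.  Two objectives are provided and agree in ordering on noise-free
renders (both are monotone in the per-row focus offset |Δ|):

- *trajectory*: the maximum |focus − shutter centre| over the window;
- *image*: the mean per-row intensity deficit `1 − I_row/I_focus` of a
  rendered swept frame, where a row exposed at offset Δ records the
  on-axis sheet intensity `s(Δ) = w0²/w(Δ)² = 1/(1 + (Δ/z_R)²)`.  Its
  pass tolerance is the deficit corresponding to a uniform |Δ| = 0.8 µm.

The identity of the optimizer and the exact image-error functional used
on real hardware are instrument-control details; differential evolution
and the mean deficit are this package's documented choices.  A single
cubic covers only the forward sweep; the return segment is generated from
it as described above.

On the default twin the 20 fps fit lands at ≈ 0.46 µm maximum error
(tolerance 0.8 µm) in ~2000 evaluations, reproducibly for a fixed seed.

## Bead metrics

The synthetic bead stacks place area-normalized anisotropic 3D Gaussians
(σ = FWHM/2.3548 per axis, point-sampled on the voxel grid — at ≥ 0.9
voxel σ the sampled sum matches the integral to ~10⁻⁷) at stated
positions, with optional per-bead FWHM triplets, Poisson noise, and a
warning when the Z step undersamples the axial FWHM (Nyquist: ≤ FWHM/2).

Detection finds local maxima above a threshold, prunes them greedily
(brightest kept) to a pairwise separation in µm, and drops candidates
near the faces.  FWHM measurement takes the three axis-aligned line
profiles through the peak voxel, crops each to ±2.5 µm (≥ ±12 samples)
around the peak, subtracts the median of the dimmer half of the crop as a
local background (robust to a neighbour's flank reaching the crop), and
locates the half-maximum crossings by linear interpolation on a 16×
band-limit (Fourier zero-padding) interpolated profile.  On
Nyquist-sampled Gaussians this keeps the estimator bias below ~1 %
(axial, ~2 samples per FWHM) and ~0.05 % (lateral), where direct linear
interpolation of the raw samples is biased by several percent; the bias
shrinks monotonically as sampling is refined.  No Gaussian fitting is
used anywhere in the measurement path; Gaussian closed forms appear only
as test oracles.  A profile with fewer than three contiguous raw samples
above half maximum is marked invalid ("undersampled"), as is one whose
crossing runs off the crop ("unbracketed half-max") — at 0.2 µm voxels
and 0.428 µm axial FWHM this conservative rule keeps roughly the
best-phased ~15 % of beads, which is why the characterization stacks
carry ≥ 200 beads.  "Lateral" statistics pool the X and Y values (two per
valid bead); the spread is the population (ddof = 0) standard deviation.

Brightness uniformity is the averaged line profile along X (averaging
over rows) or Y, reported with its maximum fractional deviation from the
mean; depth brightness is the per-plane mean normalized to plane 0.

## What the synthetic data does and does not show

The generators emulate focused-spot frames, uniform-slab sweep frames,
and bead stacks with Poisson shot noise on a constant background.  They
do not model optical aberrations, sCMOS read-noise maps or dual-direction
readout, sample drift, photobleaching, or refractive-index mismatch.
Passing tests therefore demonstrate that the *computations* — calibration,
optimization, and estimators — are correct on data obeying the stated
forward models, not that any physical instrument meets a given
specification.

## Problem sizes and numerical choices

The test suite and examples use: 100 park positions on the full 3200-row
chip (focus frames rendered as 64-column strips, since only the row
coordinate is informative); ~260 beads in an 80 × 220 × 220-voxel stack
(0.2 µm voxels) for the resolution round-trip, noise-free and at peak
SNR 20; and the full 2000-evaluation budget for the 20 fps fit.  A
320-row twin with a proportionally scaled static map is used where the
chip size is irrelevant.  Default render settings: 0.5 µm spot σ, 2000
photons per focus spot, background 20 counts.  All randomness flows
through explicit seeds (`numpy.random.default_rng`); renders, calibration,
and fits are bit-reproducible for a fixed seed, and written artifacts
embed the resolved configuration hash and seed.

## Known limitations

- The actuator is linear time-invariant; real voice coils add friction,
  saturation (only voltage clipping is modelled, with a warning), and
  temperature drift, so optimized waveforms would need periodic
  re-validation on hardware.
- The image-mode objective uses noise-free expected frames; with photon
  noise it inherits the variance of the row profile.
- The FWHM validity rule discards most beads at two samples per FWHM;
  summaries at that sampling describe the best-phased subset.
- The sheet model is a paraxial Gaussian beam; field-dependent sheet
  thickness and illumination-NA effects are out of scope.
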