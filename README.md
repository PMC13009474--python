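# aslmsim

A digital twin and calibration toolkit for **axially swept light-sheet
microscopy (ASLM)**.

In an ASLM instrument the thin waist of a Gaussian light sheet is swept
along its propagation axis by a voice-coil-driven remote-focusing mirror,
in synchrony with the rolling shutter of an sCMOS camera, so that every
camera row records only in-focus fluorescence.  For a large-field design
(3.2k × 3.2k chip, ~200 nm effective pixel, 640-µm-class field of view)
the synchronization must hold to about half the rolling-shutter width —
4 pixels, ~0.8 µm, roughly 0.13 % of the field — at frame rates up to
20 fps.  Two things make that hard: the static voltage→position response
of the voice coil is nonlinear, and at high sweep rates the actuator's
inertia makes it lag any naively commanded scan pattern.

`aslmsim` is written for instrument builders and for anyone who wants to
study or regression-test the calibration strategy without hardware.  It
provides:

- **`aslmsim.optics`** — first-principles design arithmetic: effective
  pixel size `p/(M·M_changer)`, field of view, Rayleigh resolution
  `0.61 λ/NA`, pupil diameter `D = 2·NA·f_TL/M`, Gaussian-sheet thickness
  `w(z) = w0 √(1+(z/z_R)²)`, frame rate, voxel throughput.
- **`aslmsim.instrument`** — the twin: a unit-DC-gain second-order
  actuator `x'' + 2ζω x' + ω²x = ω² g(V(t))` behind a monotone static map
  `g`, the rolling-shutter geometry, and synthetic renders (parked focus
  spots, swept frames of a uniform slab, 3D bead stacks with anisotropic
  Gaussian PSFs and Poisson noise).
- **`aslmsim.calibration`** — the two-stage synchronization calibration:
  1. *static*: park at ~100 equidistant voltages, locate the focus spot
     on the camera (brightest pixel + centroid refinement), build a
     monotone voltage↔position curve and invert it into a drive;
  2. *dynamic*: per frame rate, globally optimize the four coefficients
     of a cubic drive polynomial (differential evolution + Nelder–Mead)
     against the simulated sync error or an image-based intensity-deficit
     proxy.
- **`aslmsim.metrics`** — bead-based resolution characterization (per-axis
  FWHM from line profiles, population mean ± std), brightness-uniformity
  profiles, and depth-brightness curves.
- **`aslmsim.cli`** — an `aslmsim` command with `optics`, `simulate`,
  `calibrate-static`, `calibrate-dynamic`, `beads`, `uniformity`, and
  `depth-profile` subcommands (YAML config in, CSV/JSON/OME-TIFF out,
  seeded and reproducible).

## Worked example

```python
from aslmsim import calibration as cal
from aslmsim.config import default_config
from aslmsim.instrument import sync_error, voice_coil_response

twin = default_config()                       # the reference instrument
curve = cal.build_static_calibration(twin, n_positions=100, seed=1)
print(f"calibrated {curve.voltages.size} park positions spanning "
      f"{curve.position_range_um[0]:.1f}-{curve.position_range_um[1]:.1f} um")
for fps in (1.0, 20.0):
    shutter = twin.shutter.with_frame_rate(fps)
    drive = cal.drive_from_calibration(curve, shutter)
    err = sync_error(voice_coil_response(twin.voice_coil, drive), shutter)
    print(f"inverted-static drive at {fps:4.0f} fps: "
          f"max sync error {err.max_abs_um:.3f} um")
fit = cal.fit_dynamic_waveform(twin, 20.0, seed=1, curve=curve)
print(f"optimized cubic drive at 20 fps: max sync error "
      f"{fit.max_error_um:.3f} um (pass: {fit.passed}, "
      f"{fit.optimizer_evals} evaluations)")
```

prints (the 20 fps static drive also emits a voltage-clipping warning —
the saturated turnaround is part of why it fails):

```
calibrated 90 park positions spanning 2.9-647.1 um
inverted-static drive at    1 fps: max sync error 0.196 um
inverted-static drive at   20 fps: max sync error 6.999 um
optimized cubic drive at 20 fps: max sync error 0.456 um (pass: True, 2000 evaluations)
```

which is the calibration story in three numbers: the inverted static
curve keeps the focus within the 0.8 µm tolerance at 1 fps (0.196 µm),
inertia breaks it at 20 fps (6.999 µm), and the globally optimized cubic
waveform restores synchronization at 20 fps (0.456 µm < 0.8 µm).

The same twin feeds the characterization pipeline: render a seeded bead
stack (`aslmsim simulate --kind beads`), then `aslmsim beads` detects the
beads, measures per-axis FWHM from their line profiles, and reports
lateral (pooled X/Y) and axial mean ± std — on synthetic beads generated
at 0.586/0.428 µm FWHM and 0.2 µm voxels the pipeline recovers the means
to well within 2 % without noise and within 5 % at a peak SNR of 20.

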