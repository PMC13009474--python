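"""Two-stage synchronization calibration of the swept light sheet.

Stage one (static): the voice coil is parked at ~100 equidistant voltages,
a focused-spot image is recorded at each, and the focus position is read
off the camera by locating the brightest pixel with sub-pixel centroid
refinement.  The resulting monotone voltage→position curve is inverted to
generate the drive voltages that keep the sheet focus on the rolling
shutter.  This suffices at low frame rates where the actuator is
quasi-static.

Stage two (dynamic): at high frame rates the actuator's inertia makes it
lag the inverted-static drive, so a global optimizer (differential
evolution with a Nelder–Mead polish) searches the four coefficients of a
cubic drive polynomial — one set per frame rate — minimizing either the
simulated focus-vs-shutter error directly or an image-analysis proxy, the
mean per-row intensity deficit of a rendered sweep frame.  Both objectives
are monotone in the per-row focus offset |Δ| and therefore rank candidate
waveforms identically on noise-free renders.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import differential_evolution, minimize

from .config import RunConfig
from .errors import (
    BorderPeakError,
    CalibrationError,
    ConfigError,
    NoPeakError,
    OutOfRangeError,
)
from .instrument import (
    DriveWaveform,
    FocusTrajectory,
    SampledDrive,
    ShutterConfig,
    _return_segment,
    render_focus_frame,
    swept_row_profile,
    sync_error,
    voice_coil_response,
)
from .optics import rayleigh_range

__all__ = [
    "CalibrationCurve",
    "WaveformFit",
    "SyncReport",
    "measure_focus_position",
    "build_static_calibration",
    "drive_from_calibration",
    "cubic_fit_of_drive",
    "fit_dynamic_waveform",
    "validate_sync",
]

#: Synchronization tolerance: half the 8-pixel rolling shutter, in µm.
DEFAULT_TOLERANCE_UM = 0.8


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone voltage↔position mapping from park-and-measure samples.

    Both directions use shape-preserving (Fritsch–Carlson-type monotone
    piecewise-cubic) interpolation, so no overshoot can appear between
    samples and the inverse is built by the same construction on swapped
    axes.
    """

    voltages: np.ndarray
    positions_um: np.ndarray
    _fwd: PchipInterpolator = field(repr=False, compare=False)
    _inv: PchipInterpolator = field(repr=False, compare=False)

    @classmethod
    def from_samples(cls, voltages, positions_um) -> "CalibrationCurve":
        v = np.asarray(voltages, dtype=float)
        p = np.asarray(positions_um, dtype=float)
        if v.ndim != 1 or v.shape != p.shape or v.size < 4:
            raise CalibrationError("need matching 1D arrays of at least 4 samples")
        order = np.argsort(v)
        v, p = v[order], p[order]
        bad = np.flatnonzero(np.diff(p) <= 0)
        if bad.size:
            raise CalibrationError(
                "measured positions are not strictly increasing in voltage at "
                f"sample indices {bad.tolist()}")
        return cls(voltages=v, positions_um=p,
                   _fwd=PchipInterpolator(v, p, extrapolate=True),
                   _inv=PchipInterpolator(p, v, extrapolate=True))

    @property
    def position_range_um(self) -> tuple[float, float]:
        return float(self.positions_um[0]), float(self.positions_um[-1])

    def position(self, voltage) -> np.ndarray:
        """Interpolated focus position (µm) for a voltage within the samples."""
        return self._fwd(voltage)

    @property
    def max_spacing_um(self) -> float:
        """Largest gap between adjacent calibrated positions."""
        return float(np.max(np.diff(self.positions_um)))

    def voltage(self, position_um, extrapolation_margin_um: float | None = 0.0) -> np.ndarray:
        """Inverted curve: drive voltage that parks the focus at a position.

        Positions may exceed the calibrated range by at most
        ``extrapolation_margin_um`` (the measurable range stops short of the
        chip edges by up to one park-grid step, so driving the exact edge
        rows needs a small extrapolation).  ``None`` allows one sample
        spacing, over which the monotone end segment remains trustworthy.
        """
        p = np.asarray(position_um, dtype=float)
        lo, hi = self.position_range_um
        m = self.max_spacing_um if extrapolation_margin_um is None else extrapolation_margin_um
        if np.any(p < lo - m) or np.any(p > hi + m):
            raise OutOfRangeError(
                f"requested position outside calibrated range [{lo:.3f}, {hi:.3f}] µm "
                f"(± {m} µm margin)")
        return self._inv(p)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            pd.DataFrame({"voltage": self.voltages,
                          "position_um": self.positions_um}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        df = pd.read_csv(path, comment="#")
        return cls.from_samples(df["voltage"].to_numpy(), df["position_um"].to_numpy())


@dataclass
class WaveformFit:
    """Result of the dynamic (per-frame-rate) waveform optimization."""

    frame_rate_fps: float
    coefficients: tuple[float, float, float, float]
    max_error_um: float
    rms_error_um: float
    tolerance_um: float
    passed: bool
    optimizer_evals: int
    seed: int
    error_mode: str = "trajectory"
    objective_value: float = float("nan")
    flyback_mode: str = "smooth_return"

    def to_waveform(self, shutter: ShutterConfig) -> DriveWaveform:
        return DriveWaveform(
            acq_coeffs=self.coefficients,
            acquisition_ms=shutter.acquisition_ms,
            flyback_ms=shutter.flyback_ms,
            flyback_mode=self.flyback_mode,
        )

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "frame_rate_fps": self.frame_rate_fps,
            "coefficients": list(self.coefficients),
            "max_error_um": self.max_error_um,
            "rms_error_um": self.rms_error_um,
            "tolerance_um": self.tolerance_um,
            "passed": self.passed,
            "optimizer_evals": self.optimizer_evals,
            "seed": self.seed,
            "error_mode": self.error_mode,
            "objective_value": self.objective_value,
            "flyback_mode": self.flyback_mode,
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "WaveformFit":
        doc = json.loads(Path(path).read_text())
        return cls(
            frame_rate_fps=doc["frame_rate_fps"],
            coefficients=tuple(doc["coefficients"]),
            max_error_um=doc["max_error_um"],
            rms_error_um=doc["rms_error_um"],
            tolerance_um=doc["tolerance_um"],
            passed=doc["passed"],
            optimizer_evals=doc["optimizer_evals"],
            seed=doc["seed"],
            error_mode=doc.get("error_mode", "trajectory"),
            objective_value=doc.get("objective_value", float("nan")),
            flyback_mode=doc.get("flyback_mode", "smooth_return"),
        )


@dataclass(frozen=True)
class SyncReport:
    """Re-simulated synchronization quality of a fitted waveform."""

    frame_rate_fps: float
    max_error_um: float
    rms_error_um: float
    tolerance_um: float
    margin_um: float
    passed: bool
    per_row_error_um: np.ndarray


def measure_focus_position(
    image: np.ndarray,
    shutter: ShutterConfig,
    window_rows: int = 12,
) -> float:
    """Focus position (µm) read off a parked-spot camera image.

    Locates the brightest pixel (ties: lowest row index), then refines the
    row coordinate by an intensity-weighted centroid of the
    background-subtracted row sums over ± ``window_rows`` rows.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise CalibrationError(f"expected a 2D image, got ndim={img.ndim}")
    if img.max() == img.min():
        raise NoPeakError("image is flat; no focus spot to locate")
    peak_row = int(np.unravel_index(np.argmax(img), img.shape)[0])
    n_rows = img.shape[0]
    if peak_row - window_rows < 0 or peak_row + window_rows > n_rows - 1:
        raise BorderPeakError(
            f"peak at row {peak_row} is within {window_rows} rows of the border")
    background = float(np.median(img))
    rows = np.arange(peak_row - window_rows, peak_row + window_rows + 1)
    weights = img[rows].sum(axis=1) - img.shape[1] * background
    weights = np.clip(weights, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise NoPeakError("no intensity above background around the peak")
    centroid = float(np.dot(rows, weights) / total)
    return shutter.sweep_origin_um + centroid * shutter.effective_pixel_um


def build_static_calibration(
    system: RunConfig,
    n_positions: int = 100,
    seed: int | None = None,
    noise: bool = True,
    window_rows: int = 12,
) -> CalibrationCurve:
    """Park-and-measure calibration curve over the camera's row extent.

    Parks the actuator at ``n_positions`` equidistant voltages spanning its
    range (parked means no dynamics: the steady-state position is g(V)),
    renders a focused-spot frame at each, measures the spot position, and
    fits a monotone interpolant.  Voltages whose spot falls outside the
    measurable row extent are skipped, mimicking frames with no visible
    spot.
    """
    if n_positions < 4:
        raise ConfigError("need at least 4 park positions")
    rng = np.random.default_rng(seed)
    vlo, vhi = system.voice_coil.voltage_range
    voltages = np.linspace(vlo, vhi, n_positions)
    kept_v, measured = [], []
    for v in voltages:
        pos = float(system.voice_coil.g(v))
        try:
            frame = render_focus_frame(
                pos, system.shutter,
                spot_sigma_um=system.render.spot_sigma_um,
                photons=system.render.photons,
                background=system.render.background,
                seed=rng, noise=noise)
            measured_pos = measure_focus_position(frame, system.shutter,
                                                  window_rows=window_rows)
        except (OutOfRangeError, BorderPeakError):
            continue
        kept_v.append(v)
        measured.append(measured_pos)
    if len(kept_v) < 4:
        raise CalibrationError(
            "fewer than 4 park positions produced a measurable spot")
    return CalibrationCurve.from_samples(np.array(kept_v), np.array(measured))


def drive_from_calibration(
    curve: CalibrationCurve,
    shutter: ShutterConfig,
    samples_per_period: int = 512,
    flyback_mode: str = "smooth_return",
    extrapolation_margin_um: float | None = None,
) -> SampledDrive:
    """Inverted-static drive: V(tᵢ) = curve⁻¹(shutter_center(tᵢ)).

    Samples the acquisition window densely; the flyback returns the voltage
    to its start value, by default as an S-curve quintic (``smooth_return``)
    — a turnaround the actuator can follow without ringing into the next
    window — with ``cubic_return`` and ``linear_return`` as alternatives.
    """
    if extrapolation_margin_um is None:
        # the measurable range stops short of the chip edges by up to one
        # park-grid step plus the centroid window; allow a small fraction of
        # the sweep extent beyond the calibrated range
        extrapolation_margin_um = max(curve.max_spacing_um,
                                      0.05 * shutter.row_extent_um)
    n_acq = max(int(round(samples_per_period * shutter.acquisition_ms / shutter.period_ms)), 8)
    t_acq = np.linspace(0.0, shutter.acquisition_ms, n_acq)
    centers = shutter.sweep_origin_um + t_acq / shutter.acquisition_ms * shutter.row_extent_um
    v_acq = np.asarray(curve.voltage(centers, extrapolation_margin_um), dtype=float)
    if flyback_mode == "linear_return":
        # the periodic wrap of SampledDrive interpolates linearly back to V(0)
        times, volts = t_acq, v_acq
    elif flyback_mode in ("cubic_return", "smooth_return"):
        n_fly = max(samples_per_period - n_acq, 32)
        s = np.linspace(0.0, 1.0, n_fly + 1)[1:-1]
        fb = shutter.flyback_ms
        m0 = (v_acq[-1] - v_acq[-2]) / (t_acq[-1] - t_acq[-2]) * fb
        m1 = (v_acq[1] - v_acq[0]) / (t_acq[1] - t_acq[0]) * fb
        v_fly = _return_segment(s, v_acq[-1], m0, v_acq[0], m1, flyback_mode)
        times = np.concatenate([t_acq, shutter.acquisition_ms + s * fb])
        volts = np.concatenate([v_acq, v_fly])
    else:
        raise ConfigError(f"unknown flyback_mode {flyback_mode!r}")
    return SampledDrive(times_ms=times, voltages=volts, period_ms=shutter.period_ms)


def cubic_fit_of_drive(drive: SampledDrive, shutter: ShutterConfig) -> tuple[float, ...]:
    """Least-squares cubic (a0..a3 over normalized acquisition time) of a drive."""
    n = 257
    t = np.linspace(0.0, shutter.acquisition_ms, n)
    u = t / shutter.acquisition_ms
    v = np.asarray(drive.voltage(t), dtype=float)
    coef = np.polynomial.Polynomial.fit(u, v, 3).convert().coef
    out = np.zeros(4)
    out[: len(coef)] = coef
    return tuple(float(c) for c in out)


def _image_deficit_tolerance(system: RunConfig, tolerance_um: float) -> float:
    """Mean-intensity deficit corresponding to a uniform |Δ| = tolerance."""
    zr = rayleigh_range(system.sheet)
    r2 = (tolerance_um / zr) ** 2
    return r2 / (1.0 + r2)


def fit_dynamic_waveform(
    system: RunConfig,
    frame_rate_fps: float,
    error_mode: str = "trajectory",
    optimizer_cfg: dict | None = None,
    seed: int = 0,
    curve: CalibrationCurve | None = None,
) -> WaveformFit:
    """Globally optimize the cubic drive coefficients for one frame rate.

    Differential evolution (population 32, coefficient bounds centred on the
    inverted-static drive's cubic fit ± half the voltage range, the naive
    cubic itself seeded into the initial population) followed by a
    Nelder–Mead polish, within a fixed evaluation budget.  Non-convergence
    within the budget is reported via ``passed=False``, never raised.
    """
    cfg = {
        "population": 32,
        "max_evals": 2000,
        "tolerance_um": DEFAULT_TOLERANCE_UM,
        "max_fps": 20.0,
        "settle_periods": 2,
        "flyback_mode": "smooth_return",
        "bound_halfwidth_fraction": 0.5,
    }
    cfg.update(optimizer_cfg or {})
    if error_mode not in ("trajectory", "image"):
        raise ConfigError(f"unknown error_mode {error_mode!r}")
    if not 0 < frame_rate_fps <= cfg["max_fps"]:
        raise ConfigError(
            f"frame rate {frame_rate_fps} fps outside the supported range "
            f"(0, {cfg['max_fps']}]")
    shutter = system.shutter.with_frame_rate(frame_rate_fps)
    if curve is None:
        curve = build_static_calibration(system, seed=seed)
    naive = drive_from_calibration(curve, shutter)
    c_naive = np.array(cubic_fit_of_drive(naive, shutter))
    vlo, vhi = system.voice_coil.voltage_range
    half = cfg["bound_halfwidth_fraction"] * (vhi - vlo)
    bounds = [(c - half, c + half) for c in c_naive]
    model = system.voice_coil
    settle = cfg["settle_periods"]

    evals = 0
    best = {"x": c_naive.copy(), "f": np.inf}

    def objective(a: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        wf = DriveWaveform(tuple(float(c) for c in a), shutter.acquisition_ms,
                           shutter.flyback_ms, cfg["flyback_mode"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # clipped drives are valid candidates
            traj = voice_coil_response(model, wf, n_settle_periods=settle)
            if error_mode == "trajectory":
                f = sync_error(traj, shutter).max_abs_um
            else:
                _, s = swept_row_profile(model, wf, shutter, system.sheet,
                                         trajectory=traj)
                f = float(np.mean(1.0 - s))
        if f < best["f"]:
            best["x"], best["f"] = np.asarray(a, dtype=float).copy(), f
        return f

    pop = cfg["population"]
    rng = np.random.default_rng(seed)
    init = rng.uniform([b[0] for b in bounds], [b[1] for b in bounds], size=(pop, 4))
    init[0] = np.clip(c_naive, [b[0] for b in bounds], [b[1] for b in bounds])
    de_budget = int(cfg["max_evals"] * 0.85)
    maxiter = max(de_budget // pop - 1, 1)
    differential_evolution(
        objective, bounds, init=init, maxiter=maxiter, tol=0.0, seed=seed,
        mutation=(0.5, 1.0), recombination=0.7, polish=False)
    remaining = cfg["max_evals"] - evals
    if remaining > 20:
        minimize(objective, best["x"], method="Nelder-Mead",
                 options={"maxfev": remaining, "xatol": 1e-8, "fatol": 1e-12})

    coeffs = tuple(float(c) for c in best["x"])
    wf = DriveWaveform(coeffs, shutter.acquisition_ms, shutter.flyback_ms,
                       cfg["flyback_mode"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        traj = voice_coil_response(model, wf, n_settle_periods=5)
    err = sync_error(traj, shutter)
    if error_mode == "trajectory":
        passed = err.max_abs_um <= cfg["tolerance_um"]
    else:
        passed = best["f"] <= _image_deficit_tolerance(system, cfg["tolerance_um"])
    return WaveformFit(
        frame_rate_fps=frame_rate_fps,
        coefficients=coeffs,
        max_error_um=err.max_abs_um,
        rms_error_um=err.rms_um,
        tolerance_um=cfg["tolerance_um"],
        passed=passed,
        optimizer_evals=evals,
        seed=seed,
        error_mode=error_mode,
        objective_value=float(best["f"]),
        flyback_mode=cfg["flyback_mode"],
    )


def validate_sync(
    fit: WaveformFit,
    system: RunConfig,
    tolerance_um: float = DEFAULT_TOLERANCE_UM,
    trajectory: FocusTrajectory | None = None,
) -> SyncReport:
    """Re-simulate a fitted waveform and report its synchronization quality.

    Returns the maximum and RMS focus-vs-shutter error over the acquisition
    window, the per-row error profile, and the margin to the tolerance.
    A precomputed trajectory may be supplied (e.g. for analytic checks).
    """
    shutter = system.shutter.with_frame_rate(fit.frame_rate_fps)
    if trajectory is None:
        wf = fit.to_waveform(shutter)
        trajectory = voice_coil_response(system.voice_coil, wf, n_settle_periods=5)
    err = sync_error(trajectory, shutter)
    rows = np.arange(shutter.n_rows)
    t_rows = rows / shutter.n_rows * shutter.acquisition_ms
    per_row = np.abs(trajectory.position_at(t_rows) - shutter.row_position_um(rows))
    margin = tolerance_um - err.max_abs_um
    return SyncReport(
        frame_rate_fps=fit.frame_rate_fps,
        max_error_um=err.max_abs_um,
        rms_error_um=err.rms_um,
        tolerance_um=tolerance_um,
        margin_um=margin,
        passed=err.max_abs_um <= tolerance_um,
        per_row_error_um=per_row,
    )
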