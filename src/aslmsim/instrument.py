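"""Digital twin of the swept-sheet instrument.

The moving part of an axially swept light-sheet microscope is a voice-coil
actuator that refocuses the illumination along the detection rows of a
rolling-shutter camera.  The twin models the actuator as a unit-DC-gain
linear second-order plant

    x'' + 2 ζ ω x' + ω² x = ω² g(V(t)),      ω = 2π f_n

driven through a static, strictly monotone voltage→position nonlinearity
``g``.  This is the minimal model exhibiting the two behaviours that make
calibration necessary: a curved static response (handled by park-and-measure
calibration) and inertia at high sweep rates (handled by waveform
optimization).

The module also renders the three kinds of synthetic images the calibration
and characterization pipelines consume: a focused-spot frame per parked
voltage, a rolling-shutter sweep frame of a uniform fluorescent slab, and a
3D bead stack with an anisotropic Gaussian PSF.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError, OutOfRangeError, SimulationError
from .optics import SheetSpec, rayleigh_range
from .stacks import ImageStack

__all__ = [
    "VoiceCoilModel",
    "ShutterConfig",
    "DriveWaveform",
    "SampledDrive",
    "FocusTrajectory",
    "SyncError",
    "FLYBACK",
    "voice_coil_response",
    "simulate_transient",
    "shutter_center",
    "sync_error",
    "swept_row_profile",
    "render_focus_frame",
    "render_swept_frame",
    "render_bead_stack",
]

logger = logging.getLogger("aslmsim")

#: Sentinel returned by :func:`shutter_center` during the flyback segment.
FLYBACK = math.nan

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class VoiceCoilModel:
    """Second-order actuator with a static polynomial nonlinearity.

    ``static_map_coeffs`` are ascending polynomial coefficients of
    ``g(V)`` in µm per volt power; ``g`` must be strictly increasing over
    ``voltage_range`` and map it inside ``position_range_um``.
    """

    natural_frequency_hz: float
    damping_ratio: float
    static_map_coeffs: tuple[float, ...]
    voltage_range: tuple[float, float]
    position_range_um: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.natural_frequency_hz > 0:
            raise ConfigError("natural frequency must be positive")
        if not self.damping_ratio > 0:
            raise ConfigError("damping ratio must be positive")
        vlo, vhi = self.voltage_range
        if not vlo < vhi:
            raise ConfigError("voltage_range must be (low, high) with low < high")
        v = np.linspace(vlo, vhi, 257)
        pos = self.g(v)
        if not np.all(np.diff(pos) > 0):
            raise ConfigError("static map g(V) must be strictly increasing over voltage_range")
        plo, phi = self.position_range_um
        eps = 1e-9 * max(1.0, abs(phi - plo))
        if pos.min() < plo - eps or pos.max() > phi + eps:
            raise ConfigError(
                f"g(voltage_range) = [{pos.min():.3f}, {pos.max():.3f}] µm exceeds "
                f"position_range_um = [{plo}, {phi}]"
            )

    def g(self, voltage):
        """Static equilibrium position (µm) for a voltage (scalar or array)."""
        return np.polynomial.polynomial.polyval(voltage, np.asarray(self.static_map_coeffs))

    def g_inverse(self, position_um, tol: float = 1e-10):
        """Numerical inverse of ``g`` by bisection (oracle/testing helper)."""
        pos = np.atleast_1d(np.asarray(position_um, dtype=float))
        lo = np.full(pos.shape, self.voltage_range[0])
        hi = np.full(pos.shape, self.voltage_range[1])
        if np.any(pos < self.g(lo)) or np.any(pos > self.g(hi)):
            raise OutOfRangeError("position outside the static map's range")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            below = self.g(mid) < pos
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
            if np.max(hi - lo) < tol:
                break
        out = 0.5 * (lo + hi)
        return out if np.ndim(position_um) else float(out[0])

    @property
    def omega_per_ms(self) -> float:
        """Angular natural frequency in rad/ms."""
        return 2.0 * math.pi * self.natural_frequency_hz / 1000.0


@dataclass(frozen=True)
class ShutterConfig:
    """Rolling-shutter geometry and frame timing.

    Row 0 sits at ``sweep_origin_um``; row ``i`` at origin + i × pixel.  The
    active-band centre sweeps the full row extent during ``acquisition_ms``
    and the actuator flies back during ``flyback_ms``.
    """

    n_rows: int
    shutter_width_rows: int
    acquisition_ms: float
    flyback_ms: float
    effective_pixel_um: float
    sweep_origin_um: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.shutter_width_rows <= self.n_rows:
            raise ConfigError("shutter_width_rows must be in [1, n_rows]")
        if not (self.acquisition_ms > 0 and self.flyback_ms > 0):
            raise ConfigError("acquisition and flyback times must be positive")
        if not self.effective_pixel_um > 0:
            raise ConfigError("effective pixel must be positive")

    @property
    def period_ms(self) -> float:
        return self.acquisition_ms + self.flyback_ms

    @property
    def row_extent_um(self) -> float:
        return self.n_rows * self.effective_pixel_um

    def row_position_um(self, row) -> np.ndarray | float:
        return self.sweep_origin_um + np.asarray(row) * self.effective_pixel_um

    def with_frame_rate(self, fps: float) -> "ShutterConfig":
        """Same geometry at a different frame rate, keeping the flyback time."""
        acquisition = 1000.0 / fps - self.flyback_ms
        if acquisition <= 0:
            raise ConfigError(f"{fps} fps leaves no acquisition time at "
                              f"{self.flyback_ms} ms flyback")
        return ShutterConfig(
            n_rows=self.n_rows,
            shutter_width_rows=self.shutter_width_rows,
            acquisition_ms=acquisition,
            flyback_ms=self.flyback_ms,
            effective_pixel_um=self.effective_pixel_um,
            sweep_origin_um=self.sweep_origin_um,
        )


def _return_segment(s, p0, v0, p1, v1, mode: str):
    """Flyback shape on s ∈ [0, 1] from (p0, slope v0) to (p1, slope v1).

    ``cubic_return`` is the C¹ Hermite cubic; ``smooth_return`` the C²-style
    quintic with zero end acceleration (an S-curve).  Slopes are per unit s.
    """
    if mode == "cubic_return":
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        return h00 * p0 + h10 * v0 + h01 * p1 + h11 * v1
    if mode == "smooth_return":
        s2, s3 = s * s, s * s * s
        s4, s5 = s2 * s2, s2 * s3
        q00 = 1 - 10 * s3 + 15 * s4 - 6 * s5
        q10 = s - 6 * s3 + 8 * s4 - 3 * s5
        q01 = 10 * s3 - 15 * s4 + 6 * s5
        q11 = -4 * s3 + 7 * s4 - 3 * s5
        return q00 * p0 + q10 * v0 + q01 * p1 + q11 * v1
    raise ConfigError(f"unknown return mode {mode!r}")


@dataclass(frozen=True)
class DriveWaveform:
    """Periodic drive voltage: cubic over the acquisition segment + flyback.

    ``acq_coeffs`` are (a0, a1, a2, a3) of V(u) = a0 + a1 u + a2 u² + a3 u³
    over normalized time u ∈ [0, 1] of the acquisition segment.  The flyback
    segment returns to the acquisition start value as one of:

    ``smooth_return``
        (default) S-curve quintic with matched end velocities and zero end
        acceleration — the motion-profile shape that does not excite the
        actuator's resonance at the window boundaries.
    ``cubic_return``
        C¹ Hermite cubic matching the slopes of the adjacent acquisition
        segments.
    ``linear_return``
        straight voltage ramp (a triangular command; an inertial actuator
        cannot follow its velocity steps — kept for exactly that
        demonstration).
    """

    acq_coeffs: tuple[float, float, float, float]
    acquisition_ms: float
    flyback_ms: float
    flyback_mode: str = "smooth_return"

    def __post_init__(self) -> None:
        if len(self.acq_coeffs) != 4 or not all(math.isfinite(c) for c in self.acq_coeffs):
            raise ConfigError("acq_coeffs must be four finite numbers")
        if self.flyback_mode not in ("linear_return", "cubic_return", "smooth_return"):
            raise ConfigError(f"unknown flyback_mode {self.flyback_mode!r}")
        if not (self.acquisition_ms > 0 and self.flyback_ms > 0):
            raise ConfigError("segment durations must be positive")

    @property
    def period_ms(self) -> float:
        return self.acquisition_ms + self.flyback_ms

    def voltage(self, t_ms) -> np.ndarray:
        """Drive voltage at time(s) ``t_ms``; periodic in ``period_ms``."""
        t = np.mod(np.asarray(t_ms, dtype=float), self.period_ms)
        a0, a1, a2, a3 = self.acq_coeffs
        u = np.clip(t / self.acquisition_ms, 0.0, 1.0)
        acq = a0 + u * (a1 + u * (a2 + u * a3))
        v_end = a0 + a1 + a2 + a3
        s = np.clip((t - self.acquisition_ms) / self.flyback_ms, 0.0, 1.0)
        if self.flyback_mode == "linear_return":
            fly = v_end + (a0 - v_end) * s
        else:
            # slopes (in V per flyback) continuous with both neighbours
            m0 = (a1 + 2 * a2 + 3 * a3) / self.acquisition_ms * self.flyback_ms
            m1 = a1 / self.acquisition_ms * self.flyback_ms
            fly = _return_segment(s, v_end, m0, a0, m1, self.flyback_mode)
        out = np.where(t < self.acquisition_ms, acq, fly)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SampledDrive:
    """Periodic drive defined by sampled (time, voltage) pairs.

    Linear interpolation between samples; the series must start at t = 0 and
    the waveform wraps around after ``period_ms``.
    """

    times_ms: np.ndarray
    voltages: np.ndarray
    period_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ConfigError("times and voltages must be matching 1D arrays (n >= 2)")
        if not np.all(np.diff(t) > 0):
            raise ConfigError("sample times must be strictly increasing")
        if t[0] != 0 or t[-1] > self.period_ms:
            raise ConfigError("samples must start at 0 and stay within one period")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "voltages", v)

    def voltage(self, t_ms) -> np.ndarray:
        t = np.mod(np.asarray(t_ms, dtype=float), self.period_ms)
        tp = np.concatenate([self.times_ms, [self.period_ms]])
        vp = np.concatenate([self.voltages, [self.voltages[0]]])
        out = np.interp(t, tp, vp)
        return out if out.ndim else float(out)


@dataclass
class FocusTrajectory:
    """One steady period of the simulated light-sheet focus position."""

    times_ms: np.ndarray
    positions_um: np.ndarray
    periodic_flag: bool
    period_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.ndim != 1 or t.shape != np.shape(self.positions_um):
            raise ConfigError("times and positions must be matching 1D arrays")
        if not np.all(np.diff(t) > 0):
            raise ConfigError("trajectory times must be strictly increasing")

    def position_at(self, t_ms) -> np.ndarray:
        """Periodic linear interpolation of the focus position."""
        t = np.mod(np.asarray(t_ms, dtype=float) - self.times_ms[0],
                   self.period_ms) + self.times_ms[0]
        return np.interp(t, self.times_ms, self.positions_um)


@dataclass(frozen=True)
class SyncError:
    """Focus-vs-shutter deviation over the acquisition window."""

    max_abs_um: float
    rms_um: float


def _rk4_matrices(omega: float, zeta: float, dt: float):
    """Constant matrices of the exact RK4 step for the linear plant.

    For x' = M x + c p(t) with input sampled at (t, t+dt/2, t+dt), a classic
    RK4 step is the affine recursion x⁺ = A x + B0 p0 + B1 p1 + B2 p2; the
    matrices depend only on (ω, ζ, dt) and are precomputed once.
    """
    M = np.array([[0.0, 1.0], [-omega**2, -2.0 * zeta * omega]])
    c = np.array([0.0, omega**2])
    I = np.eye(2)
    M2, M3 = M @ M, M @ M @ M
    A = I + dt * M + dt**2 / 2 * M2 + dt**3 / 6 * M3 + dt**4 / 24 * (M2 @ M2)
    B0 = dt / 6 * (I + dt * M + dt**2 / 2 * M2 + dt**3 / 4 * M3) @ c
    B1 = dt / 6 * (4 * I + 2 * dt * M + dt**2 / 2 * M2) @ c
    B2 = dt / 6 * c
    return A, B0, B1, B2


def _propagate(A: np.ndarray, U: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Iterate x[n+1] = A x[n] + U[n]; returns states of shape (N+1, 2).

    The recursion is diagonalized and evaluated with an IIR filter, which is
    algebraically identical to the step-by-step loop (used as a fallback for
    defective A, e.g. a critically damped plant).
    """
    N = U.shape[0]
    lam, V = np.linalg.eig(A)
    if abs(lam[0] - lam[1]) > 1e-9 * max(1.0, abs(lam[0])) and np.linalg.cond(V) < 1e8:
        f = np.linalg.solve(V.astype(complex), U.T.astype(complex))
        w0 = np.linalg.solve(V.astype(complex), x0.astype(complex))
        W = np.empty((2, N + 1), dtype=complex)
        W[:, 0] = w0
        for i in range(2):
            yi, _ = lfilter([1.0 + 0j], [1.0 + 0j, -lam[i]], f[i],
                            zi=np.array([lam[i] * w0[i]]))
            W[i, 1:] = yi
        return np.ascontiguousarray((V @ W).T).real
    states = np.empty((N + 1, 2))
    states[0] = x0
    x = x0.copy()
    for n in range(N):
        x = A @ x + U[n]
        states[n + 1] = x
    return states


def _integrate(model: VoiceCoilModel, drive, duration_ms: float, dt_ms: float | None,
               x0: np.ndarray, n_steps: int | None = None):
    """Shared RK4 integration over [0, duration]; returns (times, states, dt)."""
    omega = model.omega_per_ms
    dt_max = 50.0 / model.natural_frequency_hz  # 1/(20 f_n) in ms
    if dt_ms is None:
        dt_ms = 20.0 / model.natural_frequency_hz  # 1/(50 f_n) in ms
    elif dt_ms > dt_max:
        raise ConfigError(
            f"dt = {dt_ms} ms does not resolve the dynamics (max {dt_max:.4g} ms)")
    if n_steps is None:
        n_steps = max(int(math.ceil(duration_ms / dt_ms)), 16)
    dt = duration_ms / n_steps
    if dt > dt_max:
        raise ConfigError(
            f"dt = {dt} ms does not resolve the dynamics (max {dt_max:.4g} ms)")
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    v = np.asarray(drive.voltage(t_half), dtype=float)
    vlo, vhi = model.voltage_range
    if v.min() < vlo or v.max() > vhi:
        warnings.warn("drive voltage exceeds the actuator range; clipping",
                      RuntimeWarning, stacklevel=3)
        v = np.clip(v, vlo, vhi)
    p = np.asarray(model.g(v), dtype=float)
    A, B0, B1, B2 = _rk4_matrices(omega, model.damping_ratio, dt)
    p_even, p_odd = p[0::2], p[1::2]
    U = np.outer(p_even[:-1], B0) + np.outer(p_odd, B1) + np.outer(p_even[1:], B2)
    states = _propagate(A, U, x0)
    if not np.all(np.isfinite(states)):
        raise SimulationError("simulation diverged (non-finite state)")
    times = np.arange(n_steps + 1) * dt
    return times, states, dt


def voice_coil_response(
    model: VoiceCoilModel,
    drive,
    dt_ms: float | None = None,
    n_settle_periods: int = 5,
    periodic_tol_um: float = 1e-3,
    x0_um: float | None = None,
) -> FocusTrajectory:
    """Steady periodic focus trajectory of the actuator under a drive.

    Integrates the second-order plant with a fixed-step 4th-order scheme over
    ``n_settle_periods + 1`` drive periods, discards the settling periods,
    and returns the final one.  ``periodic_flag`` records whether the state
    at the period boundaries agrees within ``periodic_tol_um`` (position;
    velocity scaled by ω), i.e. whether a steady periodic state was reached.
    """
    period = drive.period_ms
    x_start = model.g(float(np.clip(drive.voltage(0.0), *model.voltage_range)))
    x0 = np.array([x_start if x0_um is None else float(x0_um), 0.0])
    dt_req = dt_ms if dt_ms is not None else 20.0 / model.natural_frequency_hz
    n_per = max(int(math.ceil(period / dt_req)), 16)  # steps per period
    duration = (n_settle_periods + 1) * period
    times, states, dt = _integrate(model, drive, duration, dt_ms, x0,
                                   n_steps=(n_settle_periods + 1) * n_per)
    i0 = n_settle_periods * n_per
    seg = states[i0:]
    omega = model.omega_per_ms
    d = np.abs(states[i0] - states[-1])
    periodic = bool(d[0] <= periodic_tol_um and d[1] <= periodic_tol_um * omega)
    return FocusTrajectory(
        times_ms=times[i0:] - times[i0],
        positions_um=seg[:, 0].copy(),
        periodic_flag=periodic,
        period_ms=period,
    )


def simulate_transient(
    model: VoiceCoilModel,
    drive,
    duration_ms: float,
    dt_ms: float | None = None,
    x0_um: float = 0.0,
    v0_um_per_ms: float = 0.0,
):
    """Full transient (no settling discard); returns (times_ms, positions_um).

    Used for step-response and frequency-response diagnostics.
    """
    x0 = np.array([x0_um, v0_um_per_ms])
    times, states, _ = _integrate(model, drive, duration_ms, dt_ms, x0)
    return times, states[:, 0].copy()


def shutter_center(t_ms: float, shutter: ShutterConfig) -> float:
    """Position of the active-band centre at time ``t_ms`` within one period.

    Returns :data:`FLYBACK` (NaN) during the flyback segment.  Times outside
    [0, period) raise :class:`OutOfRangeError`.
    """
    if not 0.0 <= t_ms < shutter.period_ms:
        raise OutOfRangeError(
            f"t = {t_ms} ms outside the frame period [0, {shutter.period_ms}) ms")
    if t_ms <= shutter.acquisition_ms:
        return shutter.sweep_origin_um + (t_ms / shutter.acquisition_ms) * shutter.row_extent_um
    return FLYBACK


def _center_array(t_ms: np.ndarray, shutter: ShutterConfig) -> np.ndarray:
    t = np.mod(np.asarray(t_ms, dtype=float), shutter.period_ms)
    c = shutter.sweep_origin_um + (t / shutter.acquisition_ms) * shutter.row_extent_um
    return np.where(t <= shutter.acquisition_ms, c, np.nan)


def sync_error(traj: FocusTrajectory, shutter: ShutterConfig) -> SyncError:
    """Maximum and RMS focus-vs-shutter deviation over the acquisition window.

    Only the acquisition segment counts; the flyback is dead time.  The
    trajectory must cover exactly one full frame period.
    """
    span = traj.times_ms[-1] - traj.times_ms[0]
    dt = np.median(np.diff(traj.times_ms))
    if abs(span - shutter.period_ms) > dt / 2 + 1e-9:
        raise ConfigError(
            f"trajectory spans {span:.6g} ms but the frame period is "
            f"{shutter.period_ms:.6g} ms")
    t_rel = traj.times_ms - traj.times_ms[0]
    wrapped = np.mod(t_rel, shutter.period_ms)
    centers = _center_array(wrapped, shutter)
    # a closed period duplicates its first sample at t = period; drop it
    centers[(t_rel > 0) & (wrapped < dt / 4)] = np.nan
    mask = ~np.isnan(centers)
    dev = np.abs(traj.positions_um[mask] - centers[mask])
    return SyncError(max_abs_um=float(dev.max()), rms_um=float(np.sqrt(np.mean(dev**2))))


def swept_row_profile(
    model: VoiceCoilModel,
    drive,
    shutter: ShutterConfig,
    sheet: SheetSpec,
    trajectory: FocusTrajectory | None = None,
    n_settle_periods: int = 3,
):
    """Per-row focus offset Δ and relative intensity of a swept frame.

    Row ``i`` is exposed when the band centre crosses its position, at
    t_i = (i / n_rows) · acquisition.  The recorded relative intensity of a
    uniform fluorescent slab is the on-axis sheet intensity
    s(Δ) = w0²/w(Δ)² = 1 / (1 + (Δ/z_R)²).

    Returns ``(delta_um, intensity_fraction)`` arrays of length ``n_rows``.
    """
    if trajectory is None:
        trajectory = voice_coil_response(model, drive, n_settle_periods=n_settle_periods)
    rows = np.arange(shutter.n_rows)
    t_rows = rows / shutter.n_rows * shutter.acquisition_ms
    focus = trajectory.position_at(t_rows)
    delta = focus - shutter.row_position_um(rows)
    zr = rayleigh_range(sheet)
    s = 1.0 / (1.0 + (delta / zr) ** 2)
    return delta, s


def render_focus_frame(
    focus_position_um: float,
    shutter: ShutterConfig,
    spot_sigma_um: float = 0.5,
    photons: float = 2000.0,
    background: float = 20.0,
    seed: int | np.random.Generator | None = None,
    n_cols: int = 64,
    noise: bool = True,
) -> np.ndarray:
    """Image of the parked focus spot: an isotropic Gaussian plus background.

    The spot is rendered on a narrow column strip (``n_cols``) because only
    the row coordinate carries information; the full chip width is not
    needed to locate the focus.  With ``noise=False`` the expected image is
    returned (the infinite-photon limit up to a scale).
    """
    px = shutter.effective_pixel_um
    rc = (focus_position_um - shutter.sweep_origin_um) / px
    if not 0.0 <= rc <= shutter.n_rows - 1:
        raise OutOfRangeError(
            f"focus at {focus_position_um} µm falls outside the row extent")
    sig = spot_sigma_um / px
    r = np.arange(shutter.n_rows)
    c = np.arange(n_cols)
    cc = (n_cols - 1) / 2.0
    expected = photons * np.outer(
        np.exp(-0.5 * ((r - rc) / sig) ** 2),
        np.exp(-0.5 * ((c - cc) / sig) ** 2),
    ) + background
    if not noise:
        return expected
    rng = np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.float64)


def render_swept_frame(
    model: VoiceCoilModel,
    drive,
    shutter: ShutterConfig,
    sheet: SheetSpec,
    photons: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    n_cols: int = 32,
    noise: bool = True,
    trajectory: FocusTrajectory | None = None,
) -> np.ndarray:
    """Rolling-shutter frame of a uniform fluorescent slab.

    Each row's expected intensity is ``photons`` scaled by the sheet
    intensity at that row's focus offset (see :func:`swept_row_profile`);
    perfect synchronization yields a flat frame.
    """
    _, s = swept_row_profile(model, drive, shutter, sheet, trajectory=trajectory)
    expected = np.tile((photons * s)[:, None], (1, n_cols))
    if not noise:
        return expected
    rng = np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.float64)


def render_bead_stack(
    shutter: ShutterConfig,
    bead_positions_um: np.ndarray,
    fwhm_xyz_um: tuple[float, float, float],
    z_step_um: float,
    n_planes: int,
    photons: float = 50000.0,
    background: float = 10.0,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
    n_rows: int | None = None,
    n_cols: int | None = None,
) -> ImageStack:
    """3D stack of point-like beads blurred by an anisotropic Gaussian PSF.

    ``bead_positions_um`` is (N, 3) in (z, y, x) µm; plane k sits at
    z = k · z_step, row j at y = j · pixel, column i at x = i · pixel.
    ``fwhm_xyz_um`` is one (x, y, z) triplet shared by all beads, or an
    (N, 3) array of per-bead triplets.  ``photons`` is the integrated
    intensity per bead above background (the Gaussian is area-normalized,
    point-sampled on the voxel grid).  Beads whose centre falls outside the
    volume are skipped with a log entry.
    """
    fwhm_arr = np.atleast_2d(np.asarray(fwhm_xyz_um, dtype=float))
    fz = float(fwhm_arr[:, 2].min())
    if z_step_um > fz / 2:
        warnings.warn(
            f"z step {z_step_um} µm undersamples the axial FWHM {fz} µm "
            "(Nyquist would need fwhm_z / 2)", RuntimeWarning, stacklevel=2)
    px = shutter.effective_pixel_um
    ny = n_rows if n_rows is not None else shutter.n_rows
    nx = n_cols if n_cols is not None else ny
    steps = np.array([z_step_um, px, px])
    sizes = np.array([n_planes, ny, nx])
    expected = np.full(tuple(sizes), float(background))
    extent = (sizes - 1) * steps
    beads = np.atleast_2d(np.asarray(bead_positions_um, dtype=float))
    if fwhm_arr.shape[0] not in (1, beads.shape[0]):
        raise ConfigError("fwhm_xyz_um must be one triplet or one per bead")
    for k, bead in enumerate(beads):
        center_vox = bead / steps
        if np.any(bead < 0) or np.any(bead > extent):
            logger.info("bead %d at %s µm lies outside the volume; skipped", k, bead)
            continue
        fx, fy, fz = fwhm_arr[min(k, fwhm_arr.shape[0] - 1)]
        sigma_um = np.array([fz, fy, fx]) / _FWHM_PER_SIGMA
        sigma_vox = sigma_um / steps
        amp = photons * np.prod(steps / (sigma_um * math.sqrt(2.0 * math.pi)))
        lo = np.maximum(np.ceil(center_vox - 4.5 * sigma_vox).astype(int), 0)
        hi = np.minimum(np.floor(center_vox + 4.5 * sigma_vox).astype(int), sizes - 1)
        profs = [
            np.exp(-0.5 * ((np.arange(lo[a], hi[a] + 1) - center_vox[a]) / sigma_vox[a]) ** 2)
            for a in range(3)
        ]
        expected[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += (
            amp * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
        )
    if noise:
        rng = np.random.default_rng(seed)
        data = rng.poisson(expected).astype(np.float64)
    else:
        data = expected
    return ImageStack(data=data, voxel_size_um=(z_step_um, px, px))
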