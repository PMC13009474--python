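import math

import numpy as np
import pytest

from aslmsim.config import default_config
from aslmsim.errors import ConfigError, OutOfRangeError
from aslmsim.instrument import (
    FLYBACK,
    DriveWaveform,
    FocusTrajectory,
    SampledDrive,
    ShutterConfig,
    VoiceCoilModel,
    render_bead_stack,
    render_focus_frame,
    render_swept_frame,
    shutter_center,
    simulate_transient,
    swept_row_profile,
    sync_error,
    voice_coil_response,
)
from aslmsim.optics import SheetSpec, rayleigh_range


def linear_model(fn=100.0, zeta=0.5):
    return VoiceCoilModel(fn, zeta, (0.0, 1.0), (-2.0, 2.0), (-3.0, 3.0))


def constant_drive(level, period=100.0):
    return SampledDrive(np.array([0.0, period / 2]), np.array([level, level]), period)


class TestSecondOrderPlant:
    @pytest.mark.parametrize("zeta", [0.3, 0.5, 0.7])
    def test_step_overshoot_matches_closed_form(self, zeta):
        model = linear_model(zeta=zeta)
        _, x = simulate_transient(model, constant_drive(1.0), 60.0, x0_um=0.0)
        overshoot = x.max() - 1.0
        exact = math.exp(-math.pi * zeta / math.sqrt(1 - zeta**2))
        assert overshoot == pytest.approx(exact, rel=0.01)

    @pytest.mark.parametrize("ratio", [0.3, 1.0, 2.0])
    def test_sinusoid_amplitude_matches_frequency_response(self, ratio):
        zeta = 0.5
        model = linear_model(zeta=zeta)
        period = 1000.0 / (ratio * model.natural_frequency_hz)
        t = np.linspace(0.0, period, 400, endpoint=False)
        drive = SampledDrive(t, np.sin(2 * np.pi * t / period), period)
        traj = voice_coil_response(model, drive, n_settle_periods=30)
        amp = (traj.positions_um.max() - traj.positions_um.min()) / 2
        exact = 1 / math.sqrt((1 - ratio**2) ** 2 + (2 * zeta * ratio) ** 2)
        assert amp == pytest.approx(exact, rel=0.01)

    def test_constant_drive_converges_to_static_map(self):
        model = VoiceCoilModel(200.0, 0.6, (1.0, 2.0, 0.5), (-1.0, 1.0), (-2.0, 4.0))
        traj = voice_coil_response(model, constant_drive(0.5), n_settle_periods=5)
        assert traj.periodic_flag
        assert traj.positions_um == pytest.approx(
            np.full_like(traj.positions_um, model.g(0.5)), abs=1e-6)

    def test_quasi_static_drive_tracks_static_map(self):
        model = linear_model(fn=200.0)
        period = 1000.0 / (model.natural_frequency_hz / 100)  # f = f_n/100
        t = np.linspace(0.0, period, 200, endpoint=False)
        v = 0.5 + 0.5 * np.sin(2 * np.pi * t / period)
        drive = SampledDrive(t, v, period)
        traj = voice_coil_response(model, drive, n_settle_periods=5)
        target = model.g(drive.voltage(traj.times_ms))
        sweep_range = target.max() - target.min()
        assert np.max(np.abs(traj.positions_um - target)) < 0.01 * sweep_range

    def test_steady_state_independent_of_initial_conditions(self):
        model = linear_model()
        t = np.linspace(0.0, 50.0, 100, endpoint=False)
        drive = SampledDrive(t, np.sin(2 * np.pi * t / 50.0), 50.0)
        a = voice_coil_response(model, drive, n_settle_periods=10, x0_um=0.0)
        b = voice_coil_response(model, drive, n_settle_periods=10, x0_um=2.0)
        assert a.positions_um == pytest.approx(b.positions_um, abs=1e-6)

    def test_undersampled_dt_rejected(self):
        with pytest.raises(ConfigError):
            voice_coil_response(linear_model(fn=1000.0), constant_drive(1.0), dt_ms=1.0)


class TestDriveWaveform:
    @pytest.mark.parametrize("mode", ["linear_return", "cubic_return", "smooth_return"])
    def test_voltage_is_periodic_and_continuous(self, mode):
        wf = DriveWaveform((0.1, 1.0, -0.3, 0.2), 26.0, 24.0, flyback_mode=mode)
        eps = 1e-9
        assert wf.voltage(50.0 - eps) == pytest.approx(wf.voltage(0.0), abs=1e-6)
        assert wf.voltage(26.0 - eps) == pytest.approx(wf.voltage(26.0 + eps), abs=1e-6)
        assert wf.voltage(73.0) == pytest.approx(wf.voltage(23.0))

    def test_smooth_return_slope_continuity(self):
        wf = DriveWaveform((0.1, 1.0, -0.3, 0.2), 26.0, 24.0, flyback_mode="smooth_return")
        h = 1e-4
        for boundary in (26.0, 50.0):
            before = (wf.voltage(boundary - h) - wf.voltage(boundary - 2 * h)) / h
            after = (wf.voltage(boundary + 2 * h) - wf.voltage(boundary + h)) / h
            assert before == pytest.approx(after, abs=1e-2)

    def test_out_of_range_drive_clipped_with_warning(self):
        model = linear_model()
        wf = DriveWaveform((0.0, 5.0, 0.0, 0.0), 26.0, 24.0)  # exceeds ±2 V
        with pytest.warns(RuntimeWarning, match="clipping"):
            voice_coil_response(model, wf, n_settle_periods=1)


class TestShutter:
    shutter = ShutterConfig(n_rows=320, shutter_width_rows=8, acquisition_ms=76.0,
                            flyback_ms=24.0, effective_pixel_um=0.203125)

    def test_center_endpoints_and_linearity(self):
        extent = self.shutter.row_extent_um
        assert shutter_center(0.0, self.shutter) == 0.0
        assert shutter_center(38.0, self.shutter) == pytest.approx(extent / 2)
        assert shutter_center(19.0, self.shutter) == pytest.approx(extent / 4)

    def test_flyback_marker_and_range_errors(self):
        assert math.isnan(shutter_center(80.0, self.shutter))
        assert math.isnan(FLYBACK)
        with pytest.raises(OutOfRangeError):
            shutter_center(100.0, self.shutter)
        with pytest.raises(OutOfRangeError):
            shutter_center(-1.0, self.shutter)

    def test_with_frame_rate_keeps_flyback(self):
        s = self.shutter.with_frame_rate(20.0)
        assert s.acquisition_ms == pytest.approx(26.0)
        assert s.flyback_ms == 24.0
        with pytest.raises(ConfigError):
            self.shutter.with_frame_rate(50.0)


class TestSyncError:
    shutter = ShutterConfig(n_rows=320, shutter_width_rows=8, acquisition_ms=76.0,
                            flyback_ms=24.0, effective_pixel_um=0.203125)

    def make_traj(self, offset=0.0, slope_factor=1.0):
        t = np.linspace(0.0, 100.0, 2001)
        extent = self.shutter.row_extent_um
        centers = np.where(t <= 76.0, t / 76.0 * extent, 0.0)
        pos = np.where(t <= 76.0, slope_factor * t / 76.0 * extent + offset, 0.0)
        return FocusTrajectory(t, pos, True, 100.0), centers

    def test_perfect_sync_is_zero(self):
        traj, _ = self.make_traj()
        err = sync_error(traj, self.shutter)
        assert err.max_abs_um == 0.0 and err.rms_um == 0.0

    def test_constant_offset(self):
        traj, _ = self.make_traj(offset=1.25)
        err = sync_error(traj, self.shutter)
        assert err.max_abs_um == pytest.approx(1.25)
        assert err.rms_um == pytest.approx(1.25)

    def test_slope_mismatch_peaks_at_window_end(self):
        eps = 0.02
        traj, _ = self.make_traj(slope_factor=1 + eps)
        err = sync_error(traj, self.shutter)
        assert err.max_abs_um == pytest.approx(eps * self.shutter.row_extent_um, rel=1e-6)

    def test_invariant_under_period_shift(self):
        traj, _ = self.make_traj(offset=0.7)
        shifted = FocusTrajectory(traj.times_ms + 100.0, traj.positions_um, True, 100.0)
        a = sync_error(traj, self.shutter)
        b = sync_error(shifted, self.shutter)
        assert b.max_abs_um == pytest.approx(a.max_abs_um, abs=1e-9)
        assert b.rms_um == pytest.approx(a.rms_um, abs=1e-9)

    def test_period_mismatch_rejected(self):
        t = np.linspace(0.0, 60.0, 100)
        traj = FocusTrajectory(t, np.zeros_like(t), True, 100.0)
        with pytest.raises(ConfigError):
            sync_error(traj, self.shutter)


class TestRenderFocusFrame:
    shutter = ShutterConfig(n_rows=200, shutter_width_rows=8, acquisition_ms=26.0,
                            flyback_ms=24.0, effective_pixel_um=0.5)

    def test_noise_free_argmax_is_nearest_row(self):
        img = render_focus_frame(30.2, self.shutter, noise=False)
        assert np.unravel_index(np.argmax(img), img.shape)[0] == round(30.2 / 0.5)

    def test_seed_determinism(self):
        a = render_focus_frame(30.0, self.shutter, seed=7)
        b = render_focus_frame(30.0, self.shutter, seed=7)
        assert np.array_equal(a, b)

    def test_half_row_spot_straddles_equally(self):
        img = render_focus_frame(30.25, self.shutter, noise=False)  # row 60.5
        assert img[60].sum() == pytest.approx(img[61].sum())

    def test_out_of_fov_rejected(self):
        with pytest.raises(OutOfRangeError):
            render_focus_frame(120.0, self.shutter)  # extent is 100 µm


class TestRenderSweptFrame:
    shutter = ShutterConfig(n_rows=100, shutter_width_rows=8, acquisition_ms=26.0,
                            flyback_ms=24.0, effective_pixel_um=0.5)
    sheet = SheetSpec(waist_um=0.4, wavelength_nm=488.0)

    def perfect_traj(self, offset=0.0):
        t = np.linspace(0.0, 50.0, 2001)
        extent = self.shutter.row_extent_um
        pos = np.where(t <= 26.0, t / 26.0 * extent, 0.0) + offset
        return FocusTrajectory(t, pos, True, 50.0)

    def test_perfect_sync_gives_flat_frame(self):
        img = render_swept_frame(None, None, self.shutter, self.sheet,
                                 noise=False, trajectory=self.perfect_traj())
        rows = img.mean(axis=1)
        assert np.max(np.abs(rows - rows[0])) / rows[0] < 1e-9

    def test_offset_by_rayleigh_range_halves_intensity(self):
        zr = rayleigh_range(self.sheet)
        _, s = swept_row_profile(None, None, self.shutter, self.sheet,
                                 trajectory=self.perfect_traj(offset=zr))
        assert s == pytest.approx(np.full_like(s, 0.5), rel=1e-9)

    def test_sign_of_offset_is_irrelevant(self):
        _, s_plus = swept_row_profile(None, None, self.shutter, self.sheet,
                                      trajectory=self.perfect_traj(offset=0.3))
        _, s_minus = swept_row_profile(None, None, self.shutter, self.sheet,
                                       trajectory=self.perfect_traj(offset=-0.3))
        assert s_plus == pytest.approx(s_minus, rel=1e-9)


class TestRenderBeadStack:
    shutter = ShutterConfig(n_rows=64, shutter_width_rows=8, acquisition_ms=26.0,
                            flyback_ms=24.0, effective_pixel_um=0.2)

    def test_centered_bead_peaks_at_center_voxel(self):
        stack = render_bead_stack(self.shutter, [[4.0, 6.0, 6.0]],
                                  (0.6, 0.6, 0.45), 0.2, 41, background=0.0,
                                  noise=False)
        assert np.unravel_index(np.argmax(stack.data), stack.data.shape) == (20, 30, 30)

    def test_integrated_intensity_matches_photon_budget(self):
        stack = render_bead_stack(self.shutter, [[4.0, 6.0, 6.0]],
                                  (0.6, 0.6, 0.45), 0.2, 41, photons=1e4,
                                  background=0.0, noise=False)
        assert stack.data.sum() == pytest.approx(1e4, rel=0.01)

    def test_seeded_render_reproducible(self):
        beads = [[2.0, 3.0, 3.0], [6.0, 9.0, 9.0]]
        a = render_bead_stack(self.shutter, beads, (0.6, 0.6, 0.45), 0.2, 41, seed=3)
        b = render_bead_stack(self.shutter, beads, (0.6, 0.6, 0.45), 0.2, 41, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_outside_bead_skipped(self, caplog):
        import logging
        with caplog.at_level(logging.INFO, logger="aslmsim"):
            stack = render_bead_stack(self.shutter, [[4.0, 6.0, 6.0], [50.0, 6.0, 6.0]],
                                      (0.6, 0.6, 0.45), 0.2, 41, photons=1e4,
                                      background=0.0, noise=False)
        assert stack.data.sum() == pytest.approx(1e4, rel=0.01)  # only one bead rendered
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_undersampled_z_warns(self):
        with pytest.warns(RuntimeWarning, match="undersamples"):
            render_bead_stack(self.shutter, [[4.0, 6.0, 6.0]], (0.6, 0.6, 0.3),
                              0.2, 41, noise=False)


def test_default_twin_narrative(twin):
    """The reference twin's frame timing and geometry match its design intent."""
    assert twin.shutter.period_ms == pytest.approx(50.0)  # 20 fps
    assert twin.shutter.row_extent_um == pytest.approx(650.0)
    zr = rayleigh_range(twin.sheet)
    half_shutter = twin.shutter.shutter_width_rows / 2 * twin.shutter.effective_pixel_um
    assert zr == pytest.approx(half_shutter, rel=1e-6)
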