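"""First-principles optical geometry, sampling, and timing arithmetic.

The quantities computed here are the back-of-the-envelope numbers an
instrument designer checks before building a light-sheet microscope:
effective pixel size at the camera, field of view, diffraction-limited
resolution (Rayleigh criterion), objective pupil diameter, Gaussian-beam
sheet thickness, frame rate from shutter timing, and raw voxel throughput.

Lengths are micrometres internally; nanometres and millimetres appear only
at API boundaries and are converted explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError

__all__ = [
    "OpticalConfig",
    "SheetSpec",
    "effective_pixel_size",
    "field_of_view",
    "rayleigh_lateral_resolution",
    "pupil_diameter",
    "sheet_thickness",
    "rayleigh_range",
    "waist_for_rayleigh_range",
    "frame_rate_from_timing",
    "voxel_rate",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Static optical and camera geometry of the instrument.

    Parameters
    ----------
    detection_na : numerical aperture of the detection objective.
    illumination_na : numerical aperture of the illumination objective.
    magnification : nominal magnification ``M`` of the detection objective.
    changer_factor : additional magnification from a changer lens (1 if none).
    tube_lens_focal_mm : nominal tube-lens focal length ``f_TL`` in mm.
    pixel_pitch_um : physical camera pixel pitch in µm.
    n_rows, n_cols : camera chip geometry in pixels.
    refractive_index : immersion-medium refractive index ``n``.
    emission_range_nm : (low, high) emission wavelength band in nm.
    """

    detection_na: float
    illumination_na: float
    magnification: float
    changer_factor: float
    tube_lens_focal_mm: float
    pixel_pitch_um: float
    n_rows: int
    n_cols: int
    refractive_index: float
    emission_range_nm: tuple[float, float]

    def __post_init__(self) -> None:
        positive = {
            "detection_na": self.detection_na,
            "illumination_na": self.illumination_na,
            "magnification": self.magnification,
            "changer_factor": self.changer_factor,
            "tube_lens_focal_mm": self.tube_lens_focal_mm,
            "pixel_pitch_um": self.pixel_pitch_um,
            "refractive_index": self.refractive_index,
        }
        for name, value in positive.items():
            if not (value > 0 and math.isfinite(value)):
                raise ConfigError(f"{name} must be positive and finite, got {value}")
        if self.detection_na > self.refractive_index:
            raise ConfigError(
                f"detection_na ({self.detection_na}) cannot exceed the "
                f"refractive index ({self.refractive_index})"
            )
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("n_rows and n_cols must be at least 1")
        lo, hi = self.emission_range_nm
        if not (0 < lo <= hi):
            raise ConfigError(f"emission range must satisfy 0 < low <= high, got {lo}, {hi}")


@dataclass(frozen=True)
class SheetSpec:
    """Gaussian light-sheet description.

    ``waist_um`` is the 1/e² half-width w0 at focus; the sheet's depth of
    focus is twice the Rayleigh range z_R = π w0² n / λ.
    """

    waist_um: float
    wavelength_nm: float
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if not self.waist_um > 0:
            raise ConfigError(f"waist must be positive, got {self.waist_um}")
        if not 300.0 <= self.wavelength_nm <= 800.0:
            raise ConfigError(
                f"wavelength {self.wavelength_nm} nm outside sanity bounds 300-800 nm"
            )
        if not self.refractive_index > 0:
            raise ConfigError("refractive index must be positive")


def effective_pixel_size(cfg: OpticalConfig) -> float:
    """Camera pixel pitch projected into sample space, in µm.

    ``pixel_pitch / (magnification * changer_factor)``.
    """
    return cfg.pixel_pitch_um / (cfg.magnification * cfg.changer_factor)


def field_of_view(cfg: OpticalConfig, effective_pixel_um: float) -> tuple[float, float]:
    """(width, height) of the imaged field in µm for a given effective pixel.

    Width spans the columns, height the rows.
    """
    if not effective_pixel_um > 0:
        raise ConfigError(f"effective pixel must be positive, got {effective_pixel_um}")
    return (cfg.n_cols * effective_pixel_um, cfg.n_rows * effective_pixel_um)


def rayleigh_lateral_resolution(
    wavelength_nm: float, na: float, round_to_nm: float | None = None
) -> float:
    """Rayleigh-criterion lateral resolution 0.61 λ / NA, in nm.

    If ``round_to_nm`` is given, the result is rounded to the nearest
    multiple of that granularity (design summaries typically quote 10 nm).
    """
    if not na > 0:
        raise ConfigError(f"NA must be positive, got {na}")
    r = 0.61 * wavelength_nm / na
    if round_to_nm is not None:
        if not round_to_nm > 0:
            raise ConfigError("rounding granularity must be positive")
        r = round(r / round_to_nm) * round_to_nm
    return r


def pupil_diameter(na: float, tube_lens_focal_mm: float, magnification: float) -> float:
    """Back-pupil diameter D = 2 NA f_TL / M, in mm."""
    if not (na > 0 and tube_lens_focal_mm > 0 and magnification > 0):
        raise ConfigError("NA, tube-lens focal length, and magnification must be positive")
    return 2.0 * na * tube_lens_focal_mm / magnification


def rayleigh_range(spec: SheetSpec) -> float:
    """Rayleigh range z_R = π w0² n / λ of the sheet, in µm."""
    lam_um = spec.wavelength_nm * 1e-3
    return math.pi * spec.waist_um**2 * spec.refractive_index / lam_um


def waist_for_rayleigh_range(
    rayleigh_range_um: float, wavelength_nm: float, refractive_index: float = 1.33
) -> float:
    """Waist w0 whose Rayleigh range equals ``rayleigh_range_um``, in µm.

    Convenience inverse of :func:`rayleigh_range`, used to build a sheet
    whose depth of focus (2 z_R) matches the rolling-shutter width.
    """
    if not rayleigh_range_um > 0:
        raise ConfigError("Rayleigh range must be positive")
    lam_um = wavelength_nm * 1e-3
    return math.sqrt(rayleigh_range_um * lam_um / (math.pi * refractive_index))


def sheet_thickness(spec: SheetSpec, z_um: float) -> float:
    """Gaussian-beam half-width w(z) = w0 sqrt(1 + (z/z_R)²), in µm."""
    zr = rayleigh_range(spec)
    return spec.waist_um * math.sqrt(1.0 + (z_um / zr) ** 2)


def frame_rate_from_timing(acquisition_ms: float, flyback_ms: float) -> float:
    """Frame rate in fps for a frame of acquisition + flyback milliseconds."""
    if acquisition_ms < 0 or flyback_ms < 0:
        raise ConfigError("timings must be non-negative")
    total = acquisition_ms + flyback_ms
    if not total > 0:
        raise ConfigError("acquisition + flyback must be positive")
    return 1000.0 / total


def voxel_rate(n_rows: int, n_cols: int, fps: float) -> float:
    """Raw pixel throughput rows × cols × fps, in Mvoxels/s.

    This is the literal product for a full-chip readout. Published
    throughput figures may use an effective (cropped) row count, so the
    product for the full chip can exceed a quoted rate.
    """
    if not (n_rows > 0 and n_cols > 0 and fps > 0):
        raise ConfigError("rows, cols, and fps must be positive")
    return n_rows * n_cols * fps / 1e6
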