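"""Run configuration: the instrument twin assembled from a YAML file.

A :class:`RunConfig` bundles the four physical sub-models (optical geometry,
voice-coil actuator, rolling shutter, light sheet) plus rendering defaults,
and cross-validates them: the shutter's effective pixel must equal the one
implied by the optics, and the swept row extent must lie inside the
actuator's reachable position range.

``default_config()`` builds the reference twin: a 3.2k × 3.2k chip with
6.5 µm pixels behind a 20× objective and a 1.6× magnification changer
(203.125 nm effective pixel, 650 µm row extent), an 8-row rolling shutter,
26 + 24 ms frame timing (20 fps), and a light sheet whose Rayleigh range
equals half the shutter width.  The voice-coil parameters are plausible
stand-ins for a fast focusing actuator, not measurements of any particular
device: a cubic static map over ±1 V and second-order dynamics fast enough
that a quasi-static drive tracks at 1 fps yet slow enough that inertia
breaks naive synchronization at 20 fps.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .instrument import ShutterConfig, VoiceCoilModel
from .optics import OpticalConfig, SheetSpec, effective_pixel_size, waist_for_rayleigh_range

__all__ = ["RenderSettings", "RunConfig", "default_config", "load_config", "config_hash"]


@dataclass(frozen=True)
class RenderSettings:
    """Photon budget and spot shape used by the synthetic renders."""

    spot_sigma_um: float = 0.5
    photons: float = 2000.0
    background: float = 20.0

    def __post_init__(self) -> None:
        if not (self.spot_sigma_um > 0 and self.photons > 0 and self.background >= 0):
            raise ConfigError("render settings must be positive (background >= 0)")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved instrument twin."""

    optics: OpticalConfig
    voice_coil: VoiceCoilModel
    shutter: ShutterConfig
    sheet: SheetSpec
    render: RenderSettings = field(default_factory=RenderSettings)
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        px_optics = effective_pixel_size(self.optics)
        px_shutter = self.shutter.effective_pixel_um
        if abs(px_optics - px_shutter) > 1e-9:
            raise ConfigError(
                f"shutter.effective_pixel_um = {px_shutter} but the optics imply "
                f"{px_optics} (pitch / (M × changer)); the two must agree")
        lo = self.shutter.sweep_origin_um
        hi = lo + self.shutter.row_extent_um
        plo, phi = self.voice_coil.position_range_um
        if lo < plo or hi > phi:
            raise ConfigError(
                f"shutter row extent [{lo}, {hi}] µm exceeds the voice-coil "
                f"position range [{plo}, {phi}] µm")

    def to_dict(self) -> dict:
        """Resolved configuration as a plain, YAML/JSON-serializable dict."""
        return {
            "optics": {
                "detection_na": self.optics.detection_na,
                "illumination_na": self.optics.illumination_na,
                "magnification": self.optics.magnification,
                "changer_factor": self.optics.changer_factor,
                "tube_lens_focal_mm": self.optics.tube_lens_focal_mm,
                "pixel_pitch_um": self.optics.pixel_pitch_um,
                "n_rows": self.optics.n_rows,
                "n_cols": self.optics.n_cols,
                "refractive_index": self.optics.refractive_index,
                "emission_range_nm": list(self.optics.emission_range_nm),
            },
            "voice_coil": {
                "natural_frequency_hz": self.voice_coil.natural_frequency_hz,
                "damping_ratio": self.voice_coil.damping_ratio,
                "static_map_coeffs": list(self.voice_coil.static_map_coeffs),
                "voltage_range": list(self.voice_coil.voltage_range),
                "position_range_um": list(self.voice_coil.position_range_um),
            },
            "shutter": {
                "n_rows": self.shutter.n_rows,
                "shutter_width_rows": self.shutter.shutter_width_rows,
                "acquisition_ms": self.shutter.acquisition_ms,
                "flyback_ms": self.shutter.flyback_ms,
                "effective_pixel_um": self.shutter.effective_pixel_um,
                "sweep_origin_um": self.shutter.sweep_origin_um,
            },
            "sheet": {
                "waist_um": self.sheet.waist_um,
                "wavelength_nm": self.sheet.wavelength_nm,
                "refractive_index": self.sheet.refractive_index,
            },
            "render": {
                "spot_sigma_um": self.render.spot_sigma_um,
                "photons": self.render.photons,
                "background": self.render.background,
            },
            "seed": self.seed,
        }


_SECTION_FIELDS = {
    "optics": {
        "detection_na", "illumination_na", "magnification", "changer_factor",
        "tube_lens_focal_mm", "pixel_pitch_um", "n_rows", "n_cols",
        "refractive_index", "emission_range_nm",
    },
    "voice_coil": {
        "natural_frequency_hz", "damping_ratio", "static_map_coeffs",
        "voltage_range", "position_range_um",
    },
    "shutter": {
        "n_rows", "shutter_width_rows", "acquisition_ms", "flyback_ms",
        "effective_pixel_um", "sweep_origin_um",
    },
    "sheet": {"waist_um", "wavelength_nm", "refractive_index"},
    "render": {"spot_sigma_um", "photons", "background"},
}


def _default_dict() -> dict:
    excitation_nm = 488.0
    shutter = {
        "n_rows": 3200,
        "shutter_width_rows": 8,
        "acquisition_ms": 26.0,
        "flyback_ms": 24.0,
        "effective_pixel_um": 6.5 / (20.0 * 1.6),
        "sweep_origin_um": 0.0,
    }
    half_width_um = shutter["shutter_width_rows"] / 2 * shutter["effective_pixel_um"]
    return {
        "optics": {
            "detection_na": 1.0,
            "illumination_na": 0.64,
            "magnification": 20.0,
            "changer_factor": 1.6,
            "tube_lens_focal_mm": 180.0,
            "pixel_pitch_um": 6.5,
            "n_rows": 3200,
            "n_cols": 3200,
            "refractive_index": 1.33,
            "emission_range_nm": [510.0, 700.0],
        },
        "voice_coil": {
            "natural_frequency_hz": 800.0,
            "damping_ratio": 0.7,
            "static_map_coeffs": [325.0, 330.0, 0.0, 35.0],
            "voltage_range": [-1.0, 1.0],
            "position_range_um": [-40.0, 690.0],
        },
        "shutter": shutter,
        "sheet": {
            # Rayleigh range matched to half the rolling-shutter width, so the
            # sheet's depth of focus equals the shutter width.
            "waist_um": waist_for_rayleigh_range(half_width_um, excitation_nm, 1.33),
            "wavelength_nm": excitation_nm,
            "refractive_index": 1.33,
        },
        "render": {"spot_sigma_um": 0.5, "photons": 2000.0, "background": 20.0},
        "seed": 0,
    }


def _build(raw: dict, output_dir: Path | None = None) -> RunConfig:
    def section(name: str) -> dict:
        data = dict(raw.get(name, {}))
        unknown = set(data) - _SECTION_FIELDS[name]
        for key in sorted(unknown):
            warnings.warn(f"ignoring unknown config key {name}.{key}", stacklevel=3)
            data.pop(key)
        return data

    opt = section("optics")
    opt["emission_range_nm"] = tuple(opt["emission_range_nm"])
    vc = section("voice_coil")
    vc["static_map_coeffs"] = tuple(vc["static_map_coeffs"])
    vc["voltage_range"] = tuple(vc["voltage_range"])
    vc["position_range_um"] = tuple(vc["position_range_um"])
    return RunConfig(
        optics=OpticalConfig(**opt),
        voice_coil=VoiceCoilModel(**vc),
        shutter=ShutterConfig(**section("shutter")),
        sheet=SheetSpec(**section("sheet")),
        render=RenderSettings(**section("render")),
        seed=int(raw.get("seed", 0)),
        output_dir=output_dir,
    )


def default_config(**overrides) -> RunConfig:
    """The reference twin (see module docstring); section dicts may be overridden."""
    raw = _default_dict()
    for key, value in overrides.items():
        if isinstance(value, dict) and key in raw:
            raw[key].update(value)
        else:
            raw[key] = value
    return _build(raw)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML configuration, fill defaults, and cross-validate.

    Unknown keys produce warnings rather than errors, so configuration files
    written for newer versions still load.
    """
    path = Path(path)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path} does not contain a YAML mapping")
    raw = _default_dict()
    for key, value in user.items():
        if key in _SECTION_FIELDS and isinstance(value, dict):
            raw[key].update(value)
        elif key in ("seed", "output_dir"):
            raw[key] = value
        elif key in raw:
            raw[key] = value
        else:
            warnings.warn(f"ignoring unknown config key {key}", stacklevel=2)
    out_dir = raw.pop("output_dir", None)
    cfg = _build(raw, output_dir=Path(out_dir) if out_dir else None)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short SHA-256 of the resolved configuration, for artifact provenance."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
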