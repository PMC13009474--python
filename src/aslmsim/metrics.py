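"""Bead-based resolution characterization and brightness-uniformity metrics.

Resolution is quantified the way bead measurements are normally reported:
the full width at half maximum (FWHM) of each bead's intensity line
profiles along X, Y, and Z, pooled into a population mean ± standard
deviation per axis.  The estimator works on the raw line profiles (no
Gaussian fitting): each profile is band-limit interpolated (Fourier
zero-padding) onto a 16× finer grid and the half-maximum crossings are
then located by linear interpolation on that grid.  For Nyquist-sampled
profiles this reduces the chord bias of direct linear interpolation
(several percent at two to three samples per FWHM) to well below one
percent without assuming any peak shape.

Axis convention: Z is the detection optical axis (stack planes), Y the
sweep/row axis, X the orthogonal in-plane axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .errors import AslmSimError, ConfigError
from .stacks import ImageStack

__all__ = [
    "BeadMeasurement",
    "ResolutionSummary",
    "UniformityProfile",
    "detect_beads",
    "measure_fwhm",
    "summarize_resolution",
    "brightness_uniformity",
    "depth_brightness",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class BeadMeasurement:
    """Per-bead three-axis FWHM measurement."""

    center_voxel: tuple[int, int, int]  # (z, y, x) indices
    center_um: tuple[float, float, float]
    fwhm_um: tuple[float, float, float] | None  # (x, y, z); None when invalid
    peak_intensity: float
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class ResolutionSummary:
    """Population statistics of one resolution axis."""

    axis: str  # "lateral" or "axial"
    mean_um: float
    std_um: float
    n: int


@dataclass
class UniformityProfile:
    """Averaged line profile across the field and its fractional spread."""

    axis: str  # "X" or "Y"
    positions_px: np.ndarray
    profile: np.ndarray
    mean_level: float
    max_fractional_deviation: float


def detect_beads(
    stack: ImageStack,
    intensity_threshold: float,
    min_separation_um: float = 2.0,
    edge_margin_um: float = 1.0,
) -> list[tuple[int, int, int]]:
    """Candidate bead centres: bright, well-separated local maxima.

    Local maxima above ``intensity_threshold`` are pruned greedily
    (brightest first) to a pairwise distance of at least
    ``min_separation_um``; candidates within ``edge_margin_um`` of any face
    are dropped so their profiles stay measurable.
    """
    voxel = np.array(stack.require_voxel_size())
    data = np.asarray(stack.data, dtype=float)
    min_sep_vox = max(int(np.floor(min_separation_um / voxel.max())), 1)
    peaks = peak_local_max(data, min_distance=min_sep_vox,
                           threshold_abs=intensity_threshold, exclude_border=False)
    if peaks.size == 0:
        return []
    # greedy µm-metric pruning, brightest kept
    heights = data[tuple(peaks.T)]
    order = np.argsort(heights)[::-1]
    peaks_um = peaks * voxel
    kept: list[int] = []
    for idx in order:
        if all(np.linalg.norm(peaks_um[idx] - peaks_um[j]) >= min_separation_um
               for j in kept):
            kept.append(int(idx))
    extent = (np.array(data.shape) - 1) * voxel
    out = []
    for idx in kept:
        pos = peaks_um[idx]
        if np.all(pos >= edge_margin_um) and np.all(pos <= extent - edge_margin_um):
            out.append(tuple(int(c) for c in peaks[idx]))
    out.sort()
    return out


def _bandlimited_upsample(q: np.ndarray, factor: int) -> np.ndarray:
    """Fourier zero-padding interpolation onto a ``factor`` × finer grid."""
    n = q.size
    spectrum = np.fft.rfft(q)
    m = n * factor
    padded = np.zeros(m // 2 + 1, dtype=complex)
    padded[: spectrum.size] = spectrum
    if n % 2 == 0:
        padded[spectrum.size - 1] *= 0.5  # split the Nyquist bin
    return np.fft.irfft(padded, m) * factor


def _profile_fwhm(
    profile: np.ndarray,
    peak_idx: int,
    step_um: float,
    upsample: int = 16,
    crop_halfwidth_um: float = 2.5,
) -> tuple[float | None, str]:
    """FWHM of a 1D profile around ``peak_idx``; returns (fwhm_um, reason).

    The profile is cropped to ± ``crop_halfwidth_um`` around the peak
    (keeping neighbouring beads out of the measurement) and the median of
    the dimmer half of the crop — a robust local background even when a
    neighbour's flank reaches the crop — is subtracted.  Half-maximum
    crossings are found by linear interpolation on the band-limit
    interpolated crop.  Validity rules are applied on the raw samples: a
    peak carried by fewer than 3 contiguous raw samples above half maximum
    counts as undersampled, and a crossing that runs off the crop is
    unbracketed (clipped at a stack edge or crowded by a neighbour).
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        return None, "profile too short"
    halfwidth = max(int(math.ceil(crop_halfwidth_um / step_um)), 12)
    lo = max(peak_idx - halfwidth, 0)
    hi = min(peak_idx + halfwidth + 1, p.size)
    q = p[lo:hi]
    n = q.size
    if n < 5:
        return None, "profile too short"
    dim_half = np.sort(q)[: max(n // 2, 1)]
    background = float(np.median(dim_half))
    q = q - background
    k_raw = peak_idx - lo
    if q[k_raw] <= 0:
        return None, "no intensity above background"
    qq = _bandlimited_upsample(q, upsample)
    # sub-sample peak: search within ± one raw sample of the known maximum
    k0 = k_raw * upsample
    w = upsample
    sl = slice(max(k0 - w, 0), min(k0 + w + 1, qq.size))
    k = sl.start + int(np.argmax(qq[sl]))
    amp = qq[k]
    if amp <= 0:
        return None, "no intensity above background"
    half = amp / 2.0
    # contiguous above-half run through the peak
    run = 1 if q[k_raw] > half else 0
    for d in (-1, 1):
        i = k_raw + d
        while 0 <= i < n and q[i] > half:
            run += 1
            i += d
    if run < 3:
        return None, "undersampled (fewer than 3 samples above half max)"

    def crossing(direction: int) -> float | None:
        i = k
        while 0 <= i + direction < qq.size and qq[i + direction] > half:
            i += direction
        j = i + direction
        if not 0 <= j < qq.size:
            return None
        return i + (half - qq[i]) / (qq[j] - qq[i]) * direction

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return None, "unbracketed half-max"
    return (right - left) / upsample * step_um, ""


def measure_fwhm(stack: ImageStack, center: tuple[int, int, int]) -> BeadMeasurement:
    """Three-axis FWHM of one bead from its line profiles through the maximum.

    ``center`` must index a local maximum (z, y, x).  Undersampled or
    edge-clipped profiles mark the bead invalid with a reason rather than
    raising.
    """
    voxel = stack.require_voxel_size()
    data = np.asarray(stack.data, dtype=float)
    z, y, x = (int(c) for c in center)
    if not (0 <= z < data.shape[0] and 0 <= y < data.shape[1] and 0 <= x < data.shape[2]):
        raise ConfigError(f"center {center} outside the stack {data.shape}")
    profiles = {
        "z": (data[:, y, x], voxel[0]),
        "y": (data[z, :, x], voxel[1]),
        "x": (data[z, y, :], voxel[2]),
    }
    peak_idx = {"z": z, "y": y, "x": x}
    center_um = (z * voxel[0], y * voxel[1], x * voxel[2])
    fwhm = {}
    for axis, (prof, step) in profiles.items():
        value, reason = _profile_fwhm(prof, peak_idx[axis], step)
        if value is None:
            return BeadMeasurement(
                center_voxel=(z, y, x), center_um=center_um, fwhm_um=None,
                peak_intensity=float(data[z, y, x]), valid=False,
                reason=f"{axis}: {reason}")
        fwhm[axis] = value
    return BeadMeasurement(
        center_voxel=(z, y, x),
        center_um=center_um,
        fwhm_um=(fwhm["x"], fwhm["y"], fwhm["z"]),
        peak_intensity=float(data[z, y, x]),
        valid=True,
    )


def summarize_resolution(
    measurements: list[BeadMeasurement], axis: str
) -> ResolutionSummary:
    """Mean ± population std of the chosen resolution axis over valid beads.

    ``axis="lateral"`` pools the X and Y values (two per bead);
    ``axis="axial"`` uses Z.
    """
    if axis not in ("lateral", "axial"):
        raise ConfigError(f"axis must be 'lateral' or 'axial', got {axis!r}")
    values = []
    for m in measurements:
        if not m.valid or m.fwhm_um is None:
            continue
        if axis == "lateral":
            values.extend([m.fwhm_um[0], m.fwhm_um[1]])
        else:
            values.append(m.fwhm_um[2])
    if not values:
        raise AslmSimError("no valid bead measurements to summarize")
    arr = np.asarray(values, dtype=float)
    return ResolutionSummary(axis=axis, mean_um=float(arr.mean()),
                             std_um=float(arr.std(ddof=0)), n=arr.size)


def brightness_uniformity(
    image: np.ndarray,
    axis: str,
    averaging_band: slice | None = None,
) -> UniformityProfile:
    """Averaged line profile across the field and its peak fractional deviation.

    ``axis="X"`` profiles along columns (averaging over rows, i.e. over the
    sweep direction); ``axis="Y"`` profiles along rows.  ``averaging_band``
    optionally restricts the perpendicular extent being averaged.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ConfigError(f"expected a 2D image, got ndim={img.ndim}")
    if axis not in ("X", "Y"):
        raise ConfigError(f"axis must be 'X' or 'Y', got {axis!r}")
    band = averaging_band if averaging_band is not None else slice(None)
    profile = img[band, :].mean(axis=0) if axis == "X" else img[:, band].mean(axis=1)
    mean_level = float(profile.mean())
    if mean_level == 0:
        raise AslmSimError("degenerate image: zero mean intensity")
    dev = float(np.max(np.abs(profile - mean_level)) / abs(mean_level))
    return UniformityProfile(axis=axis, positions_px=np.arange(profile.size),
                             profile=profile, mean_level=mean_level,
                             max_fractional_deviation=dev)


def depth_brightness(stack: ImageStack, background: float = 0.0) -> np.ndarray:
    """Mean background-subtracted intensity per Z plane, normalized to plane 0."""
    data = np.asarray(stack.data, dtype=float)
    means = data.mean(axis=(1, 2)) - background
    if means[0] == 0:
        raise AslmSimError("plane 0 has zero mean intensity; cannot normalize")
    return means / means[0]
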