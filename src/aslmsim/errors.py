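"""Exception hierarchy shared across the package."""


class AslmSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AslmSimError, ValueError):
    """A configuration value violates an invariant or a cross-reference."""


class OutOfRangeError(AslmSimError, ValueError):
    """A requested position, time, or voltage lies outside the valid range."""


class SimulationError(AslmSimError, RuntimeError):
    """The dynamical simulation produced a non-finite or inconsistent state."""


class CalibrationError(AslmSimError, RuntimeError):
    """A calibration step failed (non-monotone curve, unusable image, ...)."""


class NoPeakError(CalibrationError):
    """The focus image contains no distinguishable intensity peak."""


class BorderPeakError(CalibrationError):
    """The brightest pixel sits too close to the image border to refine."""


class MetadataError(AslmSimError, ValueError):
    """Required image metadata (voxel size) is missing."""
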