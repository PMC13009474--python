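"""Minimal in-memory container for image stacks with voxel metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MetadataError

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A 3D image (plane, row, column) plus physical voxel sizes.

    ``voxel_size_um`` is ``(z, y, x)`` in µm, or ``None`` when the source
    file carried no calibration; operations that need physical units must
    call :meth:`require_voxel_size`.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single frame as a degenerate one-plane stack
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(f"expected 2D or 3D data, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def require_voxel_size(self) -> tuple[float, float, float]:
        if self.voxel_size_um is None:
            raise MetadataError("stack carries no voxel-size metadata")
        return self.voxel_size_um
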