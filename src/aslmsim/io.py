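"""TIFF / OME-TIFF reading and writing with voxel-size metadata.

Stacks are written as OME-TIFF (axes ZYX) carrying PhysicalSizeX/Y/Z in µm;
plain TIFFs without calibration read back with ``voxel_size_um=None`` and
downstream operations that need physical units fail loudly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile

from .errors import AslmSimError
from .stacks import ImageStack

__all__ = ["read_stack", "write_stack"]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF; voxel sizes (µm) go into the OME header."""
    path = Path(path)
    data = np.asarray(stack.data)
    metadata = {"axes": "ZYX"}
    if stack.voxel_size_um is not None:
        z, y, x = stack.voxel_size_um
        metadata.update({
            "PhysicalSizeZ": z, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": y, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": x, "PhysicalSizeXUnit": "µm",
        })
    tifffile.imwrite(path, data, ome=True, photometric="minisblack",
                     metadata=metadata)


def _voxel_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None
    try:
        return (
            float(pixels.attrib["PhysicalSizeZ"]),
            float(pixels.attrib["PhysicalSizeY"]),
            float(pixels.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        return None


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF/OME-TIFF as a (plane, row, column) stack.

    2D files become one-plane stacks.  Missing voxel-size metadata is
    carried as ``None`` rather than raising here.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            voxel = _voxel_from_ome(tf.ome_metadata) if tf.ome_metadata else None
    except (tifffile.TiffFileError, ValueError) as exc:
        raise AslmSimError(f"{path} is not a readable TIFF: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise AslmSimError(f"{path}: expected 2D or 3D image data, got shape {data.shape}")
    return ImageStack(data=data, voxel_size_um=voxel)
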