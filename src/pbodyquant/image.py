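"""Calibrated multi-channel image stacks and TIFF I/O.

The pipeline's in-memory container is a plain ``numpy`` array of intensities
(arbitrary units, a.u.) on a 3-D voxel grid with a leading channel axis, plus
the physical voxel size in micrometres.  Axis order follows the microscopy
convention ``(C, Z, Y, X)``; ``voxel_size`` is given as ``(dz, dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A calibrated 3-D (multi-channel) intensity stack.

    Parameters
    ----------
    data:
        Intensities, shape ``(C, Z, Y, X)``.  A 3-D array is promoted to a
        single channel.
    voxel_size:
        Physical voxel size ``(dz, dy, dx)`` in µm.
    channels:
        Channel names, one per leading-axis slice.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3-D or 4-D data, got shape {self.data.shape}")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(Z, Y, X)``."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's ``(Z, Y, X)`` array by name."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None
        return self.data[idx]

    def save(self, path) -> None:
        """Write as OME-TIFF with voxel size recorded in the metadata."""
        dz, dy, dx = self.voxel_size
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "CZYX",
                "PhysicalSizeX": dx,
                "PhysicalSizeY": dy,
                "PhysicalSizeZ": dz,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZUnit": "µm",
                "Channel": {"Name": self.channels},
            },
        )


def load_stack(path, voxel_size=None, channels=None) -> ImageStack:
    """Read a (OME-)TIFF stack; voxel size from OME metadata unless given."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if voxel_size is None:
            if tf.ome_metadata is None:
                raise ValueError("no OME metadata; pass voxel_size explicitly")
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            voxel_size = (
                float(px.get("PhysicalSizeZ", 1.0)),
                float(px.get("PhysicalSizeY", 1.0)),
                float(px.get("PhysicalSizeX", 1.0)),
            )
            if channels is None:
                names = [c.get("Name") for c in root.findall(".//ome:Channel", ns)]
                if names and all(n for n in names):
                    channels = names
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[None]
    return ImageStack(data, voxel_size, list(channels) if channels else [])
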