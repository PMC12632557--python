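"""Two-channel image stack container and OME-TIFF I/O.

The canonical acquisition is a two-channel (RFP, GFP) confocal z-stack of a
neuron's presynaptic region. Channel order is fixed: channel 0 = RFP (total
protein), channel 1 = GFP (old protein, pH-quenched in acidic compartments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNEL_NAMES = ("RFP", "GFP")


@dataclass
class ImageStack:
    """A calibrated two-channel 3-D intensity array.

    Parameters
    ----------
    data : ndarray, shape (2, nz, ny, nx)
        Non-negative intensities; ``data[0]`` is RFP, ``data[1]`` is GFP.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    z_step_um : float
        Axial step between planes in micrometres.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_names: tuple[str, str] = CHANNEL_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError(
                f"expected (2, nz, ny, nx) array, got shape {self.data.shape}"
            )
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")

    @property
    def rfp(self) -> np.ndarray:
        return self.data[0]

    @property
    def gfp(self) -> np.ndarray:
        return self.data[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def save(self, path: str | Path) -> None:
        """Write as OME-TIFF with channel names and calibration recorded."""
        path = Path(path)
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "CZYX",
                "Channel": {"Name": list(self.channel_names)},
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": self.z_step_um,
                "PhysicalSizeZUnit": "µm",
            },
        )
        if self.metadata:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(self.metadata, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        """Read a (OME-)TIFF written by :meth:`save` or any CZYX 2-channel TIFF."""
        path = Path(path)
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            pixel_size = 0.108
            z_step = 0.4
            if tf.ome_metadata:
                import re

                m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    pixel_size = float(m.group(1))
                m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    z_step = float(m.group(1))
        data = np.asarray(data)
        if data.ndim == 3:  # single z-plane saved as CYX
            data = data[:, None, :, :]
        if data.ndim != 4:
            raise ValueError(f"cannot interpret TIFF with shape {data.shape}")
        if data.shape[0] != 2 and data.shape[1] == 2:  # ZCYX order
            data = np.moveaxis(data, 1, 0)
        if data.shape[0] != 2:
            raise ValueError(
                f"expected 2 channels (RFP, GFP); file has shape {data.shape}"
            )
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            data=data, pixel_size_um=pixel_size, z_step_um=z_step, metadata=meta
        )
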