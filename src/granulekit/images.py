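"""Multi-channel image stack container and TIFF round-trip.

The in-memory substrate of all image quantification is :class:`ImageStack`,
an intensity array indexed ``(channel, plane, y, x)`` together with the
physical voxel geometry (pixel size in the imaging plane and spacing
between confocal planes, both in micrometres).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A multi-channel confocal stack with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_planes, ny, nx)
        Non-negative intensities. 2D images are represented with
        ``n_planes == 1``.
    pixel_size_um : float
        In-plane pixel edge length, micrometres.
    plane_spacing_um : float
        Axial distance between consecutive planes, micrometres.
    channel_names : list of str
        One label per channel, e.g. ``["marker", "query"]``.
    """

    data: np.ndarray
    pixel_size_um: float
    plane_spacing_um: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4-dimensional (channel, plane, y, x); got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all image dimensions must be >= 1")
        if self.pixel_size_um <= 0 or self.plane_spacing_um <= 0:
            raise ValueError("physical voxel sizes must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match the channel axis")
        if np.any(np.asarray(self.data, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.plane_spacing_um

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(plane, y, x)`` volume of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[idx]

    def to_tiff(self, path) -> None:
        """Write as a channel-major multi-page TIFF with geometry metadata.

        Pages are ordered channel-major: all planes of channel 0, then all
        planes of channel 1, etc. Geometry and channel names are stored in
        the TIFF description as JSON.
        """
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "plane_spacing_um": self.plane_spacing_um,
            "channel_names": self.channel_names,
            "n_channels": self.n_channels,
            "n_planes": self.n_planes,
        }
        pages = self.data.reshape((-1,) + self.data.shape[2:])
        tifffile.imwrite(path, pages, description=json.dumps(meta))

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        """Read a stack written by :meth:`to_tiff`."""
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        data = pages.reshape(
            (meta["n_channels"], meta["n_planes"]) + pages.shape[-2:]
        )
        return cls(
            data=data,
            pixel_size_um=meta["pixel_size_um"],
            plane_spacing_um=meta["plane_spacing_um"],
            channel_names=list(meta["channel_names"]),
        )
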