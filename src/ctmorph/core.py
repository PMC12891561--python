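"""Core voxel containers shared by every pipeline stage.

Conventions used throughout the package:

* Voxel stacks are indexed ``(z, y, x)`` (multichannel stacks
  ``(channel, z, y, x)``), 0-based.
* ``voxel_size`` is the physical spacing in µm per axis, ordered ``(z, y, x)``;
  confocal stacks are typically anisotropic (z step > xy pixel).
* Physical coordinates are voxel index × voxel size, i.e. the centre of voxel
  ``i`` sits at ``i * voxel_size`` on each axis.  All distances, volumes and
  surface areas are reported in µm, µm³ and µm².
* Connected components use 26-connectivity in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 3D connectivity order passed to skimage (26-connectivity).
CONNECTIVITY = 3


def validate_voxel_size(voxel_size) -> tuple[float, float, float]:
    """Coerce ``voxel_size`` to a (z, y, x) tuple of positive floats."""
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3:
        raise ValueError(f"voxel_size must have 3 entries (z, y, x), got {vs!r}")
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be strictly positive, got {vs!r}")
    return vs


@dataclass
class ImageField:
    """A multichannel 3D intensity stack on a physical grid.

    Parameters
    ----------
    data
        Nonnegative intensities, shape ``(n_channels, nz, ny, nx)``.
    voxel_size
        Physical spacing in µm, ordered ``(z, y, x)``.
    channel_names
        One label per channel, e.g. ``("dna", "chr2", "chr3", "polII")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"ImageField data must be (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("ImageField needs at least one channel")
        self.voxel_size = validate_voxel_size(self.voxel_size)
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D volume for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


@dataclass
class LabelVolume:
    """An integer-labelled segmentation sharing a grid with an ImageField.

    Label 0 is background; object labels are dense from 1.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume must be 3D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelVolume labels must be integer-typed")
        self.voxel_size = validate_voxel_size(self.voxel_size)

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    @property
    def max_label(self) -> int:
        return int(self.labels.max(initial=0))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def check_grid(self, other) -> None:
        """Raise if ``other`` (ImageField/LabelVolume/ndarray) is on another grid."""
        shape = getattr(other, "grid_shape", None)
        if shape is None:
            arr = getattr(other, "labels", other)
            shape = np.asarray(arr).shape[-3:]
        if tuple(shape) != tuple(self.labels.shape):
            raise ValueError(
                f"grid mismatch: {tuple(shape)} vs {tuple(self.labels.shape)}"
            )
        other_vs = getattr(other, "voxel_size", None)
        if other_vs is not None and not np.allclose(other_vs, self.voxel_size):
            raise ValueError(
                f"voxel size mismatch: {other_vs} vs {self.voxel_size}"
            )
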