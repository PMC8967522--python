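"""In-memory containers for image stacks and aligned label volumes.

The package-wide voxel convention is index order (slice, row, col) with
0-based voxel centers at integer coordinates.  Physical coordinates are
millimetres: x = col * pixel_spacing[1], y = row * pixel_spacing[0],
z = slice * slice_spacing, origin at voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SliceStack", "MaskVolume"]


@dataclass
class SliceStack:
    """An ordered stack of 2D grayscale slices with physical spacings.

    Parameters
    ----------
    voxels:
        3D array, index order (slice, row, col).  Grayscale values are
        expected in [0, 1] (loaders rescale on read).
    pixel_spacing:
        In-plane spacing in mm per pixel, (row, col).
    slice_spacing:
        Distance between adjacent slices in mm.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3D (slice, row, col) array, got shape {self.voxels.shape}"
            )
        if min(self.pixel_spacing) <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def spacing_zyx(self) -> tuple[float, float, float]:
        """Spacing in array index order (slice, row, col)."""
        return (self.slice_spacing, self.pixel_spacing[0], self.pixel_spacing[1])


@dataclass
class MaskVolume:
    """Lesion labels aligned voxel-for-voxel with a :class:`SliceStack`.

    ``labels`` is either binary ({0, 1}) or a probability map in [0, 1].
    """

    labels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 1.0
    binary: bool = field(default=True)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"expected a 3D (slice, row, col) array, got shape {self.labels.shape}"
            )
        if self.binary:
            vals = np.unique(self.labels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary mask may only contain values {0, 1}")
        else:
            if self.labels.min() < 0 or self.labels.max() > 1:
                raise ValueError("probability mask must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_aligned(self, stack: SliceStack) -> None:
        if self.shape != stack.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match stack shape {stack.shape}"
            )
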