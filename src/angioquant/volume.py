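"""3D image volumes with physical voxel spacing.

The package convention, used everywhere: arrays are indexed ``[x, y, z]``,
voxel spacing is ``(sx, sy, sz)`` in µm, voxel *centers* sit at
``index * spacing + origin`` (0-based indices).  Multi-page TIFF stacks are
stored page-major (z, y, x); the I/O layer transposes at the boundary so
that in-memory geometry never mixes conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterVolume"]

_MIN_SHAPE = 8


@dataclass
class RasterVolume:
    """A 3D scalar field on an anisotropic voxel grid.

    Parameters
    ----------
    voxels
        Array of shape ``(nx, ny, nz)``.  Binary masks are the boolean
        special case.
    spacing
        Physical size of one voxel, ``(sx, sy, sz)`` in µm; all positive.
    origin
        Physical position of voxel ``(0, 0, 0)``'s center in µm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # set check_shape=False for deliberately tiny fixtures
    check_shape: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if self.check_shape and any(n < _MIN_SHAPE for n in self.voxels.shape):
            raise ValueError(
                f"volume shape {self.voxels.shape} is below the minimum "
                f"({_MIN_SHAPE},)*3; pass check_shape=False for toy grids"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid in µm (n * spacing per axis)."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def is_binary(self) -> bool:
        if self.voxels.dtype == bool:
            return True
        vals = np.unique(self.voxels)
        return vals.size <= 2 and np.isin(vals, (0, 1)).all()

    def astype_mask(self) -> "RasterVolume":
        """Return a boolean view/copy of this volume (nonzero → True)."""
        return RasterVolume(
            self.voxels.astype(bool), self.spacing, self.origin, check_shape=False
        )

    def with_voxels(self, voxels: np.ndarray) -> "RasterVolume":
        """Same grid geometry, different data."""
        if voxels.shape != self.voxels.shape:
            raise ValueError("replacement array must keep the grid shape")
        return RasterVolume(voxels, self.spacing, self.origin, check_shape=False)

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical center coordinates along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]
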