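"""Image volume container.

A single confocal z-stack is held as a 3D array in ``(z, y, x)`` axis order
together with its physical voxel spacing in micrometres.  Confocal stacks of
epithelia are strongly anisotropic (z steps of ~1 um against ~0.1-0.3 um in
plane), so every operation downstream works in physical units; the spacing is
therefore mandatory, not metadata sugar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D non-negative intensity field with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3D array, axis order ``(z, y, x)``.  Values must be finite and >= 0.
    spacing:
        Physical voxel size per axis in micrometres, same ``(z, y, x)`` order.
    time_index:
        Position of this stack within its time lapse (0-based).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    time_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(s < 3 for s in self.data.shape):
            raise ValueError(
                f"volume shape {self.data.shape} degenerate: need >= 3 voxels per axis"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("volume contains negative intensities")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Return a copy of this volume carrying new intensity data."""
        return ImageVolume(data=data, spacing=self.spacing, time_index=self.time_index)

    def voxel_to_physical(self, voxel: np.ndarray) -> np.ndarray:
        """Convert (possibly fractional) voxel coordinates to micrometres."""
        return np.asarray(voxel, dtype=float) * np.asarray(self.spacing)

    def physical_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Convert micrometre coordinates to fractional voxel coordinates."""
        return np.asarray(pos, dtype=float) / np.asarray(self.spacing)
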