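"""Core image containers.

Everything in the pipeline operates on scalar volumes sampled on a regular
axis-aligned grid with millimetre voxel spacing.  World coordinates are
``index * voxel_size`` (plus whatever origin the NIfTI affine carries; the
origin is irrelevant to every algorithm here because all images in one
analysis share a grid, so internal maths uses the spacing only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalarVolume", "LabelVolume"]


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class ScalarVolume:
    """A 3D scalar image (FA map, mean FA, SD map ...) on a regular grid.

    Parameters
    ----------
    data : (X, Y, Z) float array
        Voxel values.  FA maps live in [0, 1].
    voxel_size : 3-tuple of float
        Voxel edge lengths in mm.
    affine : (4, 4) array, optional
        World affine, kept for NIfTI round-trips.  Defaults to a diagonal
        matrix built from ``voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """A new volume on this grid holding ``data``."""
        if data.shape != self.data.shape:
            raise ValueError(f"grid mismatch: {data.shape} vs {self.data.shape}")
        return ScalarVolume(data, self.voxel_size, None if self.affine is None else self.affine.copy())

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)

    def copy(self) -> "ScalarVolume":
        return self.like(self.data.copy())


# An integer label image (tract ids, 0 = background) shares the container.
LabelVolume = ScalarVolume
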