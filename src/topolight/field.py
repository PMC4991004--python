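"""Regularly gridded 3D scalar fields.

The voxel grid uses 0-based indices with x varying fastest: the linear index
of voxel (x, y, z) is ``x + nx*(y + ny*z)`` (Fortran raveling of an
(nx, ny, nz) array).  All topology code operates on this linear order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

__all__ = ["ScalarField"]


@dataclass(frozen=True)
class ScalarField:
    """A scalar function f sampled on a regular 3D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar value per grid vertex.  1D/2D inputs are accepted and padded
        with trailing singleton axes.
    spacing : tuple of 3 floats
        Physical size of a voxel along each axis (used for hypervolume).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim > 3:
            raise ValueError(f"expected at most 3 axes, got {arr.ndim}")
        while arr.ndim < 3:
            arr = arr[..., np.newaxis]
        if arr.size == 0:
            raise ValueError("empty field")
        if not np.all(np.isfinite(arr)):
            raise ValueError("field contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing!r}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_vertices(self) -> int:
        return self.values.size

    @property
    def value_range(self) -> tuple[float, float]:
        return float(self.values.min()), float(self.values.max())

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def flat(self) -> np.ndarray:
        """Values in linear (x-fastest) order."""
        return self.values.ravel(order="F")

    def total_order(self) -> np.ndarray:
        """Vertices sorted ascending by (value, linear index).

        Ties in value are broken by linear vertex index (simulation of
        simplicity), so every sweep event is distinct.
        """
        flat = self.flat()
        return np.lexsort((np.arange(flat.size), flat))

    def linear_index(self, x: int, y: int, z: int) -> int:
        nx, ny, _ = self.dims
        return x + nx * (y + ny * z)

    def vertex_value(self, v: int) -> float:
        return float(self.flat()[v])
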