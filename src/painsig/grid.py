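"""Voxel grids and weight maps.

All trial-level analysis in this package operates on vectors of in-mask
voxels. :class:`GridSpec` pins down the mask and the (deterministic,
C-order) linearization of in-mask voxels, so that every map sharing a grid
refers to the same voxel in the same slot. Maps are never implicitly
resampled: combining objects from different grids is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "WeightMap", "make_grid"]


@dataclass(frozen=True, eq=False)
class GridSpec:
    """A 3-D voxel grid with a boolean inclusion mask.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts along each axis.
    mask : ndarray of bool, shape ``shape``
        In-mask voxels. Must contain at least one True entry.

    Notes
    -----
    In-mask voxels are linearized in C (row-major) order; this ordering is
    deterministic and shared by every map built on the grid.
    """

    shape: tuple
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.shape}")
        if not mask.any():
            raise ValueError("mask is empty: no in-mask voxels")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @property
    def n_vox(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def flat_index(self) -> np.ndarray:
        """C-order flat indices of in-mask voxels (the linearization)."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    def matches(self, other: "GridSpec") -> bool:
        """True if ``other`` has the same shape and mask."""
        return (
            isinstance(other, GridSpec)
            and self.shape == other.shape
            and np.array_equal(self.mask, other.mask)
        )

    def __eq__(self, other):
        return self.matches(other)

    def __hash__(self):
        return hash((self.shape, self.mask.tobytes()))

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter in-mask vectors back into full volumes.

        ``values`` may be 1-D (``n_vox``) giving one volume, or 2-D
        (``n, n_vox``) giving a 4-D stack with the map axis last.
        """
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n_vox:
            raise ValueError(
                f"last axis {values.shape[-1]} != n_vox {self.n_vox}"
            )
        if values.ndim == 1:
            vol = np.full(self.shape, fill, dtype=float)
            vol[self.mask] = values
            return vol
        if values.ndim == 2:
            stack = np.full(self.shape + (values.shape[0],), fill, dtype=float)
            stack[self.mask, :] = values.T
            return stack
        raise ValueError("values must be 1-D or 2-D")

    def mask_volume(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask vector(s) from a 3-D volume or 4-D stack."""
        volume = np.asarray(volume, dtype=float)
        if volume.shape[:3] != self.shape:
            raise ValueError(
                f"volume shape {volume.shape[:3]} != grid shape {self.shape}"
            )
        if volume.ndim == 3:
            return volume[self.mask]
        if volume.ndim == 4:
            return volume[self.mask, :].T
        raise ValueError("volume must be 3-D or 4-D")


@dataclass
class WeightMap:
    """Voxel weights on a grid (a signature, a subject map, a stat map)."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_vox,):
            raise ValueError(
                f"values shape {self.values.shape} != (n_vox,) = ({self.grid.n_vox},)"
            )

    def to_volume(self) -> np.ndarray:
        return self.grid.unmask(self.values)


def make_grid(shape, mask_rule: str = "ellipsoid", *, semi_axes=None,
              mask: np.ndarray | None = None, seed: int | None = None) -> GridSpec:
    """Build a deterministic :class:`GridSpec`.

    Parameters
    ----------
    shape : 3-sequence of int
        Grid dimensions.
    mask_rule : {"ellipsoid", "full", "custom"}
        ``ellipsoid`` keeps voxels inside the ellipsoid centred on the grid
        (semi-axes default to ``shape/2 - 1``); ``full`` keeps everything;
        ``custom`` uses the supplied boolean ``mask``.
    semi_axes : 3-sequence of float, optional
        Ellipsoid semi-axes in voxels.
    mask : ndarray of bool, optional
        Required for ``mask_rule="custom"``.
    seed : int, optional
        Accepted for interface uniformity; the built-in rules are
        deterministic and ignore it.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("shape entries must be positive")
    if mask_rule == "full":
        m = np.ones(shape, dtype=bool)
    elif mask_rule == "ellipsoid":
        if semi_axes is None:
            semi_axes = tuple(max(s / 2.0 - 1.0, 0.5) for s in shape)
        center = [(s - 1) / 2.0 for s in shape]
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
        m = d2 <= 1.0
    elif mask_rule == "custom":
        if mask is None:
            raise ValueError("mask_rule='custom' requires a mask volume")
        m = np.asarray(mask, dtype=bool)
    else:
        raise ValueError(f"unknown mask_rule {mask_rule!r}")
    return GridSpec(shape=shape, mask=m)
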