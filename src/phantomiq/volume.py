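"""Voxel volumes on regular world-coordinate grids.

Conventions used throughout the package:

* world coordinates are in millimetres;
* arrays are indexed ``(x, y, z)`` with axial slices along the last axis;
* voxel indices are 0-based and refer to voxel *centres*: the world
  position of index ``i`` along an axis is ``origin + i * spacing``;
* regions of interest are half-open boxes in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Grid:
    """A regular 3-D sampling grid in world coordinates (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid shape, spacing and origin must be 3-vectors")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "Grid":
        """Grid whose voxel-centre bounding box is centred on ``center``."""
        origin = tuple(
            c - (n - 1) * s / 2.0 for c, n, s in zip(center, shape, spacing)
        )
        return cls(tuple(shape), tuple(spacing), origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (X, Y, Z) of voxel centres."""
        ax = [self.axis_coords(a).astype(dtype) for a in range(3)]
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def index_from_world(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points, shape (..., 3)."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_extent(self) -> tuple[tuple[float, float], ...]:
        """Half-open world extent covered by the voxels (edge to edge)."""
        return tuple(
            (o - s / 2.0, o + (n - 0.5) * s)
            for o, s, n in zip(self.origin, self.spacing, self.shape)
        )


@dataclass
class VoxelVolume:
    """A 3-D scalar field of CT numbers (HU) on a :class:`Grid`.

    ``values`` has shape ``grid.shape`` with axes (x, y, z); axial slices
    are ``values[:, :, k]``.
    """

    values: np.ndarray
    grid: Grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.values.copy(), self.grid, dict(self.meta))

    def sample_world(
        self, points: np.ndarray, background: float = -1000.0
    ) -> np.ndarray:
        """Trilinear interpolation of the volume at world points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        idx = self.grid.index_from_world(pts)
        flat = idx.reshape(-1, 3).T
        out = ndimage.map_coordinates(
            self.values,
            flat,
            order=1,
            mode="constant",
            cval=background,
        )
        return np.asarray(out, dtype=np.float64).reshape(pts.shape[:-1])


def resample_to_grid(
    volume: VoxelVolume,
    target: Grid,
    transform: np.ndarray | None = None,
    background: float = -1000.0,
) -> VoxelVolume:
    """Resample a volume onto a target grid with trilinear interpolation.

    ``transform`` is an optional 4x4 rigid (or affine, invertible) matrix
    mapping *target* world coordinates into *source* world coordinates;
    the default is the identity.  Samples falling outside the source
    domain take the ``background`` HU value.  The identity transform onto
    the source grid returns the values unchanged.
    """
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be a 4x4 homogeneous matrix")
    if abs(np.linalg.det(transform[:3, :3])) < 1e-12:
        raise ValueError("transform is not invertible")

    identity = np.allclose(transform, np.eye(4))
    if identity and target == volume.grid:
        return VoxelVolume(volume.values.copy(), target, dict(volume.meta))

    # target voxel centres -> world -> source world -> fractional indices
    tx = [target.axis_coords(a) for a in range(3)]
    sp = np.asarray(volume.grid.spacing)
    org = np.asarray(volume.grid.origin)
    if identity:
        # axis-separable index coordinates: no full meshgrid needed
        idx_ax = [(tx[a] - org[a]) / sp[a] for a in range(3)]
        coords = np.meshgrid(*idx_ax, indexing="ij", copy=False)
        coords = [np.ascontiguousarray(c, dtype=np.float32) for c in coords]
    else:
        X, Y, Z = np.meshgrid(tx[0], tx[1], tx[2], indexing="ij", copy=False)
        R, t = transform[:3, :3], transform[:3, 3]
        coords = []
        for k in range(3):
            w = R[k, 0] * X + R[k, 1] * Y + R[k, 2] * Z + t[k]
            coords.append(((w - org[k]) / sp[k]).astype(np.float32))
    out = ndimage.map_coordinates(
        volume.values,
        coords,
        order=1,
        mode="constant",
        cval=background,
    )
    return VoxelVolume(out.astype(volume.values.dtype, copy=False), target, dict(volume.meta))
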