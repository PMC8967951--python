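"""Core domain types: voxel geometry, intensity/label/instance volumes, meshes.

Conventions
-----------
* Arrays are stored in numpy page-first order ``(z, y, x)`` so that TIFF pages
  map directly to increasing z.  Public size/shape tuples (``voxel_size``,
  ``shape_xyz``) are expressed in ``(x, y, z)`` order, the order used in the
  microscopy literature (e.g. an "8 x 8 x 2" mask is 8 wide, 8 tall, 2 deep).
* Voxel indices inside the library are numpy-order ``(z, y, x)`` tuples and
  index arrays directly.
* A voxel ``(i, j, k)`` (x, y, z indices) occupies the half-open physical box
  ``origin + [i, i+1) * sx`` (etc.); its center is ``origin + (i + 0.5) * sx``.
  All physical coordinates are in micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import trimesh

#: Voxel size of the confocal stacks the pipeline was designed around, in μm.
DEFAULT_VOXEL_SIZE = (0.0751562, 0.0751562, 0.279911)

BACKGROUND, SHAFT, SPINE = 0, 1, 2


class SpineflowError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SpineflowError):
    """Input data violates a documented invariant."""


class OpenMeshError(SpineflowError):
    """A closed (watertight) surface is required."""


class NoPathError(SpineflowError):
    """A* could not find an admissible connecting path."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Anisotropic voxel grid geometry.

    Parameters
    ----------
    voxel_size : tuple of float
        Per-axis voxel edge lengths ``(sx, sy, sz)`` in μm, all positive.
    origin : tuple of float
        Physical position of the low corner of voxel (0, 0, 0), in μm.
    """

    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.voxel_size) != 3 or len(self.origin) != 3:
            raise ValidationError("voxel_size and origin must have 3 entries")
        if any(s <= 0 for s in self.voxel_size):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def spacing_zyx(self) -> Tuple[float, float, float]:
        sx, sy, sz = self.voxel_size
        return (sz, sy, sx)

    def index_to_um(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map voxel indices (z,y,x rows) to physical voxel-center coordinates (x,y,z rows)."""
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        xyz = idx[:, ::-1]
        size = np.asarray(self.voxel_size)
        return np.asarray(self.origin) + (xyz + 0.5) * size

    def um_to_index(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Map physical points (x,y,z rows) to fractional voxel indices (z,y,x rows)."""
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
        frac = (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size) - 0.5
        return frac[:, ::-1]


def _check_3d(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise ValidationError(f"{name} must be a non-empty 3-D array, got shape {arr.shape}")
    return arr


@dataclass
class IntensityVolume:
    """Raw fluorescence stack: non-negative scalars on a voxel grid."""

    values: np.ndarray  # (z, y, x)
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self):
        self.values = _check_3d(self.values, "intensity")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("intensity values must be finite")
        if self.values.min() < 0:
            raise ValidationError("intensity values must be non-negative")

    @property
    def shape_xyz(self) -> Tuple[int, int, int]:
        return self.values.shape[::-1]


@dataclass
class LabelVolume:
    """3-class segmentation: background=0, dendritic shaft=1, spine=2."""

    labels: np.ndarray  # (z, y, x), integer
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self):
        self.labels = _check_3d(self.labels, "labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValidationError("labels must be integer-valued")
            self.labels = self.labels.astype(np.uint8)
        bad = (self.labels < 0) | (self.labels > 2)
        if bad.any():
            z, y, x = (int(v[0]) for v in np.nonzero(bad))
            code = int(self.labels[z, y, x])
            raise ValidationError(
                f"label code {code} at voxel (x={x}, y={y}, z={z}) outside {{0,1,2}}"
            )

    @property
    def shape_xyz(self) -> Tuple[int, int, int]:
        return self.labels.shape[::-1]

    def one_hot(self) -> np.ndarray:
        """(3, z, y, x) one-hot view r_k(x)."""
        return np.stack([(self.labels == k) for k in range(3)]).astype(np.float32)


@dataclass
class InstanceVolume:
    """Per-voxel instance ids (0 = none) plus each id's anatomical class."""

    ids: np.ndarray  # (z, y, x), non-negative integers
    class_of: Dict[int, int]
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self):
        self.ids = _check_3d(self.ids, "instance ids")
        if self.ids.min() < 0:
            raise ValidationError("instance ids must be non-negative")
        for i, c in self.class_of.items():
            if c not in (SHAFT, SPINE):
                raise ValidationError(f"instance {i} has class {c}, expected 1 or 2")

    @property
    def instance_ids(self):
        return sorted(self.class_of)


@dataclass
class TriangleMesh:
    """Closed triangle surface in μm coordinates (one shaft or one spine).

    Wraps a :class:`trimesh.Trimesh`; watertightness is checked on
    construction and violations are reported, never silently repaired.
    """

    vertices: np.ndarray  # (n, 3) xyz in μm
    faces: np.ndarray  # (m, 3) int
    structure_class: int = SPINE

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of range")
        if self.structure_class not in (SHAFT, SPINE):
            raise ValidationError("structure_class must be 1 (shaft) or 2 (spine)")
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise OpenMeshError(
                "mesh is not closed (every edge must be shared by exactly two faces); "
                "hole filling is out of scope — provide a watertight surface"
            )

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def euler_characteristic(self) -> int:
        return self.as_trimesh().euler_number
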