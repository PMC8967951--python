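"""Mesh-to-label voxelization.

Closed shaft/spine surface meshes become a 3-class label volume in two steps:
(i) every voxel whose physical axis-aligned box intersects a surface triangle
is marked (exact separating-axis triangle/box test), producing a closed shell;
(ii) interior voxels are found by labelling the background complement and
keeping the components that do not reach the volume border.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    InstanceVolume,
    LabelVolume,
    SHAFT,
    SPINE,
    SpineflowError,
    TriangleMesh,
    VoxelGeometry,
)


class OutOfBoundsError(SpineflowError):
    pass


_UNIT_AXES = np.eye(3)


def _triangle_box_overlap(tri: np.ndarray, centers: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Separating-axis test of one triangle against many axis-aligned boxes.

    tri: (3, 3) vertex coordinates; centers: (n, 3) box centers; half: (3,)
    box half extents.  Returns a boolean mask of boxes the triangle touches.
    """
    v = tri[None, :, :] - centers[:, None, :]  # (n, 3 verts, 3)
    alive = np.ones(len(centers), dtype=bool)

    # box face normals: AABB overlap
    for ax in range(3):
        lo, hi = v[:, :, ax].min(axis=1), v[:, :, ax].max(axis=1)
        alive &= (hi >= -half[ax]) & (lo <= half[ax])
    if not alive.any():
        return alive

    edges = tri[[1, 2, 0]] - tri  # e0=v1-v0, e1=v2-v1, e2=v0-v2
    eps = 1e-12

    # triangle plane
    n = np.cross(edges[0], edges[1])
    r = np.abs(n) @ half + eps
    d = v[:, 0, :] @ n
    alive &= np.abs(d) <= r
    if not alive.any():
        return alive

    # 9 edge cross-product axes
    for e in edges:
        for a in _UNIT_AXES:
            axis = np.cross(a, e)
            if np.abs(axis).max() < 1e-14:
                continue
            p = v @ axis  # (n, 3)
            r = np.abs(axis) @ half + eps
            alive &= (p.max(axis=1) >= -r) & (p.min(axis=1) <= r)
            if not alive.any():
                return alive
    return alive


def rasterize_surface(
    mesh: TriangleMesh, geometry: VoxelGeometry, shape_xyz: Sequence[int]
) -> np.ndarray:
    """Mark every voxel whose physical box intersects the surface.

    Returns a boolean ``(z, y, x)`` shell grid.  Raises
    :class:`OutOfBoundsError` if any vertex lies outside the volume extent.
    """
    nx, ny, nz = (int(s) for s in shape_xyz)
    size = np.asarray(geometry.voxel_size)
    origin = np.asarray(geometry.origin)
    extent_hi = origin + size * np.array([nx, ny, nz])

    verts = mesh.vertices
    bad = np.nonzero(np.any((verts < origin - 1e-9) | (verts > extent_hi + 1e-9), axis=1))[0]
    if bad.size:
        i = int(bad[0])
        raise OutOfBoundsError(
            f"mesh vertex {i} at {tuple(verts[i])} μm lies outside the volume extent "
            f"{tuple(origin)}..{tuple(extent_hi)}"
        )

    shell = np.zeros((nz, ny, nx), dtype=bool)
    half = size / 2.0
    shape_arr = np.array([nx, ny, nz])
    # a polygon lying exactly on a voxel-boundary plane belongs to the voxel
    # on its inner side: shrink the surface inward by a hair (vertices move
    # along their outward vertex normals) before the box tests
    tm = mesh.as_trimesh()
    if tm.volume < 0:
        tm.invert()
    nudge = 1e-6 * float(size.min())
    shrunk = np.asarray(tm.vertices) - np.asarray(tm.vertex_normals) * nudge
    for tri in shrunk[np.asarray(tm.faces)]:
        lo = np.floor((tri.min(axis=0) - origin) / size).astype(int)
        hi = np.floor((tri.max(axis=0) - origin) / size).astype(int)
        lo = np.clip(lo, 0, shape_arr - 1)
        hi = np.clip(hi, 0, shape_arr - 1)
        ix, iy, iz = (np.arange(l, h + 1) for l, h in zip(lo, hi))
        gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
        idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)  # xyz indices
        centers = origin + (idx + 0.5) * size
        hit = _triangle_box_overlap(tri, centers, half)
        sel = idx[hit]
        shell[sel[:, 2], sel[:, 1], sel[:, 0]] = True
    return shell


def fill_interior(shell: np.ndarray) -> np.ndarray:
    """Return shell plus its enclosed interior.

    Background components are labelled with 6-connectivity; any component
    that never touches the volume border is enclosed, hence interior.
    """
    shell = np.asarray(shell, dtype=bool)
    bg, n = ndimage.label(~shell, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return shell.copy()
    border = np.zeros_like(shell)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    outside = np.unique(bg[border & ~shell])
    interior_ids = np.setdiff1d(np.arange(1, n + 1), outside)
    return shell | np.isin(bg, interior_ids)


def voxelize_scene(
    shaft: TriangleMesh | None,
    spines: Sequence[TriangleMesh],
    geometry: VoxelGeometry,
    shape_xyz: Sequence[int],
    spine_precedence: bool = True,
) -> Tuple[LabelVolume, InstanceVolume]:
    """Voxelize a shaft mesh and per-spine meshes into one 3-class volume.

    Where a voxel is claimed by both classes the spine wins by default
    (spine surfaces are traced over the shaft and spine identity is the
    analysis target); set ``spine_precedence=False`` for the opposite
    policy.  Per-spine instance provenance is returned alongside.
    """
    nx, ny, nz = (int(s) for s in shape_xyz)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    ids = np.zeros_like(labels, dtype=np.int32)
    class_of = {}

    shaft_mask = None
    if shaft is not None:
        shaft_mask = fill_interior(rasterize_surface(shaft, geometry, shape_xyz))
        labels[shaft_mask] = SHAFT
        ids[shaft_mask] = 1
        class_of[1] = SHAFT

    next_id = 2
    for spine in spines:
        mask = fill_interior(rasterize_surface(spine, geometry, shape_xyz))
        if spine_precedence:
            labels[mask] = SPINE
            ids[mask] = next_id
        else:
            free = mask & (labels == 0)
            labels[free] = SPINE
            ids[free] = next_id
        class_of[next_id] = SPINE
        next_id += 1
    return LabelVolume(labels, geometry), InstanceVolume(ids, class_of, geometry)
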