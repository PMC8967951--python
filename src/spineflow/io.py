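"""Readers and writers for the external formats the pipeline touches.

Multi-page TIFF for volumes (pages map to increasing z), OBJ/PLY for surface
meshes, CSV for metric reports.  Integer data round-trips bit-exactly.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile
import trimesh

from .core import (
    IntensityVolume,
    LabelVolume,
    SpineflowError,
    TriangleMesh,
    ValidationError,
    VoxelGeometry,
)


class UnsupportedFormatError(SpineflowError):
    pass


def _read_tiff_pages(path) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes
        if any(ax in axes for ax in "SC"):  # samples/channels: RGB or multi-channel
            raise UnsupportedFormatError(
                f"{path}: multi-channel / RGB TIFF is not supported "
                f"(axes {axes!r}); expected single-channel pages"
            )
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: expected a single-channel multi-page TIFF, got array of shape {arr.shape}"
        )
    return arr


def read_intensity_stack(path, geometry: VoxelGeometry | None = None) -> IntensityVolume:
    """Read a multi-page grayscale TIFF as an :class:`IntensityVolume`.

    Page order maps to increasing z.  Voxel geometry does not travel inside
    the TIFF, so it is supplied by the caller (defaults to the confocal
    spacing the pipeline was designed around).
    """
    arr = _read_tiff_pages(path)
    if arr.dtype.kind not in "uif":
        raise UnsupportedFormatError(f"{path}: unsupported dtype {arr.dtype}")
    return IntensityVolume(arr.astype(np.float32), geometry or VoxelGeometry())


def write_intensity_stack(volume: IntensityVolume, path) -> None:
    """Write as 16-bit unsigned multi-page TIFF (values clipped to range)."""
    vals = np.clip(np.round(volume.values), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, vals, photometric="minisblack")


def read_label_stack(path, geometry: VoxelGeometry | None = None) -> LabelVolume:
    """Read an integer label TIFF with codes in {0, 1, 2}."""
    arr = _read_tiff_pages(path)
    if arr.dtype.kind not in "ui":
        raise UnsupportedFormatError(f"{path}: label stack must be integer typed, got {arr.dtype}")
    return LabelVolume(arr.astype(np.uint8) if arr.max(initial=0) < 256 else arr,
                       geometry or VoxelGeometry())


def write_label_stack(volume: LabelVolume, path) -> None:
    tifffile.imwrite(path, volume.labels.astype(np.uint8), photometric="minisblack")


def read_mesh(path, structure_class: int = 2) -> TriangleMesh:
    """Load an OBJ/PLY surface; raises if the surface is not closed."""
    tm = trimesh.load(path, force="mesh", process=False)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise UnsupportedFormatError(f"{path}: no triangle mesh found")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), structure_class)


def write_mesh(mesh: TriangleMesh, path) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in (".obj", ".ply"):
        raise UnsupportedFormatError(f"unsupported mesh format {ext!r} (use .obj or .ply)")
    mesh.as_trimesh().export(path)
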