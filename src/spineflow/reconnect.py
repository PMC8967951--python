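"""Automatic reconnection of detached structure parts.

A structure (the dendritic shaft, or one spine) that appears as several
disconnected voxel components is repaired in five steps: clip to the
structure's bounding box, detect connected components, join components with
an A* path that trades geometric length against image density, median-filter
the confocal image, and flood-fill around the path within ellipsoid bounds
and an intensity tolerance.  The same machinery, restricted to a chosen pair
of components, powers the supervised reconnection of the postprocessing
stage.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import ReconnectConfig
from .core import (
    IntensityVolume,
    LabelVolume,
    NoPathError,
    SHAFT,
    SPINE,
    SpineflowError,
    ValidationError,
    VoxelGeometry,
)


class EmptyStructureError(SpineflowError):
    pass


# ---------------------------------------------------------------------------
# components

@dataclass
class Component:
    id: int
    structure_class: int
    voxels: np.ndarray  # (n, 3) zyx indices
    size_voxels: int
    size_um3: float
    bbox: Tuple[Tuple[int, int, int], Tuple[int, int, int]]  # zyx lo, hi inclusive


@dataclass
class ComponentSet:
    components: List[Component] = field(default_factory=list)

    def __len__(self):
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def largest_first(self) -> List[Component]:
        return sorted(self.components, key=lambda c: -c.size_voxels)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")


def find_components(
    labels: LabelVolume | np.ndarray,
    structure_class: Optional[int] = None,
    connectivity: int = 26,
    geometry: Optional[VoxelGeometry] = None,
) -> ComponentSet:
    """Connected components of one class (or of a boolean mask)."""
    if isinstance(labels, LabelVolume):
        geometry = geometry or labels.geometry
        if structure_class is None:
            raise ValidationError("structure_class required with a LabelVolume")
        mask = labels.labels == structure_class
    else:
        mask = np.asarray(labels, dtype=bool)
    geometry = geometry or VoxelGeometry()
    voxel_vol = float(np.prod(geometry.voxel_size))

    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    comps = []
    if n:
        objects = ndimage.find_objects(lab)
        for i, sl in enumerate(objects, start=1):
            vox = np.argwhere(lab == i)
            comps.append(
                Component(
                    id=i,
                    structure_class=structure_class or 0,
                    voxels=vox,
                    size_voxels=len(vox),
                    size_um3=len(vox) * voxel_vol,
                    bbox=(tuple(int(s.start) for s in sl), tuple(int(s.stop) - 1 for s in sl)),
                )
            )
    return ComponentSet(comps)


# ---------------------------------------------------------------------------
# clipping

def clip_bounding_box(
    labels: LabelVolume,
    intensity: IntensityVolume,
    structure_mask: np.ndarray,
    pad_xyz: Sequence[int] = (0, 0, 0),
):
    """Clip both volumes to the structure's padded AABB.

    Returns ``(labels_clip, intensity_clip, offset_zyx)`` where the arrays
    are copies and ``offset_zyx`` re-embeds edits losslessly.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise EmptyStructureError("structure has no voxels")
    pad_zyx = (int(pad_xyz[2]), int(pad_xyz[1]), int(pad_xyz[0]))
    lo, hi = [], []
    for ax, pad in enumerate(pad_zyx):
        idx = np.nonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))[0]
        lo.append(max(0, int(idx[0]) - pad))
        hi.append(min(mask.shape[ax], int(idx[-1]) + 1 + pad))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return labels.labels[sl].copy(), intensity.values[sl].copy(), tuple(lo)


# ---------------------------------------------------------------------------
# path cost

@dataclass
class Path:
    """Ordered voxel chain with its cost under the length/density objective."""

    voxels: List[Tuple[int, int, int]]  # zyx
    cost: float


def _step_lengths(connectivity: int, spacing_zyx, physical: bool):
    offsets = [
        off
        for off in itertools.product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0) and (connectivity == 26 or sum(map(abs, off)) == 1)
    ]
    sp = np.asarray(spacing_zyx) if physical else np.ones(3)
    dists = [float(np.linalg.norm(np.asarray(off) * sp)) for off in offsets]
    return offsets, dists


def normalized_density(intensity_clip: np.ndarray) -> np.ndarray:
    """Min-max normalize a clip to [0, 1]; a constant clip maps to zeros."""
    clip = np.asarray(intensity_clip, dtype=np.float64)
    lo, hi = clip.min(), clip.max()
    if hi == lo:
        return np.zeros_like(clip)
    return (clip - lo) / (hi - lo)


def path_cost(
    path: Sequence[Tuple[int, int, int]],
    den_volume: np.ndarray,
    config: ReconnectConfig,
    geometry: Optional[VoxelGeometry] = None,
) -> float:
    """Evaluate sum_i (1 - den(p_i)) * f_s  +  sum_i dist(p_{i-1}, p_i)."""
    geometry = geometry or VoxelGeometry()
    den = np.asarray(den_volume)
    vox = np.asarray(path, dtype=int)
    if np.any(vox < 0) or np.any(vox >= np.asarray(den.shape)):
        raise IndexError("path voxel outside volume")
    density_term = float(np.sum(1.0 - den[vox[:, 0], vox[:, 1], vox[:, 2]])) * config.f_s
    if len(vox) < 2:
        return density_term
    steps = np.diff(vox, axis=0).astype(float)
    if config.distance_units == "physical":
        steps = steps * np.asarray(geometry.spacing_zyx)
    return density_term + float(np.linalg.norm(steps, axis=1).sum())


# ---------------------------------------------------------------------------
# A* search

def astar_connect(
    source_mask: np.ndarray,
    target_mask: np.ndarray,
    den_volume: np.ndarray,
    config: ReconnectConfig,
    geometry: Optional[VoxelGeometry] = None,
    blocked: Optional[np.ndarray] = None,
) -> Path:
    """Cost-optimal connecting path from a component to any target component.

    The path starts on ``source_mask``, ends on ``target_mask`` and minimizes
    the combined density/length objective.  Voxels of other anatomical
    structures (``blocked``) are excluded from the search space.  The
    heuristic is the straight-line distance to the nearest target voxel,
    admissible because the per-voxel density term is non-negative.
    """
    geometry = geometry or VoxelGeometry()
    den = np.asarray(den_volume, dtype=np.float64)
    shape = den.shape
    src = np.asarray(source_mask, dtype=bool)
    tgt = np.asarray(target_mask, dtype=bool)
    if not src.any() or not tgt.any():
        raise EmptyStructureError("source and target components must be non-empty")
    physical = config.distance_units == "physical"
    spacing = geometry.spacing_zyx if physical else (1.0, 1.0, 1.0)

    free = np.ones(shape, dtype=bool)
    if blocked is not None:
        free &= ~np.asarray(blocked, dtype=bool)
    free |= src | tgt

    # admissible heuristic: Euclidean distance to the nearest target voxel
    h = ndimage.distance_transform_edt(~tgt, sampling=spacing)

    node_cost = (1.0 - den) * config.f_s
    offsets, dists = _step_lengths(config.connectivity, spacing, True)

    g = np.full(shape, np.inf)
    parent = np.full(shape, -1, dtype=np.int64)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    heap = []
    counter = itertools.count()
    for z, y, x in np.argwhere(src):
        c = node_cost[z, y, x]
        if c < g[z, y, x]:
            g[z, y, x] = c
            heapq.heappush(heap, (c + h[z, y, x], next(counter), (z, y, x)))

    closed = np.zeros(shape, dtype=bool)
    end = None
    while heap:
        f, _, (z, y, x) = heapq.heappop(heap)
        if closed[z, y, x]:
            continue
        closed[z, y, x] = True
        if tgt[z, y, x]:
            end = (z, y, x)
            break
        gz = g[z, y, x]
        for (dz, dy, dx), step in zip(offsets, dists):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                continue
            if closed[nz, ny, nx] or not free[nz, ny, nx]:
                continue
            cand = gz + step + node_cost[nz, ny, nx]
            if cand < g[nz, ny, nx] - 1e-15:
                g[nz, ny, nx] = cand
                parent[nz, ny, nx] = z * strides[0] + y * strides[1] + x
                heapq.heappush(heap, (cand + h[nz, ny, nx], next(counter), (nz, ny, nx)))

    if end is None:
        raise NoPathError("no admissible path between the components")

    path = [end]
    while True:
        p = parent[path[-1]]
        if p < 0:
            break
        path.append((int(p // strides[0]), int(p % strides[0] // strides[1]), int(p % strides[1])))
    path.reverse()
    return Path(voxels=path, cost=float(g[end]))


# ---------------------------------------------------------------------------
# median filter and flooding

def median_denoise(
    intensity: np.ndarray, mask_xyz: Sequence[int] = (8, 8, 2)
) -> np.ndarray:
    """Median filter with an (x, y, z) window; reflective borders.

    Even window extents are anchored with the extra reach toward the
    positive axis direction, and the upper median (rank n/2, 0-based) is
    taken for even-count windows.
    """
    size_zyx = (int(mask_xyz[2]), int(mask_xyz[1]), int(mask_xyz[0]))
    if min(size_zyx) < 1:
        raise ValidationError("median mask must be positive on every axis")
    origin = tuple(-1 if s % 2 == 0 else 0 for s in size_zyx)
    return ndimage.median_filter(
        np.asarray(intensity, dtype=np.float64), size=size_zyx, mode="reflect", origin=origin
    )


def _ellipsoid_offsets(semi_xyz: Sequence[int]) -> np.ndarray:
    """Integer zyx offsets inside an axis-aligned ellipsoid with the given
    per-axis semi-axes in voxels (0 semi-axis = no extent on that axis)."""
    a, b, c = (int(v) for v in semi_xyz)  # x, y, z
    out = []
    for dz in range(-c, c + 1):
        for dy in range(-b, b + 1):
            for dx in range(-a, a + 1):
                t = 0.0
                for d, s in ((dx, a), (dy, b), (dz, c)):
                    if s == 0:
                        if d != 0:
                            t = np.inf
                    else:
                        t += (d / s) ** 2
                if t <= 1.0 + 1e-12:
                    out.append((dz, dy, dx))
    return np.asarray(out, dtype=int)


def _stamp(mask: np.ndarray, centers: np.ndarray, offsets: np.ndarray) -> None:
    """Set mask at centers+offsets, clipped to bounds."""
    if len(centers) == 0 or len(offsets) == 0:
        return
    pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    ok = np.all((pts >= 0) & (pts < np.asarray(mask.shape)), axis=1)
    pts = pts[ok]
    mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def flood_from_path(
    path: Path,
    filtered_intensity: np.ndarray,
    config: ReconnectConfig,
    max_ellipsoid_xyz: Sequence[int],
    blocked: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Voxels to relabel around a connecting path.

    Every voxel inside the minimum ellipsoid around each path voxel (seed) is
    taken unconditionally.  From each seed, a flood fill adds voxels whose
    filtered intensity lies within ±tolerance of that seed's intensity,
    constrained to the union of maximum ellipsoids centred on the path and
    never crossing into other structures.
    """
    img = np.asarray(filtered_intensity, dtype=np.float64)
    shape = img.shape
    seeds = np.asarray(path.voxels, dtype=int)

    grow_region = np.zeros(shape, dtype=bool)
    _stamp(grow_region, seeds, _ellipsoid_offsets(max_ellipsoid_xyz))

    result = np.zeros(shape, dtype=bool)
    _stamp(result, seeds, _ellipsoid_offsets(config.min_ellipsoid))

    if blocked is not None:
        blk = np.asarray(blocked, dtype=bool)
        grow_region &= ~blk
        result &= ~blk
        # path voxels themselves always belong to the structure being repaired
        result[seeds[:, 0], seeds[:, 1], seeds[:, 2]] = True

    offsets, _ = _step_lengths(config.connectivity, (1, 1, 1), False)
    shape_arr = np.asarray(shape)
    for z, y, x in seeds:
        ref = img[z, y, x]
        lo, hi = ref * (1 - config.tolerance), ref * (1 + config.tolerance)
        if lo > hi:
            lo, hi = hi, lo
        ok = grow_region & (img >= lo - 1e-12) & (img <= hi + 1e-12)
        if not ok[z, y, x]:
            continue
        visited = np.zeros(shape, dtype=bool)
        stack = [(z, y, x)]
        visited[z, y, x] = True
        while stack:
            cz, cy, cx = stack.pop()
            result[cz, cy, cx] = True
            for dz, dy, dx in offsets:
                nz, ny, nx = cz + dz, cy + dy, cx + dx
                if 0 <= nz < shape_arr[0] and 0 <= ny < shape_arr[1] and 0 <= nx < shape_arr[2]:
                    if ok[nz, ny, nx] and not visited[nz, ny, nx]:
                        visited[nz, ny, nx] = True
                        stack.append((nz, ny, nx))
    return result


# ---------------------------------------------------------------------------
# structure-level driver

@dataclass
class ReconnectReport:
    structure: str
    components_before: int
    components_after: int
    paths: List[Path] = field(default_factory=list)
    voxels_added: int = 0
    warnings: List[str] = field(default_factory=list)


def _adjacent(mask_a: np.ndarray, mask_b: np.ndarray, connectivity: int = 26) -> bool:
    return bool((ndimage.binary_dilation(mask_a, structure=_structure(connectivity)) & mask_b).any())


def reconnect_structure(
    labels: LabelVolume,
    intensity: IntensityVolume,
    structure_mask: np.ndarray,
    structure_class: int,
    config: ReconnectConfig,
    blocked: Optional[np.ndarray] = None,
    max_ellipsoid_xyz: Optional[Sequence[int]] = None,
    name: str = "structure",
) -> Tuple[LabelVolume, ReconnectReport]:
    """Join all disconnected parts of one structure into a single component.

    Components are traversed largest first; each detached component is joined
    to the rest via A* and flood fill, and flooded voxels take the
    structure's class.  Stops when one component remains, or reports a
    warning for components that admit no path.  Never removes voxels.
    """
    if max_ellipsoid_xyz is None:
        max_ellipsoid_xyz = (
            config.max_ellipsoid_shaft if structure_class == SHAFT else config.max_ellipsoid_spine
        )
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise EmptyStructureError(f"{name} has no voxels")

    out = labels.labels.copy()
    comps = find_components(mask, structure_class, config.connectivity, labels.geometry)
    report = ReconnectReport(name, len(comps), len(comps))
    if len(comps) <= 1:
        return LabelVolume(out, labels.geometry), report

    lab_clip, int_clip, off = clip_bounding_box(labels, intensity, mask, pad_xyz=max_ellipsoid_xyz)
    sl = tuple(slice(o, o + s) for o, s in zip(off, lab_clip.shape))
    mask_c = mask[sl].copy()
    blk_c = np.asarray(blocked, dtype=bool)[sl] if blocked is not None else None

    den = normalized_density(int_clip)
    filtered = median_denoise(int_clip, config.median_mask)
    geom = labels.geometry

    failed: set = set()
    while True:
        cs = find_components(mask_c, structure_class, config.connectivity, geom)
        report.components_after = len(cs)
        if len(cs) <= 1:
            break
        ordered = cs.largest_first()
        clab = np.zeros(mask_c.shape, dtype=np.int32)
        for c in ordered:
            clab[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = c.id
        progressed = False
        for comp in ordered[1:]:
            key = frozenset(map(tuple, comp.voxels[: min(3, len(comp.voxels))]))
            if key in failed:
                continue
            src = clab == comp.id
            tgt = mask_c & ~src
            try:
                path = astar_connect(src, tgt, den, config, geom, blocked=blk_c)
            except NoPathError:
                failed.add(key)
                report.warnings.append(
                    f"{name}: component of {comp.size_voxels} voxels could not be reconnected"
                )
                continue
            grown = flood_from_path(path, filtered, config, max_ellipsoid_xyz, blocked=blk_c)
            report.paths.append(
                Path([(z + off[0], y + off[1], x + off[2]) for z, y, x in path.voxels], path.cost)
            )
            new = grown & ~mask_c
            report.voxels_added += int(new.sum())
            mask_c |= grown
            progressed = True
            break
        if not progressed:
            break

    region = out[sl]
    newly = mask_c & ~mask[sl]
    region[newly] = structure_class
    out[sl] = region
    final = find_components(mask_c, structure_class, config.connectivity, geom)
    report.components_after = len(final)
    return LabelVolume(out, labels.geometry), report


def connect_spine_to_shaft(
    labels: LabelVolume,
    intensity: IntensityVolume,
    spine_mask: np.ndarray,
    config: ReconnectConfig,
    blocked: Optional[np.ndarray] = None,
) -> Tuple[LabelVolume, Optional[Path]]:
    """Attach one spine component to the dendritic shaft.

    Shaft voxels are the A* targets; flooded connector voxels take the spine
    class.  Returns the updated labels and the connecting path (None if the
    spine already touches the shaft)."""
    shaft = labels.labels == SHAFT
    spine = np.asarray(spine_mask, dtype=bool)
    if _adjacent(spine, shaft, config.connectivity):
        return labels, None
    if not shaft.any():
        raise EmptyStructureError("no dendritic shaft to connect to")

    lab_clip, int_clip, off = clip_bounding_box(
        labels, intensity, spine | shaft, pad_xyz=config.max_ellipsoid_spine
    )
    sl = tuple(slice(o, o + s) for o, s in zip(off, lab_clip.shape))
    den = normalized_density(int_clip)
    filtered = median_denoise(int_clip, config.median_mask)
    blk_c = np.asarray(blocked, dtype=bool)[sl] if blocked is not None else None

    path = astar_connect(spine[sl], shaft[sl], den, config, labels.geometry, blocked=blk_c)
    grown = flood_from_path(path, filtered, config, config.max_ellipsoid_spine, blocked=blk_c)

    out = labels.labels.copy()
    region = out[sl]
    region[grown & (region == 0)] = SPINE
    out[sl] = region
    full_path = Path([(z + off[0], y + off[1], x + off[2]) for z, y, x in path.voxels], path.cost)
    return LabelVolume(out, labels.geometry), full_path


def preprocess_ground_truth(
    labels: LabelVolume,
    intensity: IntensityVolume,
    config: Optional[ReconnectConfig] = None,
    spine_instances: Optional[np.ndarray] = None,
) -> Tuple[LabelVolume, List[ReconnectReport]]:
    """Fully automatic repair of detached parts in a ground-truth volume.

    First the dendritic shaft gaps are filled, then each spine is processed
    independently (spine identity from ``spine_instances`` when available,
    otherwise each spine component is taken as one spine), and finally every
    spine still detached from the shaft is connected to it.  Idempotent on
    already-connected volumes.
    """
    config = config or ReconnectConfig()
    reports: List[ReconnectReport] = []
    current = labels

    shaft = current.labels == SHAFT
    if shaft.any():
        current, rep = reconnect_structure(
            current, intensity, shaft, SHAFT, config,
            blocked=current.labels == SPINE,
            max_ellipsoid_xyz=config.max_ellipsoid_shaft, name="shaft",
        )
        reports.append(rep)

    if spine_instances is not None:
        inst = np.asarray(spine_instances)
        for i in np.unique(inst[inst > 0]):
            m = inst == i
            if len(find_components(m, SPINE, config.connectivity)) > 1:
                blocked = (current.labels == SHAFT) | ((current.labels == SPINE) & ~m)
                current, rep = reconnect_structure(
                    current, intensity, m, SPINE, config, blocked=blocked,
                    max_ellipsoid_xyz=config.max_ellipsoid_spine, name=f"spine {int(i)}",
                )
                reports.append(rep)

    # connect remaining detached spine components to the shaft
    shaft = current.labels == SHAFT
    if shaft.any():
        for comp in find_components(current, SPINE, config.connectivity).largest_first():
            m = np.zeros(current.labels.shape, dtype=bool)
            m[comp.voxels[:, 0], comp.voxels[:, 1], comp.voxels[:, 2]] = True
            if _adjacent(m, current.labels == SHAFT, config.connectivity):
                continue
            blocked = (current.labels == SPINE) & ~m
            try:
                current, _ = connect_spine_to_shaft(current, intensity, m, config, blocked=blocked)
            except NoPathError:
                reports.append(
                    ReconnectReport(
                        "spine-to-shaft", 1, 1,
                        warnings=[f"spine component of {comp.size_voxels} voxels left detached"],
                    )
                )
    return current, reports
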