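"""Correction algorithms over network predictions.

Noise removal of far small components, voxel relabeling, spine/shaft
instance extraction, supervised reconnection of a chosen component pair,
seeded watershed splitting of overlapping spines, marching-cubes surface
extraction, and the unconnected-spine-part statistic used to quantify how
much ground-truth preprocessing improves trained models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.segmentation import watershed

from .config import NoiseFilterConfig, ReconnectConfig
from .core import (
    InstanceVolume,
    IntensityVolume,
    LabelVolume,
    SHAFT,
    SPINE,
    SpineflowError,
    TriangleMesh,
    ValidationError,
    VoxelGeometry,
)
from .reconnect import (
    _structure,
    astar_connect,
    clip_bounding_box,
    find_components,
    flood_from_path,
    median_denoise,
    normalized_density,
)


class SeedError(SpineflowError):
    pass


# ---------------------------------------------------------------------------
# noise removal

@dataclass
class RemovalReport:
    removed: List[Dict] = field(default_factory=list)

    @property
    def removed_voxels(self) -> int:
        return sum(r["size_voxels"] for r in self.removed)


def _component_min_distance_um(vox_a: np.ndarray, centers_b: np.ndarray) -> float:
    """Minimum voxel-center distance between two voxel sets (coordinates in μm)."""
    best = np.inf
    for i in range(0, len(vox_a), 2048):
        chunk = vox_a[i:i + 2048]
        d2 = ((chunk[:, None, :] - centers_b[None, :, :]) ** 2).sum(axis=2)
        best = min(best, float(d2.min()))
    return float(np.sqrt(best))


def remove_noise(
    labels: LabelVolume,
    cfg: Optional[NoiseFilterConfig] = None,
    connectivity: int = 26,
) -> Tuple[LabelVolume, RemovalReport]:
    """Delete small components far from any sizeable dendritic shaft.

    A component is removed iff its minimal voxel-center distance to the
    nearest shaft component with volume > ``V_d`` exceeds ``D`` *and* its
    own volume is below ``V_s``.  When no shaft component exceeds ``V_d``,
    every candidate counts as far and only the size test decides.  Surviving
    components are untouched."""
    cfg = cfg or NoiseFilterConfig()
    geom = labels.geometry
    out = labels.labels.copy()
    report = RemovalReport()

    shaft_comps = find_components(labels, SHAFT, connectivity)
    anchors = [c for c in shaft_comps if c.size_um3 > cfg.V_d]
    anchor_centers = (
        np.concatenate([geom.index_to_um(c.voxels) for c in anchors]) if anchors else None
    )

    class_map = {"shaft": SHAFT, "spine": SPINE}
    for name in cfg.apply_to:
        cls = class_map[name]
        for comp in find_components(labels, cls, connectivity):
            if cls == SHAFT and any(a.id == comp.id for a in anchors):
                continue
            if comp.size_um3 >= cfg.V_s:
                continue
            if anchor_centers is not None:
                dist = _component_min_distance_um(geom.index_to_um(comp.voxels), anchor_centers)
                if dist <= cfg.D:
                    continue
            else:
                dist = np.inf
            report.removed.append(
                {"class": name, "size_voxels": comp.size_voxels, "size_um3": comp.size_um3,
                 "distance_um": dist}
            )
            out[comp.voxels[:, 0], comp.voxels[:, 1], comp.voxels[:, 2]] = 0
    return LabelVolume(out, geom), report


# ---------------------------------------------------------------------------
# relabeling and instances

def relabel_selection(
    labels: LabelVolume, voxels_zyx: Sequence[Tuple[int, int, int]], new_code: int
) -> LabelVolume:
    """Set exactly the selected voxels to a new class code."""
    if new_code not in (0, SHAFT, SPINE):
        raise ValidationError(f"new code must be 0, 1 or 2, got {new_code}")
    out = labels.labels.copy()
    vox = np.asarray(list(voxels_zyx), dtype=int).reshape(-1, 3)
    if len(vox) == 0:
        return LabelVolume(out, labels.geometry)
    if np.any(vox < 0) or np.any(vox >= np.asarray(out.shape)):
        raise ValidationError("selection contains voxels outside the volume")
    out[vox[:, 0], vox[:, 1], vox[:, 2]] = new_code
    return LabelVolume(out, labels.geometry)


def extract_instances(labels: LabelVolume, connectivity: int = 26) -> InstanceVolume:
    """Connected components of spine and shaft classes as tagged instances."""
    ids = np.zeros(labels.labels.shape, dtype=np.int32)
    class_of: Dict[int, int] = {}
    next_id = 1
    for cls in (SHAFT, SPINE):
        lab, n = ndimage.label(labels.labels == cls, structure=_structure(connectivity))
        for i in range(1, n + 1):
            ids[lab == i] = next_id
            class_of[next_id] = cls
            next_id += 1
    return InstanceVolume(ids, class_of, labels.geometry)


# ---------------------------------------------------------------------------
# supervised reconnection

def connect_components_supervised(
    labels: LabelVolume,
    intensity: IntensityVolume,
    source_mask: np.ndarray,
    target_mask: np.ndarray,
    config: Optional[ReconnectConfig] = None,
    target_class: int = SPINE,
) -> LabelVolume:
    """One reconnection step restricted to a user-chosen component pair.

    The caller picks the source and target components (and may override the
    ellipsoid masks, median window and flood tolerance through ``config``);
    flooded voxels take ``target_class``."""
    config = config or ReconnectConfig()
    src = np.asarray(source_mask, dtype=bool)
    tgt = np.asarray(target_mask, dtype=bool)
    if not src.any() or not tgt.any():
        raise ValidationError("source and target components must be non-empty")
    if (src & tgt).any():
        raise ValidationError("source and target components must be distinct")
    max_ell = (
        config.max_ellipsoid_shaft if target_class == SHAFT else config.max_ellipsoid_spine
    )
    _, int_clip, off = clip_bounding_box(labels, intensity, src | tgt, pad_xyz=max_ell)
    sl = tuple(slice(o, o + s) for o, s in zip(off, int_clip.shape))
    other = (labels.labels > 0) & ~(src | tgt)
    den = normalized_density(int_clip)
    filtered = median_denoise(int_clip, config.median_mask)
    path = astar_connect(src[sl], tgt[sl], den, config, labels.geometry, blocked=other[sl])
    grown = flood_from_path(path, filtered, config, max_ell, blocked=other[sl])
    out = labels.labels.copy()
    region = out[sl]
    region[grown & (region == 0)] = target_class
    out[sl] = region
    return LabelVolume(out, labels.geometry)


# ---------------------------------------------------------------------------
# watershed splitting

def watershed_split(
    instance_mask: np.ndarray,
    seeds_zyx: Sequence[Tuple[int, int, int]],
    geometry: Optional[VoxelGeometry] = None,
    intensity: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Split one instance into per-seed instances by marker-based watershed.

    The relief is the negated (anisotropy-aware) Euclidean distance
    transform of the mask, so splits land on the neck/ridge between lobes;
    pass ``intensity`` to flood a negated-intensity relief instead.  The
    output partition covers the mask exactly and each seed keeps its own
    instance tag (1-based, in seed order)."""
    mask = np.asarray(instance_mask, dtype=bool)
    seeds = np.asarray(list(seeds_zyx), dtype=int).reshape(-1, 3)
    if len(seeds) == 0:
        raise SeedError("at least one seed is required")
    for s in seeds:
        if np.any(s < 0) or np.any(s >= np.asarray(mask.shape)) or not mask[tuple(s)]:
            raise SeedError(f"seed {tuple(int(v) for v in s)} lies outside the instance mask")
    geometry = geometry or VoxelGeometry()
    if intensity is not None:
        relief = -np.asarray(intensity, dtype=np.float64)
    else:
        relief = -ndimage.distance_transform_edt(mask, sampling=geometry.spacing_zyx)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, s in enumerate(seeds, start=1):
        markers[tuple(s)] = i
    return watershed(relief, markers=markers, mask=mask)


# ---------------------------------------------------------------------------
# surface extraction

def mesh_from_labels(
    instances: InstanceVolume, geometry: Optional[VoxelGeometry] = None
) -> List[TriangleMesh]:
    """Per-instance marching-cubes surfaces at iso-level 0.5, vertices in μm.

    Masks are zero-padded by one voxel so instances away from the border
    yield watertight meshes; no smoothing is applied."""
    geometry = geometry or instances.geometry
    sz, sy, sx = geometry.spacing_zyx
    meshes = []
    for i in instances.instance_ids:
        mask = instances.ids == i
        if not mask.any():
            continue
        padded = np.pad(mask.astype(np.float32), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(sz, sy, sx))
        # padded voxel p corresponds to voxel p-1; voxel centers sit at (i+0.5)*s
        verts_zyx = verts + np.array([(-1 + 0.5) * sz, (-1 + 0.5) * sy, (-1 + 0.5) * sx])
        verts_xyz = verts_zyx[:, ::-1] + np.asarray(geometry.origin)
        meshes.append(TriangleMesh(verts_xyz, faces, instances.class_of[i]))
    return meshes


# ---------------------------------------------------------------------------
# connectivity statistics

@dataclass
class UnconnectedCounts:
    unconnected: int  # predicted spine parts (with GT overlap) not touching predicted shaft
    total_considered: int  # predicted spine parts with GT overlap


def count_unconnected_spine_parts(
    pred: LabelVolume, gt: Optional[LabelVolume] = None, connectivity: int = 26
) -> UnconnectedCounts:
    """Count predicted spine components detached from any predicted shaft voxel.

    Only components that share at least one voxel with the ground-truth
    spine class are considered (predictions of structures the annotators
    skipped are ignored).  Pass ``gt=None`` (or the volume itself) to score
    a single volume against itself, e.g. counting detached spine components
    of a raw annotation."""
    if gt is None:
        gt = pred
    if pred.labels.shape != gt.labels.shape:
        raise ValidationError("volumes must be aligned")
    gt_spine = gt.labels == SPINE
    shaft = pred.labels == SHAFT
    shaft_halo = ndimage.binary_dilation(shaft, structure=_structure(26))
    n_unconnected = 0
    n_total = 0
    for comp in find_components(pred, SPINE, connectivity):
        m = np.zeros(pred.labels.shape, dtype=bool)
        m[comp.voxels[:, 0], comp.voxels[:, 1], comp.voxels[:, 2]] = True
        if not (m & gt_spine).any():
            continue
        n_total += 1
        if not (m & shaft_halo).any():
            n_unconnected += 1
    return UnconnectedCounts(n_unconnected, n_total)


def improvement_ratio(before: int, after: int) -> float:
    """Percentage reduction 100*(before-after)/before, to 2 decimals."""
    if before <= 0:
        raise ValidationError("improvement ratio needs a positive baseline count")
    return round(100.0 * (before - after) / before, 2)
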