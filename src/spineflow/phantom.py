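"""Synthetic dendrite phantoms: paired confocal-like stacks and ground truth.

A phantom is a tubular dendritic shaft along a smooth random polyline with
spherical spine heads attached through thin cylindrical necks.  The
intensity channel is the structure indicator blurred by an anisotropic
Gaussian PSF (axially elongated, as in confocal stacks) with additive
sensor noise.  Two weak-annotation defects can be injected: spine necks
erased from the labels while the image keeps them (unattached components),
and a collateral branch visible in the image but absent from the labels
(missing reconstructions).  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .config import PhantomConfig
from .core import (
    IntensityVolume,
    LabelVolume,
    SHAFT,
    SPINE,
    TriangleMesh,
    ValidationError,
    VoxelGeometry,
)


@dataclass
class SpineRecord:
    head_center_um: Tuple[float, float, float]  # xyz
    head_radius_um: float
    neck_length_um: float
    attach_um: Tuple[float, float, float]
    broken: bool


@dataclass
class PhantomTruth:
    spines: List[SpineRecord] = field(default_factory=list)
    broken_count: int = 0
    skipped_spines: int = 0
    missing_branch: bool = False
    seed: int = 0


def _grid_coords_um(shape_zyx, geometry: VoxelGeometry) -> Tuple[np.ndarray, ...]:
    """Voxel-center coordinate grids (x, y, z), each shaped (z, y, x)."""
    nz, ny, nx = shape_zyx
    sx, sy, sz = geometry.voxel_size
    ox, oy, oz = geometry.origin
    zs = oz + (np.arange(nz) + 0.5) * sz
    ys = oy + (np.arange(ny) + 0.5) * sy
    xs = ox + (np.arange(nx) + 0.5) * sx
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    return X, Y, Z


def _dist_to_segment(X, Y, Z, p0, p1) -> np.ndarray:
    """Distance from every voxel center to a 3-D segment (all in μm)."""
    d = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    L2 = float(d @ d)
    vx, vy, vz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 == 0:
        return np.sqrt(vx**2 + vy**2 + vz**2)
    t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / L2, 0.0, 1.0)
    return np.sqrt((vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2)


def _dist_to_polyline(X, Y, Z, pts: np.ndarray) -> np.ndarray:
    d = np.full(X.shape, np.inf)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        np.minimum(d, _dist_to_segment(X, Y, Z, p0, p1), out=d)
    return d


def generate_phantom(
    cfg: Optional[PhantomConfig] = None,
) -> Tuple[IntensityVolume, LabelVolume, PhantomTruth]:
    """Generate one phantom: intensity stack, 3-class labels, and truth record.

    With ``neck_break_probability`` > 0, selected spines have their neck
    erased from the labels only, leaving a detached head whose bright neck
    is still present in the image — the scenario the reconnection stage is
    built for.  Spines that cannot be placed without overlap after bounded
    retries are skipped and counted in the truth record.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.shape
    geometry = VoxelGeometry(cfg.voxel_size)
    shape_zyx = (nz, ny, nx)
    X, Y, Z = _grid_coords_um(shape_zyx, geometry)
    ext = np.array([nx, ny, nz]) * np.asarray(cfg.voxel_size)

    # --- shaft: smooth polyline along x around the volume mid-plane
    n_ctrl = 7
    xs = np.linspace(0.0, ext[0], n_ctrl)
    amp_y = min(0.15 * ext[1], 1.0)
    amp_z = min(0.10 * ext[2], 0.5)
    phase_y, phase_z = rng.uniform(0, 2 * np.pi, size=2)
    ys = ext[1] / 2 + amp_y * np.sin(2 * np.pi * xs / ext[0] + phase_y)
    zs = ext[2] / 2 + amp_z * np.sin(2 * np.pi * xs / ext[0] + phase_z)
    ctrl = np.stack([xs, ys, zs], axis=1)
    shaft_dist = _dist_to_polyline(X, Y, Z, ctrl)
    shaft_mask = shaft_dist <= cfg.shaft_radius

    labels = np.zeros(shape_zyx, dtype=np.uint8)
    labels[shaft_mask] = SHAFT
    instances = np.zeros(shape_zyx, dtype=np.int32)

    # --- spines: heads on necks, perpendicular-ish to the shaft
    truth = PhantomTruth(seed=cfg.seed, missing_branch=cfg.missing_branch)
    placed_heads: List[Tuple[np.ndarray, float]] = []
    spine_id = 0
    bright = np.zeros(shape_zyx, dtype=np.float64)
    bright[shaft_mask] = 1.0

    spine_any = np.zeros(shape_zyx, dtype=bool)
    for _ in range(cfg.spine_count):
        ok = False
        for _attempt in range(25):
            t = rng.uniform(0.1, 0.9)
            seg = min(int(t * (n_ctrl - 1)), n_ctrl - 2)
            frac = t * (n_ctrl - 1) - seg
            axis_pt = ctrl[seg] * (1 - frac) + ctrl[seg + 1] * frac
            ang = rng.uniform(0, 2 * np.pi)
            tilt = rng.uniform(-0.3, 0.3)
            u = np.array([tilt, np.cos(ang), np.sin(ang) * 0.5])
            u /= np.linalg.norm(u)
            r_h = rng.uniform(*cfg.head_radius_range)
            L = rng.uniform(*cfg.neck_length_range)
            attach = axis_pt + u * (cfg.shaft_radius * 0.5)
            head = axis_pt + u * (cfg.shaft_radius + L + r_h)
            if np.any(head - r_h < 0.05) or np.any(head + r_h > ext - 0.05):
                continue
            if any(np.linalg.norm(head - h) < r_h + r2 + 0.15 for h, r2 in placed_heads):
                continue
            neck_dist = _dist_to_segment(X, Y, Z, attach, head)
            head_dist = np.sqrt(
                (X - head[0]) ** 2 + (Y - head[1]) ** 2 + (Z - head[2]) ** 2
            )
            neck_mask = neck_dist <= cfg.neck_radius
            # necks are thinner than the axial voxel size: also stamp the voxel
            # chain under the neck axis so the rasterized spine stays connected
            for t in np.linspace(0, 1, 256):
                p = attach * (1 - t) + head * t
                k = np.floor(
                    (p - np.asarray(geometry.origin)) / np.asarray(cfg.voxel_size)
                ).astype(int)
                if np.all(k >= 0) and np.all(k < np.array([nx, ny, nz])):
                    neck_mask[k[2], k[1], k[0]] = True
            head_mask = head_dist <= r_h
            spine_mask = neck_mask | head_mask
            # keep rasterized spines separated so each stays its own component
            halo = ndimage.binary_dilation(
                spine_mask, structure=ndimage.generate_binary_structure(3, 3)
            )
            if (halo & spine_any).any():
                continue
            ok = True
            break
        if not ok:
            truth.skipped_spines += 1
            continue

        spine_id += 1
        spine_any |= spine_mask
        labels[spine_mask] = SPINE  # spine precedence over shaft at the joint
        instances[spine_mask] = spine_id
        bright[spine_mask] = 1.0
        placed_heads.append((head, r_h))

        broken = bool(rng.random() < cfg.neck_break_probability)
        if broken:
            # erase the neck, plus any head voxel touching the shaft, so the
            # remaining head is guaranteed detached
            shaft_halo = ndimage.binary_dilation(
                shaft_mask, structure=ndimage.generate_binary_structure(3, 3)
            )
            erase = (spine_mask & ~head_mask) | (spine_mask & shaft_halo)
            labels[erase] = np.where(shaft_mask[erase], SHAFT, 0)
            instances[erase] = 0
            truth.broken_count += 1
        truth.spines.append(
            SpineRecord(tuple(head), r_h, L, tuple(attach), broken)
        )

    # --- missing reconstruction: a collateral branch only the image shows
    if cfg.missing_branch:
        y0 = rng.uniform(0.15, 0.25) * ext[1]
        branch = np.stack(
            [np.linspace(0, ext[0], 4),
             np.full(4, y0) + rng.uniform(-0.3, 0.3, 4),
             np.full(4, ext[2] * 0.5) + rng.uniform(-0.2, 0.2, 4)],
            axis=1,
        )
        branch_mask = _dist_to_polyline(X, Y, Z, branch) <= cfg.shaft_radius * 0.8
        bright[branch_mask] = 1.0

    # --- imaging: anisotropic PSF blur + sensor noise on a 16-bit scale
    img = bright * cfg.peak_intensity
    sx, sy, sz = cfg.voxel_size
    sigma_vox = (cfg.psf_sigma_z / sz, cfg.psf_sigma_xy / sy, cfg.psf_sigma_xy / sx)
    if max(sigma_vox) > 0:
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if cfg.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 65535.0)

    intensity = IntensityVolume(img.astype(np.float32), geometry)
    label_volume = LabelVolume(labels, geometry)
    label_volume.spine_instances = instances  # per-spine provenance
    return intensity, label_volume, truth


# ---------------------------------------------------------------------------
# analytic mesh fixtures

def generate_mesh_fixture(kind: str, params: Optional[Dict] = None) -> TriangleMesh:
    """Watertight analytic meshes for exercising the voxelizer.

    kinds: ``icosphere`` (radius, subdivisions, center), ``box`` (extents,
    center), ``dumbbell`` (two spheres of given radius joined by a neck
    cylinder; built as an iso-surface of the union distance field so the
    result is closed)."""
    params = dict(params or {})
    cls = int(params.pop("structure_class", SPINE))
    if kind == "icosphere":
        radius = float(params.pop("radius", 1.0))
        subdiv = int(params.pop("subdivisions", 3))
        center = np.asarray(params.pop("center", (0.0, 0.0, 0.0)))
        tm = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
        return TriangleMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces), cls)
    if kind == "box":
        extents = np.asarray(params.pop("extents", (1.0, 1.0, 1.0)), dtype=float)
        center = np.asarray(params.pop("center", (0.0, 0.0, 0.0)))
        tm = trimesh.creation.box(extents=extents)
        return TriangleMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces), cls)
    if kind == "dumbbell":
        r = float(params.pop("radius", 1.0))
        sep = float(params.pop("separation", 3.0))
        neck = float(params.pop("neck_radius", 0.35 * r))
        res = int(params.pop("resolution", 48))
        half = sep / 2
        lim = half + r * 1.5
        xs = np.linspace(-lim, lim, res)
        ys = np.linspace(-r * 1.5, r * 1.5, res)
        h = xs[1] - xs[0]
        Xg, Yg, Zg = np.meshgrid(xs, ys, ys, indexing="ij")
        s1 = np.sqrt((Xg + half) ** 2 + Yg**2 + Zg**2) - r
        s2 = np.sqrt((Xg - half) ** 2 + Yg**2 + Zg**2) - r
        cy = np.maximum(np.sqrt(Yg**2 + Zg**2) - neck, np.abs(Xg) - half)
        sdf = np.minimum(np.minimum(s1, s2), cy)
        verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=(h, h, h))
        verts = verts + np.array([xs[0], ys[0], ys[0]])
        return TriangleMesh(verts, faces, cls)
    raise ValidationError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# label corruption

def corrupt_labels(
    labels: LabelVolume,
    defect: str,
    params: Optional[Dict] = None,
    seed: int = 0,
) -> Tuple[LabelVolume, List[Dict]]:
    """Inject a weak-annotation defect into any label volume.

    ``break_necks``: for each spine component (chosen with probability
    ``rate``, default 1.0) erase its voxels within ``gap_um`` (default 0.35)
    of the shaft, detaching it.  ``drop_branch``: delete one whole labeled
    component of class ``class`` (default shaft, the smallest component).
    Returns the corrupted volume and a record of affected components."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    out = labels.labels.copy()
    record: List[Dict] = []
    from .reconnect import find_components  # local import avoids cycle at import time

    if defect == "break_necks":
        rate = float(params.pop("rate", 1.0))
        gap = float(params.pop("gap_um", 0.35))
        shaft = out == SHAFT
        if not shaft.any():
            return LabelVolume(out, labels.geometry), record
        d = ndimage.distance_transform_edt(~shaft, sampling=labels.geometry.spacing_zyx)
        for comp in find_components(labels, SPINE, 26):
            if rng.random() >= rate:
                continue
            m = np.zeros(out.shape, dtype=bool)
            m[comp.voxels[:, 0], comp.voxels[:, 1], comp.voxels[:, 2]] = True
            erase = m & (d <= gap)
            if erase.any() and not erase.all():
                out[erase] = 0
                record.append({"defect": "break_necks", "component_voxels": comp.size_voxels,
                               "erased_voxels": int(erase.sum())})
        return LabelVolume(out, labels.geometry), record

    if defect == "drop_branch":
        cls = int(params.pop("class", SHAFT))
        comps = find_components(labels, cls, 26).largest_first()
        if len(comps) > 0:
            victim = comps[-1] if len(comps) > 1 else comps[0]
            out[victim.voxels[:, 0], victim.voxels[:, 1], victim.voxels[:, 2]] = 0
            record.append({"defect": "drop_branch", "component_voxels": victim.size_voxels})
        return LabelVolume(out, labels.geometry), record

    raise ValidationError(f"unknown defect {defect!r}")
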