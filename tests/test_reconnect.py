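"""Gap reconnection: components, path search, median filter, flooding."""

import heapq
import itertools

import numpy as np
import pytest

from spineflow.config import ReconnectConfig
from spineflow.core import (
    IntensityVolume,
    LabelVolume,
    NoPathError,
    SHAFT,
    SPINE,
    VoxelGeometry,
)
from spineflow.reconnect import (
    EmptyStructureError,
    Path,
    astar_connect,
    clip_bounding_box,
    find_components,
    flood_from_path,
    median_denoise,
    normalized_density,
    path_cost,
    preprocess_ground_truth,
    reconnect_structure,
)

CONFOCAL = VoxelGeometry()


# ---------------------------------------------------------------------------
# independent oracles

def union_find_components(mask, connectivity):
    """Brute-force union-find partition of a boolean grid."""
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    vox = [tuple(v) for v in np.argwhere(mask)]
    for v in vox:
        parent[v] = v
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3)
            if o != (0, 0, 0) and (connectivity == 26 or sum(map(abs, o)) == 1)]
    for v in vox:
        for o in offs:
            u = tuple(np.add(v, o))
            if u in parent:
                ra, rb = find(v), find(u)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for v in vox:
        groups.setdefault(find(v), set()).add(v)
    return set(frozenset(g) for g in groups.values())


def dijkstra_cost(src, tgt, den, cfg, geom, blocked=None):
    """Plain Dijkstra over the same search space; returns optimal cost or None."""
    sp = geom.spacing_zyx if cfg.distance_units == "physical" else (1, 1, 1)
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3)
            if o != (0, 0, 0) and (cfg.connectivity == 26 or sum(map(abs, o)) == 1)]
    dists = [float(np.linalg.norm(np.array(o) * np.array(sp))) for o in offs]
    node = (1 - den) * cfg.f_s
    shape = den.shape
    free = np.ones(shape, bool)
    if blocked is not None:
        free &= ~blocked
    free |= src | tgt
    g, heap, cnt, seen = {}, [], itertools.count(), set()
    for v in map(tuple, np.argwhere(src)):
        g[v] = node[v]
        heapq.heappush(heap, (g[v], next(cnt), v))
    while heap:
        c, _, v = heapq.heappop(heap)
        if v in seen:
            continue
        seen.add(v)
        if tgt[v]:
            return c
        for o, d in zip(offs, dists):
            u = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if not all(0 <= u[i] < shape[i] for i in range(3)):
                continue
            if u in seen or not free[u]:
                continue
            nc = c + d + node[u]
            if nc < g.get(u, np.inf):
                g[u] = nc
                heapq.heappush(heap, (nc, next(cnt), u))
    return None


# ---------------------------------------------------------------------------

class TestFindComponents:
    def test_in_plane_diagonal_depends_on_connectivity(self):
        lab = np.zeros((1, 4, 4), dtype=np.uint8)
        lab[0, 1, 1] = SPINE
        lab[0, 2, 2] = SPINE
        vol = LabelVolume(lab)
        assert len(find_components(vol, SPINE, 26)) == 1
        assert len(find_components(vol, SPINE, 6)) == 2

    def test_empty_class_gives_empty_set(self):
        vol = LabelVolume(np.zeros((3, 3, 3), dtype=np.uint8))
        assert len(find_components(vol, SPINE, 26)) == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_union_find_oracle(self, rng, connectivity):
        for _ in range(5):
            mask = rng.random((8, 8, 8)) < 0.25
            got = find_components(mask, SPINE, connectivity)
            partition = set(
                frozenset(map(tuple, c.voxels)) for c in got
            )
            assert partition == union_find_components(mask, connectivity)

    def test_sizes_in_physical_units(self, confocal_geometry):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, :2] = True
        comps = find_components(mask, SPINE, 26, confocal_geometry)
        voxel_vol = np.prod(confocal_geometry.voxel_size)
        assert comps.components[0].size_um3 == pytest.approx(2 * voxel_vol)


class TestClipBoundingBox:
    def test_single_voxel_with_spine_padding(self):
        lab = np.zeros((8, 16, 16), dtype=np.uint8)
        lab[2, 5, 5] = SPINE
        mask = lab == SPINE
        labels = LabelVolume(lab)
        intensity = IntensityVolume(np.zeros_like(lab, dtype=float))
        clip, _, off = clip_bounding_box(labels, intensity, mask, pad_xyz=(6, 6, 2))
        assert off == (0, 0, 0)  # clamped at 2-6<0, 5-6<0
        assert clip.shape == (5, 12, 12)  # z: [0, 2+2+1), y/x: [0, 5+6+1)

    def test_structure_filling_volume_clips_whole_volume(self):
        lab = np.full((4, 4, 4), SHAFT, dtype=np.uint8)
        labels = LabelVolume(lab)
        intensity = IntensityVolume(np.zeros_like(lab, dtype=float))
        clip, _, off = clip_bounding_box(labels, intensity, lab > 0)
        assert clip.shape == (4, 4, 4) and off == (0, 0, 0)

    def test_empty_structure_raises(self):
        labels = LabelVolume(np.zeros((3, 3, 3), dtype=np.uint8))
        intensity = IntensityVolume(np.zeros((3, 3, 3)))
        with pytest.raises(EmptyStructureError):
            clip_bounding_box(labels, intensity, labels.labels > 0)


class TestPathCost:
    def test_single_voxel_full_density_costs_zero(self):
        den = np.ones((3, 3, 3))
        cfg = ReconnectConfig()
        assert path_cost([(1, 1, 1)], den, cfg, CONFOCAL) == 0.0

    def test_two_neighbor_hand_value(self):
        # two in-plane 6-neighbors along x, den 0.5 each, f_s=1, physical units
        den = np.full((3, 3, 3), 0.5)
        cfg = ReconnectConfig(f_s=1.0, distance_units="physical")
        cost = path_cost([(1, 1, 0), (1, 1, 1)], den, cfg, CONFOCAL)
        assert cost == pytest.approx(0.5 + 0.5 + 0.0751562, abs=1e-9)

    def test_fs_zero_reduces_to_geometric_length(self, rng):
        den = rng.random((5, 5, 5))
        path = [(0, 0, 0), (0, 0, 1), (0, 1, 2), (1, 2, 2)]
        cfg = ReconnectConfig(f_s=0.0, distance_units="voxel")
        expected = sum(
            np.linalg.norm(np.subtract(b, a)) for a, b in zip(path, path[1:])
        )
        assert path_cost(path, den, cfg) == pytest.approx(expected)

    def test_outside_volume_raises(self):
        with pytest.raises(IndexError):
            path_cost([(5, 5, 5)], np.zeros((3, 3, 3)), ReconnectConfig())


class TestNormalizedDensity:
    def test_constant_clip_maps_to_zero(self):
        assert np.all(normalized_density(np.full((4, 4, 4), 7.0)) == 0)

    def test_midpoint_maps_to_half(self):
        clip = np.arange(101, dtype=float).reshape(1, 1, 101)
        den = normalized_density(clip)
        assert den[0, 0, 50] == pytest.approx(0.5)
        assert den.min() == 0 and den.max() == 1


class TestAStar:
    def test_follows_bright_corridor(self):
        den = np.zeros((1, 9, 9))
        den[0, 4, :] = 1.0  # bright straight corridor
        src = np.zeros_like(den, bool)
        tgt = np.zeros_like(den, bool)
        src[0, 4, 0] = True
        tgt[0, 4, 8] = True
        cfg = ReconnectConfig(distance_units="voxel", f_s=1.0)
        path = astar_connect(src, tgt, den, cfg)
        assert all(v[1] == 4 for v in path.voxels)  # stays on the corridor
        assert path.cost == pytest.approx(dijkstra_cost(src, tgt, den, cfg, CONFOCAL))

    def test_adjacent_components_short_path(self):
        den = np.zeros((2, 3, 3))
        src = np.zeros_like(den, bool)
        tgt = np.zeros_like(den, bool)
        src[0, 0, 0] = True
        tgt[0, 0, 1] = True
        cfg = ReconnectConfig(distance_units="voxel")
        path = astar_connect(src, tgt, den, cfg)
        assert len(path.voxels) == 2
        assert path.cost == pytest.approx(dijkstra_cost(src, tgt, den, cfg, CONFOCAL))

    def test_uniform_intensity_geodesic_cost(self):
        den = np.full((6, 6, 6), 0.3)
        src = np.zeros_like(den, bool)
        tgt = np.zeros_like(den, bool)
        src[0, 0, 0] = True
        tgt[5, 5, 5] = True
        cfg = ReconnectConfig(distance_units="voxel", connectivity=26)
        path = astar_connect(src, tgt, den, cfg)
        assert path.cost == pytest.approx(dijkstra_cost(src, tgt, den, cfg, CONFOCAL))

    def test_no_path_raises(self):
        den = np.zeros((1, 3, 5))
        src = np.zeros_like(den, bool)
        tgt = np.zeros_like(den, bool)
        src[0, :, 0] = True
        tgt[0, :, 4] = True
        blocked = np.zeros_like(den, bool)
        blocked[0, :, 2] = True  # full wall
        with pytest.raises(NoPathError):
            astar_connect(src, tgt, den, ReconnectConfig(), CONFOCAL, blocked=blocked)

    def test_oracle_equality_random_instances(self, rng):
        """A* cost equals Dijkstra cost on randomized small instances."""
        cfgs = 0
        for _ in range(40):
            shape = tuple(rng.integers(4, 12, 3))
            den = rng.random(shape)
            src = np.zeros(shape, bool)
            tgt = np.zeros(shape, bool)
            src[tuple(rng.integers(0, shape))] = True
            t = tuple(rng.integers(0, shape))
            if src[t]:
                continue
            tgt[t] = True
            blocked = rng.random(shape) < 0.15
            cfg = ReconnectConfig(
                connectivity=int(rng.choice([6, 26])),
                f_s=float(rng.choice([0.0, 0.5, 1.0])),
                distance_units=str(rng.choice(["physical", "voxel"])),
            )
            oracle = dijkstra_cost(src, tgt, den, cfg, CONFOCAL, blocked)
            try:
                got = astar_connect(src, tgt, den, cfg, CONFOCAL, blocked=blocked).cost
            except NoPathError:
                got = None
            if oracle is None:
                assert got is None
            else:
                assert got == pytest.approx(oracle, abs=1e-9)
                cfgs += 1
        assert cfgs > 20  # most instances admit a path


class TestMedianDenoise:
    def test_constant_volume_unchanged(self):
        vol = np.full((6, 6, 6), 3.0)
        assert np.array_equal(median_denoise(vol, (8, 8, 2)), vol)

    def test_single_hot_voxel_suppressed(self):
        vol = np.zeros((3, 9, 9))
        vol[1, 4, 4] = 100.0
        out = median_denoise(vol, (3, 3, 1))
        assert out[1, 4, 4] == 0.0

    def test_matches_naive_sliding_window_oracle(self, rng):
        """Even windows reach one voxel further toward +axis; upper median."""
        vol = rng.random((8, 8, 8))
        size_xyz = (4, 3, 2)
        got = median_denoise(vol, size_xyz)
        sz, sy, sx = 2, 3, 4
        padded = np.pad(vol, [(s, s) for s in (sz, sy, sx)], mode="symmetric")

        def window_range(s):
            return range(-(s // 2 - 1), s // 2 + 1) if s % 2 == 0 else range(-(s // 2), s // 2 + 1)

        for z in range(8):
            for y in range(8):
                for x in range(8):
                    vals = sorted(
                        padded[z + sz + dz, y + sy + dy, x + sx + dx]
                        for dz in window_range(sz)
                        for dy in window_range(sy)
                        for dx in window_range(sx)
                    )
                    expected = vals[len(vals) // 2]  # upper median for even counts
                    assert got[z, y, x] == expected


class TestFloodFromPath:
    def test_zero_max_ellipsoid_yields_exactly_path(self):
        img = np.random.default_rng(0).random((5, 5, 5))
        path = Path([(2, 2, 1), (2, 2, 2), (2, 2, 3)], 0.0)
        cfg = ReconnectConfig(min_ellipsoid=(0, 0, 0))
        grown = flood_from_path(path, img, cfg, (0, 0, 0))
        assert set(map(tuple, np.argwhere(grown))) == set(path.voxels)

    def test_tolerance_zero_constant_intensity_floods_max_region(self):
        img = np.full((5, 9, 9), 5.0)
        path = Path([(2, 4, 4)], 0.0)
        cfg = ReconnectConfig(tolerance=0.0, min_ellipsoid=(1, 1, 0))
        grown = flood_from_path(path, img, cfg, (3, 3, 1))
        # constant intensity: the flood covers the whole max ellipsoid
        zz, yy, xx = np.nonzero(grown)
        assert grown[2, 4, 4]
        for z, y, x in zip(zz, yy, xx):
            assert ((x - 4) / 3) ** 2 + ((y - 4) / 3) ** 2 + (z - 2) ** 2 <= 1 + 1e-9

    def test_growth_never_exceeds_max_ellipsoid_union(self, rng):
        img = rng.random((7, 11, 11)) * 100
        path = Path([(3, 5, 3), (3, 5, 4), (3, 6, 5)], 0.0)
        cfg = ReconnectConfig(tolerance=0.9, min_ellipsoid=(1, 1, 0))
        grown = flood_from_path(path, img, cfg, (2, 2, 1))
        allowed = np.zeros_like(grown)
        for (pz, py, px) in path.voxels:
            for z in range(7):
                for y in range(11):
                    for x in range(11):
                        if ((x - px) / 2) ** 2 + ((y - py) / 2) ** 2 + (z - pz) ** 2 <= 1 + 1e-9:
                            allowed[z, y, x] = True
        assert not (grown & ~allowed).any()

    def test_monotone_in_tolerance(self, rng):
        img = rng.random((7, 9, 9)) * 100
        path = Path([(3, 4, 2), (3, 4, 3), (3, 4, 4)], 0.0)
        prev = None
        for tol in (0.0, 0.2, 0.5, 0.8):
            cfg = ReconnectConfig(tolerance=tol)
            grown = flood_from_path(path, img, cfg, (4, 4, 2))
            if prev is not None:
                assert (prev & ~grown).sum() == 0  # growing tolerance never shrinks
            prev = grown


class TestReconnectStructure:
    def _volume_with_blobs(self):
        lab = np.zeros((3, 9, 21), dtype=np.uint8)
        img = np.full((3, 9, 21), 100.0)
        for x0 in (1, 9, 17):
            lab[1, 3:6, x0:x0 + 3] = SPINE
        img[1, 4, :] = 20000.0  # bright corridor through all three blobs
        return LabelVolume(lab), IntensityVolume(img)

    def test_connected_structure_unchanged(self):
        lab = np.zeros((3, 5, 5), dtype=np.uint8)
        lab[1, 1:4, 1:4] = SHAFT
        labels = LabelVolume(lab)
        intensity = IntensityVolume(np.zeros_like(lab, dtype=float))
        out, report = reconnect_structure(
            labels, intensity, lab == SHAFT, SHAFT, ReconnectConfig()
        )
        assert np.array_equal(out.labels, lab)
        assert report.components_after == 1 and not report.paths

    def test_three_blobs_become_one_component(self):
        labels, intensity = self._volume_with_blobs()
        cfg = ReconnectConfig(max_ellipsoid_spine=(2, 2, 1))
        out, report = reconnect_structure(
            labels, intensity, labels.labels == SPINE, SPINE, cfg
        )
        assert len(find_components(out, SPINE, 26)) == 1
        assert report.components_before == 3
        # no voxels deleted
        assert np.all(out.labels[labels.labels == SPINE] == SPINE)

    def test_never_deletes_voxels(self, broken_phantom_pair):
        img, lab, _ = broken_phantom_pair
        out, _ = preprocess_ground_truth(lab, img)
        assert np.all(out.labels[lab.labels > 0] == lab.labels[lab.labels > 0])


class TestPreprocessGroundTruth:
    def test_identity_on_connected_ground_truth(self, phantom_pair):
        img, lab, _ = phantom_pair
        out, reports = preprocess_ground_truth(lab, img)
        assert np.array_equal(out.labels, lab.labels)
        # shaft stays a single component
        assert len(find_components(out, SHAFT, 26)) == 1

    def test_idempotent(self, broken_phantom_pair):
        img, lab, _ = broken_phantom_pair
        once, _ = preprocess_ground_truth(lab, img)
        twice, _ = preprocess_ground_truth(once, img)
        assert np.array_equal(once.labels, twice.labels)

    def test_detached_shaft_and_spines_reattached(self):
        """Three-part scenario: split shaft plus a detached spine head."""
        lab = np.zeros((5, 11, 31), dtype=np.uint8)
        img = np.full((5, 11, 31), 50.0)
        lab[2, 4:7, 2:12] = SHAFT
        lab[2, 4:7, 19:29] = SHAFT  # gap in the shaft
        img[2, 5, :] = 10000.0
        lab[2, 8:10, 14:17] = SPINE  # head floating above the gap
        img[2, 6:10, 15] = 10000.0  # its neck is visible in the image
        labels = LabelVolume(lab)
        intensity = IntensityVolume(img)
        out, _ = preprocess_ground_truth(labels, intensity)
        assert len(find_components(out, SHAFT, 26)) == 1
        from spineflow.reconnect import _adjacent

        for comp in find_components(out, SPINE, 26):
            m = np.zeros(out.labels.shape, bool)
            m[comp.voxels[:, 0], comp.voxels[:, 1], comp.voxels[:, 2]] = True
            assert _adjacent(m, out.labels == SHAFT, 26)
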