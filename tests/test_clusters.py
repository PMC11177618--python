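from collections import deque

import numpy as np
import pytest

from connmap.clusters import (
    ClusterRecord,
    PermDistribution,
    apply_threshold,
    cluster_stats,
    clusters_to_table,
    label_clusters,
    permutation_cluster_threshold,
    size_threshold,
    table_to_frame,
)
from connmap.volumes import VolumeGeometry

from conftest import box_mask


def flood_fill_components(sel: np.ndarray, adjacency: int = 6):
    """Brute-force BFS connected components of a boolean volume."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if adjacency == 6 and order > 1:
                    continue
                if adjacency == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    remaining = {tuple(v) for v in np.argwhere(sel)}
    comps = []
    while remaining:
        start = remaining.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.fixture()
def geom8():
    return VolumeGeometry.isotropic((8, 8, 8), 2.0, world_convention="right_positive_x")


class TestLabelClusters:
    def test_all_zero_map_yields_nothing(self, geom8):
        mask = box_mask(geom8, 0, 8, 0, 8, 0, 8)
        assert label_clusters(np.zeros((8, 8, 8)), mask, 1.96) == []

    def test_single_positive_block(self, geom8):
        mask = box_mask(geom8, 0, 8, 0, 8, 0, 8)
        z = np.zeros((8, 8, 8))
        z[2:5, 2:5, 2:5] = 3.0
        records = label_clusters(z, mask, 1.96)
        assert len(records) == 1
        assert records[0].sign == 1
        assert records[0].size == 27
        assert records[0].peak_z == pytest.approx(3.0)

    @pytest.mark.parametrize("adjacency", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, geom8, rng, adjacency):
        mask = box_mask(geom8, 0, 8, 0, 8, 0, 8)
        z = rng.standard_normal((8, 8, 8)) * 2.0
        records = label_clusters(z, mask, 1.96, adjacency=adjacency)
        pos = flood_fill_components((z > 1.96), adjacency)
        neg = flood_fill_components((z < -1.96), adjacency)
        got_pos = {r.voxels for r in records if r.sign > 0}
        got_neg = {r.voxels for r in records if r.sign < 0}
        assert got_pos == pos
        assert got_neg == neg

    def test_partition_covers_every_suprathreshold_voxel_once(self, geom8, rng):
        mask = box_mask(geom8, 1, 7, 1, 7, 1, 7)
        z = rng.standard_normal((8, 8, 8)) * 2.5
        records = label_clusters(z, mask, 1.96)
        seen = {}
        for r in records:
            for v in r.voxels:
                assert v not in seen
                seen[v] = r.sign
        expected = {
            tuple(v)
            for v in np.argwhere((np.abs(z) > 1.96) & mask.indicator)
        }
        assert set(seen) == expected

    def test_restricted_to_mask(self, geom8):
        mask = box_mask(geom8, 0, 4, 0, 8, 0, 8)
        z = np.full((8, 8, 8), 3.0)
        (rec,) = label_clusters(z, mask, 1.96)
        assert rec.size == 4 * 8 * 8


class TestClusterStats:
    def test_volume_is_count_times_voxel_volume(self, geom8):
        cluster = ClusterRecord(voxels=frozenset((i, j, 1) for i in range(8) for j in range(6)), sign=1)
        done = cluster_stats(cluster, geom8)
        assert done.volume_mm3 == pytest.approx(done.size * 8.0)

    def test_44_voxels_at_2mm_gives_352_mm3(self, geom8):
        vox = [(i, j, 1) for i in range(8) for j in range(8)][:44]
        done = cluster_stats(ClusterRecord(voxels=frozenset(vox), sign=-1), geom8)
        assert done.volume_mm3 == pytest.approx(352.0)

    def test_single_voxel_center(self, geom8):
        done = cluster_stats(ClusterRecord(voxels=frozenset({(3, 1, 2)}), sign=1), geom8)
        assert done.center_world == pytest.approx((6.0, 2.0, 4.0))

    def test_symmetric_block_center_is_central_voxel(self, geom8):
        vox = [(i, j, k) for i in range(2, 5) for j in range(2, 5) for k in range(2, 5)]
        done = cluster_stats(ClusterRecord(voxels=frozenset(vox), sign=1), geom8)
        from connmap.volumes import world_coords

        assert done.center_world == pytest.approx(world_coords((3, 3, 3), geom8))

    def test_empty_cluster_rejected(self, geom8):
        with pytest.raises(ValueError):
            cluster_stats(ClusterRecord(voxels=frozenset(), sign=1), geom8)


class TestSizeThreshold:
    def test_all_zero_null_gives_threshold_one(self):
        dist = PermDistribution(max_cluster_sizes=[0] * 100, n_perm=100, alpha=0.05)
        assert dist.threshold_voxels == 1

    def test_strict_exceedance_definition(self):
        # 100 sizes: five 30s, rest 0 -> exceedance(30) = 0.05, not < 0.05
        sizes = [30] * 5 + [0] * 95
        assert size_threshold(sizes, 100, 0.05) == 31

    def test_monotone_in_alpha(self, rng):
        sizes = rng.integers(0, 50, size=100)
        t_strict = size_threshold(sizes, 100, 0.01)
        t_loose = size_threshold(sizes, 100, 0.10)
        assert t_strict >= t_loose


class TestPermutationThreshold:
    def test_identical_conditions_give_zero_null(self, geom8, rng):
        mask = box_mask(geom8, 0, 8, 0, 8, 0, 8)
        maps = rng.standard_normal((6, 8, 8, 8))
        dist = permutation_cluster_threshold(maps, maps.copy(), mask, 1.96, n_perm=20, seed=0)
        assert dist.max_cluster_sizes == [0] * 20
        assert dist.threshold_voxels == 1

    def test_deterministic_given_seed(self, geom8, rng):
        mask = box_mask(geom8, 0, 8, 0, 8, 0, 8)
        a = rng.standard_normal((6, 8, 8, 8))
        b = rng.standard_normal((6, 8, 8, 8))
        d1 = permutation_cluster_threshold(a, b, mask, 1.96, n_perm=30, seed=7)
        d2 = permutation_cluster_threshold(a, b, mask, 1.96, n_perm=30, seed=7)
        assert d1.max_cluster_sizes == d2.max_cluster_sizes

    def test_stricter_voxel_threshold_shrinks_clusters(self, geom8, rng):
        mask = box_mask(geom8, 0, 8, 0, 8, 0, 8)
        a = rng.standard_normal((8, 8, 8, 8))
        b = rng.standard_normal((8, 8, 8, 8))
        lenient = permutation_cluster_threshold(a, b, mask, 1.0, n_perm=40, seed=3)
        strict = permutation_cluster_threshold(a, b, mask, 3.0, n_perm=40, seed=3)
        assert lenient.threshold_voxels >= strict.threshold_voxels


class TestApplyThreshold:
    def _records(self, sizes):
        return [
            ClusterRecord(voxels=frozenset((i, 0, n) for i in range(s)), sign=1)
            for n, s in enumerate(sizes)
        ]

    def test_keeps_clusters_at_or_above_threshold(self):
        kept = apply_threshold(self._records([5, 20, 44]), 20)
        assert sorted(c.size for c in kept) == [20, 44]

    def test_floor_dominates_small_permutation_threshold(self):
        # permutation alone would admit 7- and 15-voxel clusters; the
        # imposed 20-voxel floor rejects both
        kept = apply_threshold(self._records([7, 15]), 7, floor_voxels=20)
        assert kept == []

    def test_empty_input(self):
        assert apply_threshold([], 5) == []


class TestClusterTable:
    def test_empty_list_gives_header_only(self):
        text = clusters_to_table([])
        assert text.splitlines()[0].startswith("id\trole")
        assert len(text.strip().splitlines()) == 1

    def test_drivers_follow_parent_hotspot(self, geom8):
        hot = cluster_stats(
            ClusterRecord(voxels=frozenset({(1, 1, 1), (1, 1, 2)}), sign=1, role="hotspot", cluster_id=1),
            geom8,
        )
        d1 = cluster_stats(
            ClusterRecord(voxels=frozenset({(5, 5, 5)}), sign=-1, role="driver", cluster_id=1, parent_hotspot_id=1),
            geom8,
        )
        d2 = cluster_stats(
            ClusterRecord(voxels=frozenset({(6, 6, 6)}), sign=1, role="driver", cluster_id=2, parent_hotspot_id=1),
            geom8,
        )
        frame = table_to_frame(clusters_to_table([hot, d1, d2]))
        assert len(frame) == 3
        assert list(frame["role"]) == ["hotspot", "driver", "driver"]
        assert list(frame["parent_id"].iloc[1:]) == [1, 1]

    def test_numeric_round_trip_is_exact(self, geom8, rng):
        recs = []
        for n in range(3):
            vox = frozenset((int(i), int(j), int(k)) for i, j, k in rng.integers(0, 8, size=(4, 3)))
            rec = ClusterRecord(voxels=vox, sign=1 if n % 2 == 0 else -1, peak_z=float(rng.normal()), role="hotspot", cluster_id=n + 1)
            recs.append(cluster_stats(rec, geom8))
        text = clusters_to_table(recs)
        frame = table_to_frame(text)
        for row, rec in zip(frame.itertuples(), recs):
            assert row.n_voxels == rec.size
            assert row.volume_mm3 == pytest.approx(rec.volume_mm3)
            assert row.x == pytest.approx(round(rec.center_world[0], 3))
            assert row.peak_z == pytest.approx(round(rec.peak_z, 1))
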