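"""Step 2: seed-based "driver" detection for each hotspot.

The spatially averaged series of a hotspot seeds a network-constrained
correlation map per subject per condition; the paired contrast of those maps
(standardized z threshold 3.291, i.e. two-tailed p < 0.001) yields clusters
whose connectivity with the hotspot changed — its drivers. Cluster size is
calibrated per hotspot by the same sign-flip permutation, but a conservative
20-voxel floor is imposed on top of the permutation threshold.

The hotspot's own voxels are excluded from driver candidacy by default
(the seed trivially correlates with itself).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from connmap.clusters import (
    ClusterRecord,
    PermDistribution,
    apply_threshold,
    cluster_stats,
    label_clusters,
    permutation_cluster_threshold,
)
from connmap.stats import GroupContrastMap, fisher_z, paired_contrast_map
from connmap.volumes import BoldRun, NetworkMask


def hotspot_seed_series(run: BoldRun, hotspot: ClusterRecord) -> np.ndarray:
    """Unweighted per-frame mean over the hotspot's member voxels."""
    if hotspot.size == 0:
        raise ValueError("empty hotspot")
    ii, jj, kk = hotspot.index_arrays()
    shape = run.geometry.shape
    if ii.max() >= shape[0] or jj.max() >= shape[1] or kk.max() >= shape[2]:
        raise ValueError("hotspot voxels outside run geometry")
    return run.data[ii, jj, kk, :].mean(axis=0)


def seed_correlation_map(run: BoldRun, seed_series: np.ndarray, network: NetworkMask) -> np.ndarray:
    """Fisher-z correlation of a seed series with every network voxel (3D, NaN off-mask)."""
    seed = np.asarray(seed_series, dtype=float)
    if seed.shape != (run.n_frames,):
        raise ValueError("seed series must have one value per frame")
    valid = run.valid_frames
    if valid.sum() < 3:
        raise ValueError("need at least 3 non-censored frames")
    s = seed[valid]
    sc = s - s.mean()
    sn = np.linalg.norm(sc)
    if sn == 0:
        raise ValueError("constant seed series")
    X = run.data[network.indicator][:, valid].T.astype(float)
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    r = np.full(network.n_voxels, np.nan)
    ok = norms > 0
    r[ok] = (X[:, ok].T @ sc) / (norms[ok] * sn)
    out = np.full(run.geometry.shape, np.nan)
    out[network.indicator] = fisher_z(np.clip(r, -1.0, 1.0))
    return out


@dataclass
class DriverResult:
    """Driver clusters of one hotspot, with their permutation calibration."""

    clusters: list[ClusterRecord]
    hotspot: ClusterRecord
    contrast: tuple[str, str]
    contrast_map: GroupContrastMap
    perm: PermDistribution

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)


def find_drivers(
    hotspot: ClusterRecord,
    runs_a,
    runs_b,
    network: NetworkMask,
    voxel_z: float = 3.291,
    n_perm: int = 100,
    alpha: float = 0.05,
    floor_voxels: int = 20,
    adjacency: int = 6,
    seed: int = 0,
    allow_self_drivers: bool = False,
) -> DriverResult:
    """Detect clusters whose seed connectivity with ``hotspot`` changed.

    Refuses datasets from a different contrast than the one the hotspot was
    derived from (structural guard against circular analysis).
    """
    if len(runs_a) != len(runs_b) or len(runs_a) < 2:
        raise ValueError("need the same >= 2 subjects in both conditions")
    contrast = (runs_a[0].condition, runs_b[0].condition)
    if hotspot.contrast is not None and tuple(hotspot.contrast) != contrast:
        raise ValueError(
            f"hotspot belongs to contrast {hotspot.contrast}, got runs for {contrast}"
        )
    candidate = network
    if not allow_self_drivers:
        hot_mask = NetworkMask.from_voxels(network.geometry, hotspot.voxels, name="hotspot")
        candidate = network.minus(hot_mask, name=f"{network.name}_minus_hotspot")
    maps_a = np.stack(
        [seed_correlation_map(r, hotspot_seed_series(r, hotspot), candidate) for r in runs_a]
    )
    maps_b = np.stack(
        [seed_correlation_map(r, hotspot_seed_series(r, hotspot), candidate) for r in runs_b]
    )
    gmap = paired_contrast_map(maps_a, maps_b, mask=candidate, contrast=contrast)
    perm = permutation_cluster_threshold(
        maps_a,
        maps_b,
        candidate,
        voxel_z_threshold=voxel_z,
        n_perm=n_perm,
        alpha=alpha,
        adjacency=adjacency,
        seed=seed,
    )
    raw = label_clusters(gmap.z_map, candidate, voxel_z, adjacency=adjacency)
    kept = apply_threshold(raw, perm.threshold_voxels, floor_voxels)
    kept.sort(key=lambda c: -abs(c.peak_z))
    clusters = [
        replace(
            cluster_stats(c, network.geometry),
            role="driver",
            cluster_id=i + 1,
            parent_hotspot_id=hotspot.cluster_id,
            contrast=contrast,
        )
        for i, c in enumerate(kept)
    ]
    return DriverResult(
        clusters=clusters, hotspot=hotspot, contrast=contrast, contrast_map=gmap, perm=perm
    )
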