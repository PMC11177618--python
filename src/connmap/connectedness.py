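"""Step 1: per-run network connectedness maps and hotspot detection.

A voxel's connectedness is its mean Pearson correlation with every *other*
voxel of the network mask, Fisher-z transformed after averaging. The map is
computed in a block matrix form — standardize the in-mask series to unit
columns and use one matrix-vector product per run — so networks of ~15,000
voxels cost O(T V) rather than O(T V^2).

Hotspots are clusters where connectedness differs between two conditions:
paired t per voxel, standardized z threshold 1.96, cluster size calibrated
by the sign-flip permutation null.
"""

from __future__ import annotations

import warnings
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
from connmap.volumes import BoldRun, NetworkMask, VolumeGeometry


@dataclass
class ConnectednessMap:
    """Per-subject, per-condition 3D connectedness map (NaN off-mask)."""

    geometry: VolumeGeometry
    values: np.ndarray
    subject_id: str = ""
    condition: str = ""
    network_name: str = ""

    def on_mask(self, mask: NetworkMask) -> np.ndarray:
        return self.values[mask.indicator]


def _standardized_columns(run: BoldRun, mask: NetworkMask):
    """(T_valid x V) matrix of demeaned unit-norm in-mask series.

    Constant (undefined-correlation) voxels get zero columns; the boolean
    ``ok`` flags the well-defined ones.
    """
    valid = run.valid_frames
    if valid.sum() < 3:
        raise ValueError("need at least 3 non-censored frames")
    X = run.data[mask.indicator][:, valid].T.astype(float)  # (T, V)
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    ok = norms > 1e-12 * max(1.0, float(np.abs(run.data).max()))
    Z = np.zeros_like(X)
    Z[:, ok] = X[:, ok] / norms[ok]
    return Z, ok


def connectedness_map(
    run: BoldRun,
    network: NetworkMask,
    include_self: bool = False,
    z_before_average: bool = False,
) -> ConnectednessMap:
    """Fisher-z mean correlation of each network voxel with all others.

    Self-correlation is excluded by default ("every other voxel"); pass
    ``include_self=True`` to reproduce the inclusive mean some toolchains
    use. ``z_before_average`` averages arctanh(r) instead of r (sensitivity
    variant; requires the dense correlation matrix, so reserve it for small
    networks). Censored frames are dropped; constant voxel series are
    excluded from the pair means with a warning and left NaN themselves.
    """
    if not run.geometry.compatible(network.geometry):
        raise ValueError("run and network geometries differ")
    V = network.n_voxels
    if V < 2:
        raise ValueError("network must have at least 2 voxels")
    Z, ok = _standardized_columns(run, network)
    n_ok = int(ok.sum())
    if n_ok < V:
        warnings.warn(
            f"{V - n_ok} constant voxel series excluded from connectedness means",
            stacklevel=2,
        )
    mean_r = np.full(V, np.nan)
    if n_ok >= 2:
        if z_before_average:
            R = Z.T @ Z  # (V, V); zero rows/cols for bad voxels
            np.clip(R, -1.0 + 1e-7, 1.0 - 1e-7, out=R)
            ZR = np.arctanh(R)
            rows = ZR[np.ix_(ok, ok)]
            if include_self:
                mean_r[ok] = np.tanh(rows.mean(axis=1))
            else:
                np.fill_diagonal(rows, 0.0)
                mean_r[ok] = np.tanh(rows.sum(axis=1) / (n_ok - 1))
        else:
            s = Z.sum(axis=1)
            rowsum = Z.T @ s  # includes the self term (=1) for ok voxels
            if include_self:
                mean_r[ok] = rowsum[ok] / n_ok
            else:
                mean_r[ok] = (rowsum[ok] - 1.0) / (n_ok - 1)
    values = np.full(run.geometry.shape, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # |mean r| = 1 clip handled upstream
        values[network.indicator] = fisher_z(mean_r)
    return ConnectednessMap(
        geometry=run.geometry,
        values=values,
        subject_id=run.subject_id,
        condition=run.condition,
        network_name=network.name,
    )


@dataclass
class HotspotResult:
    """Hotspot clusters for one contrast, with the calibration that made them."""

    clusters: list[ClusterRecord]
    contrast: tuple[str, str]
    contrast_map: GroupContrastMap
    perm: PermDistribution
    network_name: str = ""

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)


def _stack_maps(runs, network: NetworkMask, include_self: bool) -> np.ndarray:
    return np.stack(
        [connectedness_map(r, network, include_self=include_self).values for r in runs]
    )


def find_hotspots(
    runs_a,
    runs_b,
    network: NetworkMask,
    voxel_z: float = 1.96,
    n_perm: int = 100,
    alpha: float = 0.05,
    adjacency: int = 6,
    seed: int = 0,
    include_self: bool = False,
    floor_voxels: int = 0,
) -> HotspotResult:
    """Detect connectedness-change hotspots between paired condition runs.

    Positive sign means condition a > condition b. The cluster-size threshold
    comes from a fresh sign-flip permutation null on the same maps.
    """
    if len(runs_a) != len(runs_b) or len(runs_a) < 2:
        raise ValueError("need the same >= 2 subjects in both conditions")
    for ra, rb in zip(runs_a, runs_b):
        if ra.subject_id != rb.subject_id:
            raise ValueError("runs must be subject-aligned across conditions")
    contrast = (runs_a[0].condition, runs_b[0].condition)
    maps_a = _stack_maps(runs_a, network, include_self)
    maps_b = _stack_maps(runs_b, network, include_self)
    gmap = paired_contrast_map(maps_a, maps_b, mask=network, contrast=contrast)
    perm = permutation_cluster_threshold(
        maps_a,
        maps_b,
        network,
        voxel_z_threshold=voxel_z,
        n_perm=n_perm,
        alpha=alpha,
        adjacency=adjacency,
        seed=seed,
    )
    raw = label_clusters(gmap.z_map, network, voxel_z, adjacency=adjacency)
    kept = apply_threshold(raw, perm.threshold_voxels, floor_voxels)
    kept.sort(key=lambda c: -abs(c.peak_z))
    clusters = [
        replace(
            cluster_stats(c, network.geometry),
            role="hotspot",
            cluster_id=i + 1,
            contrast=contrast,
        )
        for i, c in enumerate(kept)
    ]
    return HotspotResult(
        clusters=clusters,
        contrast=contrast,
        contrast_map=gmap,
        perm=perm,
        network_name=network.name,
    )
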