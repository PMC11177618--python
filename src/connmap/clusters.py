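"""Connected-component clustering and permutation cluster-size calibration.

Suprathreshold (z > +thr) and subthreshold (z < -thr) voxels are clustered
separately, restricted to the analysis mask. The family-wise cluster-size
threshold is calibrated with a sign-flip Monte-Carlo permutation: each
permutation swaps the two conditions for a uniformly random half of the
subjects, re-runs the paired contrast, and records the maximum cluster size
over both signs jointly; the threshold is the smallest size whose exceedance
proportion in the null distribution falls strictly below alpha.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from connmap.stats import paired_t, t_to_z
from connmap.volumes import NetworkMask, VolumeGeometry, world_coords

#: scipy binary structures for 6/18/26-neighbour adjacency in 3D.
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def adjacency_structure(adjacency: int) -> np.ndarray:
    try:
        return _STRUCTURES[int(adjacency)]
    except KeyError:
        raise ValueError(f"adjacency must be one of {sorted(_STRUCTURES)}") from None


@dataclass
class ClusterRecord:
    """One hotspot or driver cluster with its reporting statistics."""

    voxels: frozenset[tuple[int, int, int]]
    sign: int  # +1 or -1
    peak_z: float = float("nan")
    center_world: tuple[float, float, float] | None = None
    volume_mm3: float = float("nan")
    role: str = "cluster"  # {"hotspot", "driver", "cluster"}
    cluster_id: int | None = None
    parent_hotspot_id: int | None = None
    contrast: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.voxels = frozenset(tuple(int(v) for v in ijk) for ijk in self.voxels)
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    @property
    def size(self) -> int:
        return len(self.voxels)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = np.array(sorted(self.voxels), dtype=int)
        return idx[:, 0], idx[:, 1], idx[:, 2]


@dataclass
class PermDistribution:
    """Null distribution of maximum cluster sizes from sign-flip permutations."""

    max_cluster_sizes: list[int]
    n_perm: int
    alpha: float
    threshold_voxels: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.max_cluster_sizes) != self.n_perm:
            raise ValueError("one max size per permutation required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        self.max_cluster_sizes = [int(s) for s in self.max_cluster_sizes]
        self.threshold_voxels = size_threshold(self.max_cluster_sizes, self.n_perm, self.alpha)


def size_threshold(max_sizes, n_perm: int, alpha: float) -> int:
    """Smallest integer s with ``#(sizes >= s) / n_perm < alpha``.

    Ties are broken conservatively upward: a size whose exceedance equals
    alpha exactly does not qualify.
    """
    sizes = np.asarray(max_sizes, dtype=int)
    for s in range(1, int(sizes.max(initial=0)) + 2):
        if np.count_nonzero(sizes >= s) / n_perm < alpha:
            return s
    raise RuntimeError("unreachable")  # pragma: no cover


def label_clusters(
    z_map: np.ndarray,
    mask: NetworkMask,
    voxel_z_threshold: float,
    adjacency: int = 6,
) -> list[ClusterRecord]:
    """Connected components of supra/subthreshold voxels, per sign, in-mask."""
    structure = adjacency_structure(adjacency)
    z = np.asarray(z_map, dtype=float)
    if z.shape != mask.geometry.shape:
        raise ValueError("z map does not match mask geometry")
    ind = mask.indicator
    records: list[ClusterRecord] = []
    with np.errstate(invalid="ignore"):
        for sign, sel in ((1, (z > voxel_z_threshold)), (-1, (z < -voxel_z_threshold))):
            sel = sel & ind
            labels, n = ndimage.label(sel, structure=structure)
            for comp in range(1, n + 1):
                where = np.argwhere(labels == comp)
                vox = frozenset(tuple(int(v) for v in ijk) for ijk in where)
                zs = z[labels == comp]
                peak = float(zs[np.argmax(np.abs(zs))])
                records.append(ClusterRecord(voxels=vox, sign=sign, peak_z=peak))
    return records


def cluster_stats(cluster: ClusterRecord, geometry: VolumeGeometry) -> ClusterRecord:
    """Complete a cluster record: world center of mass and volume in mm^3.

    The center is the unweighted mean of member voxel-center world
    coordinates; volume is exactly voxel count x voxel volume.
    """
    if cluster.size == 0:
        raise ValueError("empty cluster")
    coords = np.array([world_coords(ijk, geometry) for ijk in sorted(cluster.voxels)])
    center = tuple(float(c) for c in coords.mean(axis=0))
    volume = cluster.size * geometry.voxel_volume_mm3
    return replace(cluster, center_world=center, volume_mm3=volume)


def _max_cluster_size(z: np.ndarray, ind: np.ndarray, thr: float, structure) -> int:
    """Maximum component size over both signs jointly (one null statistic)."""
    best = 0
    with np.errstate(invalid="ignore"):
        for sel in ((z > thr) & ind, (z < -thr) & ind):
            labels, n = ndimage.label(sel, structure=structure)
            if n:
                best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def permutation_cluster_threshold(
    maps_a,
    maps_b,
    mask: NetworkMask,
    voxel_z_threshold: float,
    n_perm: int = 100,
    alpha: float = 0.05,
    adjacency: int = 6,
    seed: int | np.random.Generator = 0,
) -> PermDistribution:
    """Sign-flip permutation null of maximum cluster sizes.

    Each permutation swaps (a, b) for exactly ``floor(n/2)`` uniformly chosen
    subjects (fresh draw per permutation, duplicates across permutations
    allowed), recomputes the paired t -> z map, and records the largest
    cluster over both signs. Deterministic given ``seed``.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("subject map stacks must align")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    structure = adjacency_structure(adjacency)
    ind = mask.indicator
    d = a - b
    d = np.where(np.isnan(d), 0.0, d)  # off-mask voxels never cluster
    n_flip = n // 2
    max_sizes = []
    for _ in range(n_perm):
        signs = np.ones(n)
        flip = rng.choice(n, size=n_flip, replace=False)
        signs[flip] = -1.0
        dp = d * signs[:, None, None, None]
        t, df = paired_t(dp, np.zeros_like(dp), axis=0)
        z = t_to_z(t, df)
        max_sizes.append(_max_cluster_size(z, ind, voxel_z_threshold, structure))
    return PermDistribution(max_cluster_sizes=max_sizes, n_perm=n_perm, alpha=alpha)


def apply_threshold(
    clusters: list[ClusterRecord], threshold_voxels: int, floor_voxels: int = 0
) -> list[ClusterRecord]:
    """Keep clusters of at least ``max(threshold_voxels, floor_voxels)`` voxels."""
    if threshold_voxels < 1:
        raise ValueError("threshold_voxels must be >= 1")
    cut = max(threshold_voxels, floor_voxels)
    return [c for c in clusters if c.size >= cut]


# ---------------------------------------------------------------------------
# Reporting

TABLE_COLUMNS = [
    "id",
    "role",
    "parent_id",
    "sign",
    "x",
    "y",
    "z",
    "n_voxels",
    "volume_mm3",
    "peak_z",
]


def clusters_to_table(records: list[ClusterRecord]) -> str:
    """TSV cluster table: hotspots followed by their drivers (parent ordering).

    Columns mirror the reporting convention of the field's cluster tables
    (center mm coordinates, volume in mm^3, peak standardized z at one
    decimal).
    """
    hotspots = [r for r in records if r.role != "driver"]
    drivers = [r for r in records if r.role == "driver"]
    ordered: list[ClusterRecord] = []
    for h in sorted(hotspots, key=lambda r: (r.cluster_id is None, r.cluster_id)):
        ordered.append(h)
        ordered.extend(
            d
            for d in drivers
            if d.parent_hotspot_id is not None and d.parent_hotspot_id == h.cluster_id
        )
    orphans = [d for d in drivers if d not in ordered]
    ordered.extend(orphans)

    rows = []
    for r in ordered:
        cx, cy, cz = r.center_world if r.center_world is not None else (np.nan,) * 3
        rows.append(
            {
                "id": r.cluster_id if r.cluster_id is not None else "",
                "role": r.role,
                "parent_id": r.parent_hotspot_id if r.parent_hotspot_id is not None else "",
                "sign": "+" if r.sign > 0 else "-",
                "x": round(float(cx), 3),
                "y": round(float(cy), 3),
                "z": round(float(cz), 3),
                "n_voxels": r.size,
                "volume_mm3": round(float(r.volume_mm3), 3),
                "peak_z": round(float(r.peak_z), 1),
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.to_csv(sep="\t", index=False)


def table_to_frame(text: str) -> pd.DataFrame:
    """Parse a TSV cluster table back into a DataFrame (numeric dtypes)."""
    return pd.read_csv(io.StringIO(text), sep="\t")
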