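"""Group network-mask definition from seed connectivity.

The group masks are built the way seed-defined resting-state networks are:
per subject, correlate the seed-mean series with every brain voxel (Fisher
z); test the stack against zero with a one-sample t; threshold the
standardized z map at a very strict voxel-wise p; keep clusters that clear a
noise-simulation cluster-size threshold; dilate one step; intersect with the
brain mask. Membership uses the positive tail by default — these networks
are positive-connectivity structures — with a flag for two-sided membership.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from connmap.clusters import adjacency_structure, apply_threshold, label_clusters, size_threshold
from connmap.drivers import seed_correlation_map
from connmap.stats import GroupContrastMap, one_sample_t, t_to_z
from connmap.volumes import BoldRun, NetworkMask


def _mean_series(run: BoldRun, seed: NetworkMask) -> np.ndarray:
    return run.data[seed.indicator].mean(axis=0)


def group_seed_map(
    sham_runs,
    seed,
    brain_mask: NetworkMask | None = None,
    name: str = "seed",
) -> GroupContrastMap:
    """One-sample group z map of seed connectivity over the sham runs.

    ``seed`` may be a single mask shared by all subjects or a per-subject
    sequence of masks (individualized seeds).
    """
    runs = list(sham_runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 subjects")
    seeds = list(seed) if isinstance(seed, (list, tuple)) else [seed] * len(runs)
    if len(seeds) != len(runs):
        raise ValueError("one seed per subject (or a single shared seed) required")
    geom = runs[0].geometry
    if brain_mask is None:
        brain_mask = NetworkMask(geom, np.ones(geom.shape, dtype=bool), name="brain")
    maps = np.stack(
        [
            seed_correlation_map(r, _mean_series(r, s), brain_mask)
            for r, s in zip(runs, seeds)
        ]
    )
    t, df = one_sample_t(maps, axis=0)
    z = t_to_z(np.asarray(t, dtype=float), df)
    t = np.where(brain_mask.indicator, t, np.nan)
    z = np.where(brain_mask.indicator, z, np.nan)
    return GroupContrastMap(t_map=t, z_map=z, df=df, contrast=(name, "zero"), mask=brain_mask)


def noise_cluster_alpha(
    mask: NetworkMask,
    smooth_fwhm_mm: float,
    voxel_p: float,
    n_sim: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    adjacency: int = 6,
) -> int:
    """Monte-Carlo noise-field cluster-size threshold.

    Simulates smoothed Gaussian noise on the grid, standardizes it within the
    mask, thresholds two-sided at ``voxel_p``, and records max cluster sizes;
    returns the smallest size with exceedance proportion strictly below
    ``alpha``.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0,1)")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    structure = adjacency_structure(adjacency)
    ind = mask.indicator
    if ind.sum() == 0:
        raise ValueError("degenerate grid: empty mask")
    vs = mask.geometry.voxel_size_mm
    sigma = tuple(
        smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in vs
    )
    zthr = norm.isf(voxel_p / 2.0)
    max_sizes = []
    for _ in range(n_sim):
        field = rng.standard_normal(mask.geometry.shape)
        if smooth_fwhm_mm > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma, mode="constant")
        sd = field[ind].std()
        if sd > 0:
            field = (field - field[ind].mean()) / sd
        sup = (np.abs(field) > zthr) & ind
        labels, n = ndimage.label(sup, structure=structure)
        size = int(np.bincount(labels.ravel())[1:].max()) if n else 0
        max_sizes.append(size)
    return size_threshold(max_sizes, n_sim, alpha)


def define_network(
    group_map: GroupContrastMap,
    voxel_p: float = 1e-8,
    cluster_threshold: int = 1,
    dilate_iters: int = 1,
    adjacency: int = 6,
    two_sided: bool = False,
    brain_mask: NetworkMask | None = None,
    name: str = "network",
) -> NetworkMask:
    """Threshold a group seed map into a network mask, with dilation.

    Raises when no voxel survives — networks must be non-empty for
    connectedness analysis.
    """
    mask = brain_mask if brain_mask is not None else group_map.mask
    if mask is None:
        raise ValueError("a brain mask is required")
    zthr = float(norm.isf(voxel_p))
    records = label_clusters(group_map.z_map, mask, zthr, adjacency=adjacency)
    if not two_sided:
        records = [r for r in records if r.sign > 0]
    records = apply_threshold(records, max(1, int(cluster_threshold)))
    ind = np.zeros(mask.geometry.shape, dtype=bool)
    for rec in records:
        ii, jj, kk = rec.index_arrays()
        ind[ii, jj, kk] = True
    if not ind.any():
        raise ValueError("network definition produced an empty mask")
    if dilate_iters > 0:
        ind = ndimage.binary_dilation(
            ind, structure=adjacency_structure(adjacency), iterations=int(dilate_iters)
        )
    ind &= mask.indicator
    return NetworkMask(mask.geometry, ind, name=name)


def network_overlap(a: NetworkMask, b: NetworkMask) -> int:
    """Number of voxels shared by two network masks (a first-class report quantity)."""
    if not a.geometry.compatible(b.geometry):
        raise ValueError("incompatible geometries")
    return int((a.indicator & b.indicator).sum())
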