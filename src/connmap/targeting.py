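"""Individualized seed selection from a baseline run.

The stimulation target chain: (1) the hippocampal target is the most
interconnected fraction of a bilateral anatomical hippocampus mask — voxels
ranked by within-mask connectedness; (2) the parietal stimulation site is
the single cortical voxel of a parietal search mask whose series correlates
most strongly (Fisher z) with the target's mean series. Both selections are
invariant to per-voxel affine rescaling of the baseline data, since they
rank correlations.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from connmap.connectedness import connectedness_map
from connmap.drivers import seed_correlation_map
from connmap.volumes import BoldRun, NetworkMask

log = logging.getLogger(__name__)


def hippocampal_target(
    baseline: BoldRun, hippo_mask: NetworkMask, top_fraction: float = 0.05
) -> NetworkMask:
    """Top ``top_fraction`` of hippocampus voxels by within-mask connectedness."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if hippo_mask.n_voxels < 2:
        raise ValueError("hippocampus mask must have at least 2 voxels")
    cmap = connectedness_map(baseline, hippo_mask)
    scores = cmap.values[hippo_mask.indicator]
    coords = np.argwhere(hippo_mask.indicator)
    n_keep = max(1, math.ceil(top_fraction * len(scores)))
    order = np.argsort(-np.nan_to_num(scores, nan=-np.inf), kind="stable")
    keep = coords[order[:n_keep]]
    return NetworkMask.from_voxels(
        hippo_mask.geometry, [tuple(v) for v in keep], name="hippocampal_target"
    )


def parietal_site(
    baseline: BoldRun, target: NetworkMask, parietal_mask: NetworkMask
) -> tuple[int, int, int]:
    """Parietal voxel with peak Fisher-z connectivity to the target mean series.

    Ties break to the lowest linear index (logged).
    """
    if target.n_voxels == 0 or parietal_mask.n_voxels == 0:
        raise ValueError("target and parietal masks must be non-empty")
    seed_series = baseline.data[target.indicator].mean(axis=0)
    zmap = seed_correlation_map(baseline, seed_series, parietal_mask)
    scores = np.nan_to_num(zmap, nan=-np.inf)
    scores = np.where(parietal_mask.indicator, scores, -np.inf)
    flat = int(np.argmax(scores))  # argmax takes the first (lowest linear index) on ties
    if np.count_nonzero(scores == scores.ravel()[flat]) > 1:
        log.info("parietal site tie broken to lowest linear index %d", flat)
    return tuple(int(v) for v in np.unravel_index(flat, scores.shape))
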