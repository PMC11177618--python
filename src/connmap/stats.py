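"""Statistical primitives: Pearson r, Fisher z, paired t, and t -> standardized z.

Voxel-wise thresholds throughout the pipeline are applied on the
standardized-z scale (1.96 for two-tailed p < 0.05, 3.291 for p < 0.001),
so the t -> z conversion is the load-bearing primitive here: it composes the
t CDF with the standard-normal quantile tail-symmetrically in log space,
which keeps very large |t| finite instead of overflowing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

#: Sentinel magnitude used for non-finite t inputs (far beyond any attainable z).
Z_SENTINEL = 40.0

#: Clipping bound applied to correlations before arctanh.
_R_CLIP = 1.0 - 1e-7


def pearson_r(x, y, valid=None) -> float:
    """Pearson correlation over valid (non-censored) frames only.

    Returns NaN with a warning when either series is constant on the valid
    frames.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and equal length")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        x = x[valid]
        y = y[valid]
    if x.size < 3:
        raise ValueError("need at least 3 valid frames")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc * xc).sum())
    ny = np.sqrt((yc * yc).sum())
    if nx == 0 or ny == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return float("nan")
    r = float((xc * yc).sum() / (nx * ny))
    return min(1.0, max(-1.0, r))


def fisher_z(r):
    """Variance-stabilizing arctanh transform; |r| >= 1 clipped with a warning."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    out_of_range = np.abs(r) >= 1.0
    if np.any(out_of_range[np.isfinite(r)] if r.ndim else (out_of_range and np.isfinite(r))):
        warnings.warn("|r| >= 1 clipped before Fisher z", stacklevel=2)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    z = np.where(np.isnan(r), np.nan, z)
    return float(z) if scalar else z


def paired_t(values_a, values_b, axis: int = 0):
    """Paired t statistic over aligned per-subject values.

    ``d_i = a_i - b_i``; ``t = mean(d) / (sd(d)/sqrt(n))`` with the n-1
    variance denominator; ``df = n - 1``. Degenerate cases: zero spread with a
    non-zero mean gives a signed infinity sentinel, all-zero differences give
    t = 0. Works element-wise on stacked maps (subjects along ``axis``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shapes")
    n = a.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    mean = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    if np.any(zero_sd):
        sentinel = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
        t = np.where(zero_sd, sentinel, t)
    if t.ndim == 0:
        t = float(t)
    return t, n - 1


def t_to_z(t, df: int):
    """Map a t statistic to the standard-normal (standardized z) scale.

    ``z = Phi^{-1}(F_t(t; df))`` evaluated through the smaller tail in log
    space so that large |t| stays finite and monotone. Non-finite t propagates
    its sign as a +/-40 sentinel.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    z = np.full(tt.shape, np.nan)
    finite = np.isfinite(tt)
    at = np.abs(tt[finite])
    # tail probability of |t| in log space -> normal upper-tail quantile
    log_sf = sps.t.logsf(at, df)
    z[finite] = -special.ndtri_exp(log_sf) * np.sign(tt[finite])
    z[finite] = np.clip(z[finite], -Z_SENTINEL, Z_SENTINEL)
    inf = np.isinf(tt)
    z[inf] = np.sign(tt[inf]) * Z_SENTINEL
    return float(z[0]) if scalar else z.reshape(t.shape)


@dataclass
class GroupContrastMap:
    """Voxel-wise group-level paired contrast: t map, standardized z map, df."""

    t_map: np.ndarray
    z_map: np.ndarray
    df: int
    contrast: tuple[str, str]
    mask: "object" = None  # NetworkMask; kept loose to avoid an import cycle

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")


def paired_contrast_map(maps_a, maps_b, mask=None, contrast=("a", "b")) -> GroupContrastMap:
    """Stack per-subject 3D maps and run a voxel-wise paired t -> z contrast.

    Off-mask voxels are NaN in the outputs.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    t, df = paired_t(a, b, axis=0)
    t = np.asarray(t, dtype=float)
    z = t_to_z(t, df)
    if mask is not None:
        ind = mask.indicator
        t = np.where(ind, t, np.nan)
        z = np.where(ind, z, np.nan)
    return GroupContrastMap(t_map=t, z_map=z, df=df, contrast=tuple(contrast), mask=mask)


def one_sample_t(values, axis: int = 0):
    """One-sample t of stacked per-subject maps against zero."""
    v = np.asarray(values, dtype=float)
    n = v.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = v.mean(axis=axis)
    sd = v.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    sentinel = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
    t = np.where(sd == 0, sentinel, t)
    if t.ndim == 0:
        t = float(t)
    return t, n - 1
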