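"""Residualization chain: bandpass, nuisance regression, smoothing, scaling.

Bandpass filtering is realized as frequency-regressor projection — sine and
cosine terms at the out-of-band DFT frequencies enter the same ordinary
least-squares design as the nuisance regressors and a linear trend, and the
voxel series is replaced by the residual of that single fit. This makes
filtering and nuisance removal a single simultaneous linear model rather
than sequential filters, avoiding filter/regression interaction artifacts.

Censored frames are excluded from the fit, zero-filled in the output, and
kept flagged so correlation code downstream can drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from connmap.sim import FWHM_TO_SIGMA
from connmap.volumes import BoldRun


@dataclass
class NuisanceSet:
    """Frame-aligned nuisance regressors (e.g. motion estimates + derivatives)."""

    regressors: np.ndarray  # (n_frames, k)
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a 2D matrix")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("regressors must be finite")
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("one name per regressor column required")

    @classmethod
    def empty(cls, n_frames: int) -> "NuisanceSet":
        return cls(regressors=np.zeros((n_frames, 0)), names=[])

    @classmethod
    def from_text(cls, path, names=None) -> "NuisanceSet":
        """Whitespace-delimited text, one row per frame."""
        mat = np.loadtxt(path, ndmin=2)
        names = list(names) if names else [f"reg{i}" for i in range(mat.shape[1])]
        return cls(regressors=mat, names=names)


def fourier_regressors(n_frames: int, tr_s: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Sine/cosine columns at DFT frequencies OUTSIDE [low_hz, high_hz].

    Projecting these out of a series is a bandpass: the intercept handles
    0 Hz, so only k >= 1 harmonics appear here.
    """
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 <= low < high < Nyquist {nyquist:.4g}"
        )
    t = np.arange(n_frames)
    cols = []
    for k in range(1, n_frames // 2 + 1):
        f = k / (n_frames * tr_s)
        if low_hz <= f <= high_hz:
            continue
        phase = 2.0 * np.pi * k * t / n_frames
        cols.append(np.cos(phase))
        if k < (n_frames + 1) // 2:  # Nyquist bin has no independent sine
            cols.append(np.sin(phase))
    if not cols:
        return np.zeros((n_frames, 0))
    return np.column_stack(cols)


def _ols_residuals(Y: np.ndarray, X: np.ndarray, fit_rows: np.ndarray) -> np.ndarray:
    """Residualize Y (T x V) against X (T x k), fitting on ``fit_rows`` only."""
    Xf = X[fit_rows]
    rank = np.linalg.matrix_rank(Xf) if Xf.shape[1] else 0
    if Xf.shape[1] and rank < Xf.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank}/{Xf.shape[1]}): collinear columns "
            "resolved by a minimum-norm fit",
            stacklevel=3,
        )
    if Xf.shape[1] == 0:
        return Y.copy()
    beta, *_ = np.linalg.lstsq(Xf, Y[fit_rows], rcond=None)
    return Y - X @ beta


def residualize(
    run: BoldRun,
    nuisance: NuisanceSet | None = None,
    band: tuple[float, float] | None = (0.01, 0.1),
    censored=None,
) -> BoldRun:
    """Single simultaneous OLS per voxel: intercept + trend + nuisance + out-of-band Fourier.

    ``censored`` frames (defaulting to the run's existing flags) are excluded
    from the fit and zero-filled in the output.
    """
    T = run.n_frames
    if nuisance is None:
        nuisance = NuisanceSet.empty(T)
    if nuisance.regressors.shape[0] != T:
        raise ValueError("nuisance rows must align with frames")
    censored_set = run.censored_frames if censored is None else frozenset(int(f) for f in censored)
    cols = [np.ones(T), np.arange(T, dtype=float)]
    if nuisance.regressors.shape[1]:
        cols.append(nuisance.regressors)
    if band is not None:
        cols.append(fourier_regressors(T, run.tr_s, band[0], band[1]))
        if band[0] > 0 and T * run.tr_s < 2.0 / band[0]:
            warnings.warn("run shorter than two periods of the low band edge", stacklevel=2)
    X = np.column_stack(cols)
    fit_rows = np.ones(T, dtype=bool)
    if censored_set:
        fit_rows[sorted(censored_set)] = False
    Y = run.data.reshape(-1, T).T  # (T, V)
    resid = _ols_residuals(Y, X, fit_rows)
    resid[~fit_rows] = 0.0
    out = resid.T.reshape(run.data.shape)
    return replace(run, data=out, censored_frames=censored_set)


def bandpass(run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldRun:
    """Bandpass by out-of-band Fourier projection (no nuisance columns)."""
    return residualize(run, nuisance=None, band=(low_hz, high_hz))


def smooth(volume_series: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-frame 3D Gaussian smoothing with zero-padded edges.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` converted to voxels per axis;
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    data = np.asarray(volume_series, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in vs)
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma, mode="constant")
    if data.ndim == 4:
        return ndimage.gaussian_filter(data, sigma=sigma + (0.0,), mode="constant")
    raise ValueError("expected a 3D volume or 4D series")


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    return replace(run, data=smooth(run.data, fwhm_mm, run.geometry.voxel_size_mm))


def normalize_intensity(run: BoldRun, target_mean: float = 100.0) -> BoldRun:
    """Scale every voxel series to mean ``target_mean`` over non-censored frames.

    Voxels with (near-)zero mean — e.g. all-zero voxels outside the head —
    are left untouched.
    """
    valid = run.valid_frames
    data = run.data
    m = data[..., valid].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(np.abs(m) > 1e-8, target_mean / m, 1.0)
    return replace(run, data=data * scale[..., None])


def read_censor_column(path) -> frozenset[int]:
    """0/1 text column, one row per frame; 0 marks a censored frame."""
    col = np.loadtxt(path).astype(int).ravel()
    return frozenset(int(i) for i in np.flatnonzero(col == 0))
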