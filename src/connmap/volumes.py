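"""Volumetric containers and NIfTI I/O.

Owns the voxel-grid / world-coordinate contract used by every other module:
0-based voxel indexing, world coordinates are voxel-center millimetres, and a
configurable handedness convention for the reported x axis (tables in the
stimulation literature often print right-hemisphere structures with negative
x, i.e. a left-positive axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Reported x grows to the subject's left; right-hemisphere voxels get
#: negative x (the convention used by the cluster tables this package emits).
RIGHT_NEGATIVE_X = "right_negative_x"
#: Standard RAS-style reporting: x grows to the subject's right.
RIGHT_POSITIVE_X = "right_positive_x"

_CONVENTIONS = (RIGHT_NEGATIVE_X, RIGHT_POSITIVE_X)


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape, voxel size and voxel-index -> world-mm mapping of a 3D grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    world_convention: str = RIGHT_NEGATIVE_X

    def __post_init__(self) -> None:
        if self.world_convention not in _CONVENTIONS:
            raise ValueError(f"unknown world convention {self.world_convention!r}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"bad grid shape {self.shape}")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        a = self.affine[:3, :3]
        return tuple(float(np.linalg.norm(a[:, j])) for j in range(3))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @classmethod
    def isotropic(
        cls,
        shape: tuple[int, int, int],
        voxel_mm: float = 2.0,
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        world_convention: str = RIGHT_NEGATIVE_X,
    ) -> "VolumeGeometry":
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
        aff[:3, 3] = origin
        return cls(shape=tuple(shape), affine=aff, world_convention=world_convention)

    def compatible(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def world_coords(index, geometry: VolumeGeometry) -> tuple[float, float, float]:
    """World-mm coordinates of a voxel center (or fractional voxel position).

    Under the ``right_negative_x`` convention the x coordinate of a
    right-positive affine is sign-flipped, so right-hemisphere voxels report
    negative x.
    """
    idx = np.asarray(index, dtype=float)
    if idx.shape[-1] != 3:
        raise ValueError("index must have three components")
    ints = np.round(idx)
    if np.array_equal(ints, idx):
        if np.any(idx < 0) or np.any(idx >= np.asarray(geometry.shape)):
            raise IndexError(f"voxel index {tuple(idx.astype(int))} out of bounds")
    xyz = geometry.affine[:3, :3] @ idx + geometry.affine[:3, 3]
    if geometry.world_convention == RIGHT_NEGATIVE_X:
        xyz = xyz.copy()
        xyz[0] = -xyz[0]
    return tuple(float(v) for v in xyz)


@dataclass
class BoldRun:
    """One subject x condition 4D residual BOLD series.

    Censored (motion-excised) frames are carried both as metadata
    (``censored_frames``) and as literal zeros in ``data``; correlation code
    downstream drops them via the flags.
    """

    geometry: VolumeGeometry
    data: np.ndarray  # (x, y, z, t)
    tr_s: float
    censored_frames: frozenset[int] = field(default_factory=frozenset)
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[:3] != self.geometry.shape:
            raise ValueError("data grid does not match geometry")
        self.censored_frames = frozenset(int(f) for f in self.censored_frames)
        if self.censored_frames:
            bad = [f for f in self.censored_frames if not (0 <= f < self.n_frames)]
            if bad:
                raise ValueError(f"censored frames out of range: {bad}")
            idx = sorted(self.censored_frames)
            if np.any(self.data[..., idx] != 0):
                raise ValueError("censored frames must be zero-filled")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def valid_frames(self) -> np.ndarray:
        """Boolean (t,) mask of non-censored frames."""
        ok = np.ones(self.n_frames, dtype=bool)
        if self.censored_frames:
            ok[sorted(self.censored_frames)] = False
        return ok

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


@dataclass
class NetworkMask:
    """Labeled boolean 3D volume (a network, seed, or anatomical region)."""

    geometry: VolumeGeometry
    indicator: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.shape != self.geometry.shape:
            raise ValueError("mask grid does not match geometry")
        if self.n_voxels == 0:
            warnings.warn(f"mask {self.name!r} is empty", stacklevel=3)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def voxels(self) -> set[tuple[int, int, int]]:
        return {tuple(int(v) for v in ijk) for ijk in np.argwhere(self.indicator)}

    @classmethod
    def from_voxels(
        cls, geometry: VolumeGeometry, voxels, name: str = ""
    ) -> "NetworkMask":
        ind = np.zeros(geometry.shape, dtype=bool)
        for ijk in voxels:
            i, j, k = (int(v) for v in ijk)
            if not (0 <= i < geometry.shape[0] and 0 <= j < geometry.shape[1] and 0 <= k < geometry.shape[2]):
                raise IndexError(f"voxel {ijk} outside grid {geometry.shape}")
            ind[i, j, k] = True
        return cls(geometry=geometry, indicator=ind, name=name)

    def intersect(self, other: "NetworkMask", name: str = "") -> "NetworkMask":
        if not self.geometry.compatible(other.geometry):
            raise ValueError("incompatible geometries")
        return NetworkMask(self.geometry, self.indicator & other.indicator, name)

    def minus(self, other: "NetworkMask", name: str = "") -> "NetworkMask":
        if not self.geometry.compatible(other.geometry):
            raise ValueError("incompatible geometries")
        return NetworkMask(self.geometry, self.indicator & ~other.indicator, name)


def mask_from_volume(
    vol: np.ndarray, threshold: float, geometry: VolumeGeometry, name: str = ""
) -> NetworkMask:
    """Mask of voxels with value strictly above ``threshold``."""
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError(f"expected 3D volume, got {vol.ndim}D")
    if vol.shape != geometry.shape:
        raise ValueError("volume does not match geometry")
    return NetworkMask(geometry=geometry, indicator=vol > threshold, name=name)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _geometry_from_img(img, world_convention: str) -> VolumeGeometry:
    return VolumeGeometry(
        shape=tuple(int(s) for s in img.shape[:3]),
        affine=np.asarray(img.affine, dtype=float),
        world_convention=world_convention,
    )


def read_volume(path, world_convention: str = RIGHT_NEGATIVE_X):
    """Read a 3D NIfTI volume; returns ``(data, geometry)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path.name}, got {data.ndim}D")
    return data, _geometry_from_img(img, world_convention)


def read_bold(
    path,
    subject_id: str = "",
    condition: str = "",
    censored_frames=(),
    world_convention: str = RIGHT_NEGATIVE_X,
) -> BoldRun:
    """Read a 4D NIfTI time series as a :class:`BoldRun`.

    TR is taken from the header's temporal zoom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series in {path.name}, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
    return BoldRun(
        geometry=_geometry_from_img(img, world_convention),
        data=data,
        tr_s=tr_s,
        censored_frames=frozenset(censored_frames),
        subject_id=subject_id,
        condition=condition,
    )


def write_volume(vol, path, geometry: VolumeGeometry | None = None, tr_s: float | None = None) -> None:
    """Write a 3D volume, 4D array, or :class:`BoldRun` as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, BoldRun):
        geometry = vol.geometry
        tr_s = vol.tr_s
        data = vol.data
    else:
        data = np.asarray(vol)
        if geometry is None:
            raise ValueError("geometry required when writing a bare array")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), geometry.affine)
    if data.ndim == 4 and tr_s:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_s
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    img.to_filename(str(path))


def write_mask(mask: NetworkMask, path) -> None:
    """Store a mask as a uint8 indicator NIfTI volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.indicator.astype(np.uint8), mask.geometry.affine)
    img.to_filename(str(path))


def read_mask(path, name: str = "", world_convention: str = RIGHT_NEGATIVE_X) -> NetworkMask:
    data, geom = read_volume(path, world_convention=world_convention)
    return NetworkMask(geometry=geom, indicator=data > 0, name=name or Path(path).stem)
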