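"""Synthetic multi-subject BOLD study generator with known ground truth.

Each run's voxel series is a loading-weighted copy of its network's latent
signal plus temporally autocorrelated, spatially smoothed Gaussian noise:

    y_v(t) = sum_k (lambda_kv + delta_kv(c)) * g_k(t) + eps_v(t)

where g_k is a unit-variance AR(1) latent drawn independently per network
per run, lambda_kv is the network base loading inside network k (0 outside),
delta_kv(c) is a condition-dependent coupling perturbation confined to a
declared effect region, and eps_v is AR(1) noise smoothed to a target FWHM
and rescaled so its marginal standard deviation stays ``noise_sd``. A
fraction of frames per run is zero-filled and flagged as censored.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from connmap.volumes import BoldRun, NetworkMask, VolumeGeometry

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NetworkSpec:
    """A latent-signal community: name, member voxels, base loading."""

    name: str
    region: frozenset[tuple[int, int, int]]
    base_loading: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "region", frozenset(tuple(int(v) for v in ijk) for ijk in self.region)
        )
        if self.base_loading <= 0:
            raise ValueError("base_loading must be positive")

    def indicator(self, shape) -> np.ndarray:
        ind = np.zeros(shape, dtype=bool)
        idx = np.array(sorted(self.region), dtype=int)
        ind[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return ind


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth coupling perturbation confined to a voxel region.

    ``coupling_delta`` is added to the named network's latent loading inside
    ``region`` for the affected conditions (negative values weaken coupling).
    """

    region: frozenset[tuple[int, int, int]]
    conditions_affected: frozenset[str]
    coupling_delta: float
    network: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "region", frozenset(tuple(int(v) for v in ijk) for ijk in self.region)
        )
        object.__setattr__(self, "conditions_affected", frozenset(self.conditions_affected))
        if not np.isfinite(self.coupling_delta):
            raise ValueError("coupling_delta must be finite")

    def indicator(self, shape) -> np.ndarray:
        ind = np.zeros(shape, dtype=bool)
        idx = np.array(sorted(self.region), dtype=int)
        ind[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return ind


def _box(i0, i1, j0, j1, k0, k1) -> frozenset[tuple[int, int, int]]:
    return frozenset(
        (i, j, k) for i in range(i0, i1) for j in range(j0, j1) for k in range(k0, k1)
    )


def default_network_specs(grid_shape=(20, 20, 12), base_loading=0.2) -> list[NetworkSpec]:
    """Two overlapping multi-region networks on the reduced grid.

    An HCN-like and a PN-like community sharing one block, each built from
    several spatially separated ~100-125-voxel regions. Distributed geometry
    matters: real seed-defined networks are unions of distant patches, and a
    smooth noise field cannot grow the outsized connected excursions it
    would inside one compact solid mask.
    """
    nx, ny, nz = grid_shape
    if (nx, ny, nz) != (20, 20, 12):
        raise ValueError("default networks are defined for the 20x20x12 grid")
    overlap = _box(8, 12, 8, 12, 3, 9)  # 96 voxels shared by both networks
    hcn = (
        _box(2, 7, 2, 7, 3, 8)
        | _box(2, 7, 13, 18, 3, 8)
        | _box(13, 18, 2, 7, 3, 8)
        | _box(13, 18, 13, 18, 6, 11)
        | overlap
    )  # 596 voxels
    pn = (
        _box(2, 7, 8, 12, 7, 12)
        | _box(14, 19, 8, 12, 3, 8)
        | _box(8, 12, 2, 7, 6, 11)
        | _box(8, 12, 13, 18, 3, 8)
        | overlap
    )  # 496 voxels
    return [
        NetworkSpec("hcn", hcn, base_loading),
        NetworkSpec("pn", pn, base_loading),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale study: 12 subjects, 300 frames at TR 0.555 s
    on a 20x20x12 grid of 2-mm voxels, two overlapping multi-region networks
    with loading 0.2 over unit-SD AR(1) noise (phi = 0.3) smoothed to 3-mm
    FWHM, with 5% of frames censored — i.e. a network-mean pairwise
    correlation near 0.04, in the range typical of distributed resting-state
    networks. The full-cohort scale (24 subjects, 550 frames) is reachable
    by config.
    """

    n_subjects: int = 12
    n_frames: int = 300
    tr_s: float = 0.555
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 2.0
    conditions: tuple[str, ...] = ("sham", "cTBS", "iTBS")
    network_specs: list[NetworkSpec] = field(default_factory=default_network_specs)
    effects: list[EffectSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    smooth_fwhm_mm: float = 3.0
    censor_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        names = {n.name for n in self.network_specs}
        for eff in self.effects:
            net = eff.network or (self.network_specs[0].name if self.network_specs else "")
            if net not in names:
                raise ValueError(f"effect names unknown network {net!r}")
            spec = next(n for n in self.network_specs if n.name == net)
            if not eff.region <= spec.region:
                raise ValueError("effect region must lie inside its network")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry.isotropic(self.grid_shape, self.voxel_size_mm)


@dataclass
class StudyDataset:
    """A full synthetic cohort: runs, masks, generative truth, and config."""

    runs: dict[tuple[str, str], BoldRun]
    masks: dict[str, NetworkMask]
    truth: list[EffectSpec]
    config: SimConfig

    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.runs})

    def condition_runs(self, condition: str) -> list[BoldRun]:
        """Runs of one condition, ordered by subject (paired across calls)."""
        return [self.runs[(s, condition)] for s in self.subjects()]


def _ar1(rng: np.random.Generator, shape_t: tuple, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) over the last axis."""
    e = rng.standard_normal(shape_t)
    if phi == 0:
        return e
    scale = np.sqrt(1.0 - phi * phi)
    e = e * scale
    e[..., 0] /= scale  # x_0 ~ N(0, 1): stationary start
    return signal.lfilter([1.0], [1.0, -phi], e, axis=-1)


def _smoothing_norm(sigma_vox: tuple[float, float, float]) -> float:
    """sqrt of the variance-reduction factor of separable Gaussian smoothing.

    Dividing white noise smoothed with these sigmas by this value restores a
    unit marginal standard deviation (interior voxels; edges are slightly
    under-dispersed with zero-padding).
    """
    factor = 1.0
    for s in sigma_vox:
        if s <= 0:
            continue
        radius = int(4.0 * s + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / s) ** 2)
        w /= w.sum()
        factor *= float((w * w).sum())
    return float(np.sqrt(factor))


def generate_study(config: SimConfig) -> StudyDataset:
    """Simulate every subject x condition run plus masks and truth manifest."""
    geom = config.geometry
    shape = config.grid_shape
    T = config.n_frames
    sigma_vox = tuple(
        config.smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in geom.voxel_size_mm
    )
    smooth_norm = _smoothing_norm(sigma_vox) if config.smooth_fwhm_mm > 0 else 1.0

    # per-network loading fields and per-(network, condition) deltas
    base_lam = {}
    for net in config.network_specs:
        lam = np.zeros(shape)
        lam[net.indicator(shape)] = net.base_loading
        base_lam[net.name] = lam
    deltas: dict[tuple[str, str], np.ndarray] = {}
    for eff in config.effects:
        net = eff.network or config.network_specs[0].name
        for cond in eff.conditions_affected:
            key = (net, cond)
            if key not in deltas:
                deltas[key] = np.zeros(shape)
            deltas[key][eff.indicator(shape)] += eff.coupling_delta

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects * len(config.conditions))
    n_censor = int(round(config.censor_fraction * T))

    runs: dict[tuple[str, str], BoldRun] = {}
    idx = 0
    for si in range(config.n_subjects):
        subject = f"sub{si:02d}"
        for cond in config.conditions:
            rng = np.random.default_rng(children[idx])
            idx += 1
            data = np.zeros(shape + (T,))
            for net in config.network_specs:
                g = _ar1(rng, (T,), config.ar1_phi)
                lam = base_lam[net.name]
                d = deltas.get((net.name, cond))
                if d is not None:
                    lam = lam + d
                data += lam[..., None] * g[None, None, None, :]
            noise = _ar1(rng, shape + (T,), config.ar1_phi)
            if config.smooth_fwhm_mm > 0:
                noise = ndimage.gaussian_filter(
                    noise, sigma=sigma_vox + (0.0,), mode="constant"
                )
                noise /= smooth_norm
            data += config.noise_sd * noise
            censored: frozenset[int] = frozenset()
            if n_censor:
                frames = rng.choice(T, size=n_censor, replace=False)
                data[..., frames] = 0.0
                censored = frozenset(int(f) for f in frames)
            runs[(subject, cond)] = BoldRun(
                geometry=geom,
                data=data,
                tr_s=config.tr_s,
                censored_frames=censored,
                subject_id=subject,
                condition=cond,
            )

    masks = {
        net.name: NetworkMask(geom, net.indicator(shape), name=net.name)
        for net in config.network_specs
    }
    return StudyDataset(runs=runs, masks=masks, truth=list(config.effects), config=config)


def truth_overlap(detected, truth: EffectSpec | frozenset) -> float:
    """Dice coefficient between a detected voxel set and a ground-truth region."""
    a = {tuple(int(v) for v in ijk) for ijk in detected}
    region = truth.region if isinstance(truth, EffectSpec) else truth
    b = {tuple(int(v) for v in ijk) for ijk in region}
    if not a and not b:
        warnings.warn("both sets empty: Dice defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


# ---------------------------------------------------------------------------
# Study-directory round trip (runs + masks + truth manifest)


def _config_to_dict(config: SimConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "n_frames": config.n_frames,
        "tr_s": config.tr_s,
        "grid_shape": list(config.grid_shape),
        "voxel_size_mm": config.voxel_size_mm,
        "conditions": list(config.conditions),
        "network_specs": [
            {
                "name": n.name,
                "region": sorted(map(list, n.region)),
                "base_loading": n.base_loading,
            }
            for n in config.network_specs
        ],
        "effects": [
            {
                "region": sorted(map(list, e.region)),
                "conditions_affected": sorted(e.conditions_affected),
                "coupling_delta": e.coupling_delta,
                "network": e.network,
                "description": e.description,
            }
            for e in config.effects
        ],
        "noise_sd": config.noise_sd,
        "ar1_phi": config.ar1_phi,
        "smooth_fwhm_mm": config.smooth_fwhm_mm,
        "censor_fraction": config.censor_fraction,
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> SimConfig:
    return SimConfig(
        n_subjects=d["n_subjects"],
        n_frames=d["n_frames"],
        tr_s=d["tr_s"],
        grid_shape=tuple(d["grid_shape"]),
        voxel_size_mm=d["voxel_size_mm"],
        conditions=tuple(d["conditions"]),
        network_specs=[
            NetworkSpec(
                name=n["name"],
                region=frozenset(map(tuple, n["region"])),
                base_loading=n["base_loading"],
            )
            for n in d["network_specs"]
        ],
        effects=[
            EffectSpec(
                region=frozenset(map(tuple, e["region"])),
                conditions_affected=frozenset(e["conditions_affected"]),
                coupling_delta=e["coupling_delta"],
                network=e["network"],
                description=e.get("description", ""),
            )
            for e in d["effects"]
        ],
        noise_sd=d["noise_sd"],
        ar1_phi=d["ar1_phi"],
        smooth_fwhm_mm=d["smooth_fwhm_mm"],
        censor_fraction=d["censor_fraction"],
        seed=d["seed"],
    )


def write_study(study: StudyDataset, path) -> None:
    """Persist a study as NIfTI runs + masks + a JSON truth manifest."""
    import json
    from pathlib import Path

    from connmap.volumes import write_mask, write_volume

    root = Path(path)
    (root / "runs").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    censor = {}
    for (subject, cond), run in sorted(study.runs.items()):
        write_volume(run, root / "runs" / f"{subject}_{cond}.nii.gz")
        censor[f"{subject}_{cond}"] = sorted(run.censored_frames)
    for name, mask in study.masks.items():
        write_mask(mask, root / "masks" / f"{name}.nii.gz")
    manifest = {
        "config": _config_to_dict(study.config),
        "censored_frames": censor,
        "truth": _config_to_dict(study.config)["effects"],
    }
    (root / "study.json").write_text(json.dumps(manifest, indent=1))


def read_study(path) -> StudyDataset:
    """Load a study directory written by :func:`write_study`."""
    import json
    from pathlib import Path

    from connmap.volumes import read_bold, read_mask

    root = Path(path)
    manifest = json.loads((root / "study.json").read_text())
    config = config_from_dict(manifest["config"])
    runs = {}
    for si in range(config.n_subjects):
        subject = f"sub{si:02d}"
        for cond in config.conditions:
            key = f"{subject}_{cond}"
            runs[(subject, cond)] = read_bold(
                root / "runs" / f"{key}.nii.gz",
                subject_id=subject,
                condition=cond,
                censored_frames=manifest["censored_frames"][key],
            )
    masks = {
        n.name: read_mask(root / "masks" / f"{n.name}.nii.gz", name=n.name)
        for n in config.network_specs
    }
    return StudyDataset(runs=runs, masks=masks, truth=list(config.effects), config=config)
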