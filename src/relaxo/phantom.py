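"""Digital rat-brain phantom: parcellation, truth maps, simulated acquisitions.

The phantom emulates the study layout of a multicenter relaxometry
experiment without any real data: a 29-region parcellation (13 bilateral
region pairs plus 3 non-lateralized structures) placed inside an
ellipsoidal brain envelope, piecewise-constant ground-truth T1/T2/proton
density maps, inversion-recovery and multi-echo magnitude series with
Rician noise, per-center gain/bias/noise effects, and smooth label
perturbations standing in for inter-atlas delineation and registration
variability.

Geometry is schematic (compact blobs grown around seed points), not
anatomically faithful: only region count, size ratios (ventricles much
smaller than parenchymal structures) and mirror symmetry matter to the
downstream analysis.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import AcquisitionProtocol, ImageSeries, LabelVolume, Modality

__all__ = [
    "RegionTruth",
    "PhantomSpec",
    "CenterEffect",
    "canonical_lut",
    "default_region_truth",
    "default_ir_protocol",
    "default_multiecho_protocol",
    "make_label_phantom",
    "truth_maps",
    "simulate_ir_series",
    "simulate_multiecho_series",
    "apply_center_effect",
    "perturb_labels",
]

# 13 bilateral pairs + 3 non-lateralized structures = 29 regions.
_BILATERAL = (
    "Amygdala",
    "Caudate-putamen",
    "Cerebellum",
    "Cingulate cortex",
    "Cortical white matter",
    "Frontal cortex",
    "Hippocampus",
    "Lateral ventricle",
    "Occipital cortex",
    "Olfactory bulb",
    "Parietal cortex",
    "Temporal cortex",
    "Thalamus",
)
_MIDLINE = ("3rd and 4th ventricles", "Brain stem", "Cerebellar white matter")

VENTRICLE_REGIONS = (
    "Lateral ventricle L",
    "Lateral ventricle R",
    "3rd and 4th ventricles",
)

# Relative voxel-count weights: lateral ventricles ~3500 voxels, the 3rd and
# 4th ventricles ~11000, parenchymal structures ~33000 on average at the
# full acquisition matrix; the phantom preserves these ratios at any grid.
_SIZE_WEIGHTS = {
    "Lateral ventricle": 3500.0,
    "3rd and 4th ventricles": 11000.0,
}
_DEFAULT_WEIGHT = 33000.0

# Plausible healthy rat-brain values at 7 T (ms); proton density in
# arbitrary signal units. CSF-filled ventricles: long T1/T2, higher PD.
_TRUTH_TABLE = {
    "Amygdala": (1800.0, 44.0, 1000.0),
    "Caudate-putamen": (1750.0, 44.0, 1000.0),
    "Cerebellum": (1800.0, 45.0, 1000.0),
    "Cingulate cortex": (1850.0, 45.0, 1000.0),
    "Cortical white matter": (1650.0, 38.0, 950.0),
    "Frontal cortex": (1900.0, 46.0, 1000.0),
    "Hippocampus": (1850.0, 45.0, 1000.0),
    "Lateral ventricle": (2600.0, 110.0, 1150.0),
    "Occipital cortex": (1880.0, 45.0, 1000.0),
    "Olfactory bulb": (1900.0, 46.0, 1000.0),
    "Parietal cortex": (1860.0, 44.0, 1000.0),
    "Temporal cortex": (1840.0, 43.0, 1000.0),
    "Thalamus": (1700.0, 41.0, 1000.0),
    "3rd and 4th ventricles": (2500.0, 105.0, 1150.0),
    "Brain stem": (1650.0, 40.0, 980.0),
    "Cerebellar white matter": (1600.0, 37.0, 950.0),
}

T1_MAX_MS = 3000.0
T2_MAX_MS = 300.0
MIN_REGION_VOXELS = 8


def canonical_lut() -> pd.DataFrame:
    """The study lookup table: 29 regions, ids 1..29, alphabetical order."""
    rows = []
    names = sorted(
        [f"{n} {h}" for n in _BILATERAL for h in ("L", "R")] + list(_MIDLINE)
    )
    for i, name in enumerate(names, start=1):
        if name.endswith(" L"):
            hemi = "L"
        elif name.endswith(" R"):
            hemi = "R"
        else:
            hemi = "none"
        rows.append({"label_id": i, "region_name": name, "hemisphere": hemi})
    return pd.DataFrame(rows)


def _base_name(region_name: str) -> str:
    for suffix in (" L", " R"):
        if region_name.endswith(suffix):
            return region_name[: -len(suffix)]
    return region_name


@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth relaxation parameters of one region."""

    t1_ms: float
    t2_ms: float
    proton_density: float

    def __post_init__(self) -> None:
        if not 0 < self.t1_ms <= T1_MAX_MS:
            raise ValueError(f"t1_ms must be in (0, {T1_MAX_MS}], got {self.t1_ms}")
        if not 0 < self.t2_ms <= T2_MAX_MS:
            raise ValueError(f"t2_ms must be in (0, {T2_MAX_MS}], got {self.t2_ms}")
        if self.proton_density < 0:
            raise ValueError("proton_density must be >= 0")


def default_region_truth() -> dict[int, RegionTruth]:
    lut = canonical_lut()
    return {
        int(r.label_id): RegionTruth(*_TRUTH_TABLE[_base_name(r.region_name)])
        for r in lut.itertuples()
    }


def default_ir_protocol() -> AcquisitionProtocol:
    """Seven-point inversion-recovery protocol (TI in ms, TR = 6500 ms)."""
    return AcquisitionProtocol(
        modality=Modality.IR_T1,
        times_ms=(247.0, 408.0, 674.0, 1112.0, 1838.0, 3030.0, 5000.0),
        tr_ms=6500.0,
    )


def default_multiecho_protocol() -> AcquisitionProtocol:
    """28-echo multi-echo protocol: TE = 8, 16, ..., 224 ms; TR = 600 ms."""
    return AcquisitionProtocol(
        modality=Modality.MULTIECHO_T2,
        times_ms=tuple(8.0 * k for k in range(1, 29)),
        tr_ms=600.0,
    )


@dataclass
class PhantomSpec:
    """Geometry, ground truth and size targets of the digital phantom.

    ``target_size_ratios`` maps label_id to a relative voxel-count weight;
    realized counts are the weights normalized over the brain envelope.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    region_truth: dict[int, RegionTruth] = field(default_factory=default_region_truth)
    target_size_ratios: dict[int, float] = field(default_factory=dict)
    voxel_size_um: np.ndarray = field(
        default_factory=lambda: np.array([211.0, 211.0, 424.0])
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints: {self.grid_shape}")
        lut = canonical_lut()
        if set(self.region_truth) != set(lut["label_id"]):
            raise ValueError("region_truth must cover exactly the 29 canonical labels")
        if not self.target_size_ratios:
            self.target_size_ratios = {
                int(r.label_id): _SIZE_WEIGHTS.get(
                    _base_name(r.region_name), _DEFAULT_WEIGHT
                )
                for r in lut.itertuples()
            }
        if set(self.target_size_ratios) != set(lut["label_id"]):
            raise ValueError("target_size_ratios must cover all 29 labels")
        if any(w <= 0 for w in self.target_size_ratios.values()):
            raise ValueError("size ratios must be positive")

    @property
    def lut(self) -> pd.DataFrame:
        return canonical_lut()


@dataclass(frozen=True)
class CenterEffect:
    """Multiplicative gain, smooth bias field and extra noise of one center."""

    gain: float = 1.0
    bias_field_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if not 0 <= self.bias_field_amplitude < 1:
            raise ValueError(
                f"bias_field_amplitude must be in [0, 1), got "
                f"{self.bias_field_amplitude}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


# ---------------------------------------------------------------------------
# Parcellation generation


def _brain_envelope(shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean ellipsoid occupying ~90% of each grid extent."""
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def make_label_phantom(spec: PhantomSpec) -> LabelVolume:
    """Generate the 29-region parcellation.

    Regions are grown by capacity-constrained nearest-seed assignment: each
    region claims its target number of nearest unassigned envelope voxels,
    smallest regions first, so realized sizes match the target ratios
    exactly up to rounding. Bilateral pairs use mirrored seed points.
    Deterministic for a fixed ``spec.seed``.
    """
    lut = spec.lut
    envelope = _brain_envelope(spec.grid_shape)
    coords = np.argwhere(envelope).astype(float)
    n_total = len(coords)

    weights = np.array(
        [spec.target_size_ratios[int(l)] for l in lut["label_id"]], dtype=float
    )
    counts = np.maximum(
        MIN_REGION_VOXELS, np.round(weights / weights.sum() * n_total).astype(int)
    )
    if counts.sum() > n_total:
        # shrink the largest regions first, never below the floor
        order = np.argsort(-counts)
        excess = counts.sum() - n_total
        for i in order:
            take = min(excess, counts[i] - MIN_REGION_VOXELS)
            counts[i] -= take
            excess -= take
            if excess == 0:
                break
        if excess > 0:
            bad = lut["region_name"].tolist()
            raise ValueError(
                f"grid {spec.grid_shape} too small to place 29 regions of >= "
                f"{MIN_REGION_VOXELS} voxels each; unplaceable regions: {bad}"
            )

    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0

    # Seed points: left-half positions mirrored to the right for bilateral
    # pairs; midline positions for non-lateralized regions. Sampled in a
    # fixed order (base-name alphabetical) for determinism.
    seeds: dict[int, np.ndarray] = {}
    name_to_id = {r.region_name: int(r.label_id) for r in lut.itertuples()}
    for base in sorted(_BILATERAL):
        p = rng.uniform(0.15, 0.85, size=3) * (shape - 1)
        p[0] = center[0] - abs(p[0] - center[0])  # force into left half (x low)
        seeds[name_to_id[f"{base} L"]] = p
        q = p.copy()
        q[0] = 2 * center[0] - p[0]
        seeds[name_to_id[f"{base} R"]] = q
    for base in sorted(_MIDLINE):
        p = rng.uniform(0.2, 0.8, size=3) * (shape - 1)
        p[0] = center[0] + rng.uniform(-1.0, 1.0)
        seeds[name_to_id[base]] = p

    labels = np.zeros(spec.grid_shape, dtype=np.uint16)
    unassigned = np.ones(n_total, dtype=bool)
    order = np.argsort(counts, kind="stable")  # smallest (ventricles) first
    for i in order:
        label_id = int(lut["label_id"].iloc[i])
        want = int(counts[i])
        idx_pool = np.flatnonzero(unassigned)
        if len(idx_pool) < want:
            raise ValueError(
                f"grid too small: region '{lut['region_name'].iloc[i]}' needs "
                f"{want} voxels, only {len(idx_pool)} remain"
            )
        d2 = np.sum((coords[idx_pool] - seeds[label_id]) ** 2, axis=1)
        take = idx_pool[np.argpartition(d2, want - 1)[:want]]
        unassigned[take] = False
        vox = coords[take].astype(int)
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = label_id

    # Leftover envelope voxels (rounding slack) go to the nearest seed.
    leftover = np.flatnonzero(unassigned)
    if len(leftover):
        seed_mat = np.stack([seeds[int(l)] for l in lut["label_id"]])
        d2 = (
            np.sum(coords[leftover] ** 2, axis=1)[:, None]
            - 2 * coords[leftover] @ seed_mat.T
            + np.sum(seed_mat**2, axis=1)[None, :]
        )
        nearest = lut["label_id"].to_numpy()[np.argmin(d2, axis=1)]
        vox = coords[leftover].astype(int)
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = nearest

    return LabelVolume(
        labels=labels, lut=lut, voxel_size_um=np.asarray(spec.voxel_size_um)
    )


def truth_maps(
    labels: LabelVolume, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant ground-truth (t1_ms, t2_ms, proton-density) maps."""
    present = set(np.unique(labels.labels)) - {0}
    missing = sorted(present - set(spec.region_truth))
    if missing:
        raise ValueError(f"missing region_truth entries for labels: {missing}")
    t1 = np.zeros(labels.labels.shape, dtype=float)
    t2 = np.zeros_like(t1)
    pd_map = np.zeros_like(t1)
    for label_id, truth in spec.region_truth.items():
        mask = labels.labels == label_id
        t1[mask] = truth.t1_ms
        t2[mask] = truth.t2_ms
        pd_map[mask] = truth.proton_density
    return t1, t2, pd_map


# ---------------------------------------------------------------------------
# Signal simulation


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of complex Gaussian noise added to a real signal.

    out = sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2). At zero signal
    this is the Rayleigh floor with mean sigma*sqrt(pi/2).
    """
    if sigma == 0:
        return signal
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_ir_series(
    t1_map: np.ndarray,
    pd_map: np.ndarray,
    protocol: AcquisitionProtocol,
    inversion_efficiency: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    voxel_size_um: np.ndarray | None = None,
) -> ImageSeries:
    """Simulate a magnitude inversion-recovery series.

    Noiseless signal per voxel: ``|PD * (1 - B * exp(-TI/T1))|`` with
    B = ``inversion_efficiency`` (2 = perfect inversion). Rician noise of
    scale ``noise_sigma`` is applied to the magnitude; background voxels
    (PD = 0) carry the pure Rician floor.
    """
    if protocol.modality is not Modality.IR_T1:
        raise ValueError(f"expected IR_T1 protocol, got {protocol.modality}")
    if not 0 < inversion_efficiency <= 2:
        raise ValueError("inversion_efficiency must be in (0, 2]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    t1 = np.asarray(t1_map, dtype=float)
    pd_ = np.asarray(pd_map, dtype=float)
    if t1.shape != pd_.shape:
        raise ValueError("t1_map and pd_map shapes differ")

    fg = pd_ > 0
    safe_t1 = np.where(fg & (t1 > 0), t1, 1.0)
    ti = protocol.times[None, :]
    recovery = 1.0 - inversion_efficiency * np.exp(-ti / safe_t1.reshape(-1, 1))
    signal = np.abs(pd_.reshape(-1, 1) * recovery)
    signal[~fg.ravel()] = 0.0

    rng = np.random.default_rng(seed)
    noisy = _rician(signal, noise_sigma, rng)
    data = noisy.reshape(t1.shape + (len(protocol),))
    if voxel_size_um is None:
        voxel_size_um = np.array([211.0, 211.0, 424.0])
    return ImageSeries(data=data, protocol=protocol, voxel_size_um=voxel_size_um)


def simulate_multiecho_series(
    t2_map: np.ndarray,
    pd_map: np.ndarray,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
    voxel_size_um: np.ndarray | None = None,
) -> ImageSeries:
    """Simulate a mono-exponential multi-echo series: ``PD * exp(-TE/T2)``."""
    if protocol.modality is not Modality.MULTIECHO_T2:
        raise ValueError(f"expected MULTIECHO_T2 protocol, got {protocol.modality}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    t2 = np.asarray(t2_map, dtype=float)
    pd_ = np.asarray(pd_map, dtype=float)
    if t2.shape != pd_.shape:
        raise ValueError("t2_map and pd_map shapes differ")

    fg = pd_ > 0
    safe_t2 = np.where(fg & (t2 > 0), t2, 1.0)
    te = protocol.times[None, :]
    signal = pd_.reshape(-1, 1) * np.exp(-te / safe_t2.reshape(-1, 1))
    signal[~fg.ravel()] = 0.0

    rng = np.random.default_rng(seed)
    noisy = _rician(signal, noise_sigma, rng)
    data = noisy.reshape(t2.shape + (len(protocol),))
    if voxel_size_um is None:
        voxel_size_um = np.array([211.0, 211.0, 424.0])
    return ImageSeries(data=data, protocol=protocol, voxel_size_um=voxel_size_um)


def _bias_field(
    shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * f, max |f| = 1.

    f is a random combination of low-frequency separable cosine modes.
    """
    axes = [np.linspace(0.0, 1.0, s) for s in shape]
    f = np.zeros(shape)
    for _ in range(4):
        freq = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0.0, 2 * np.pi, size=3)
        coef = rng.normal()
        mode = coef
        for ax, (x, fr, ph) in enumerate(zip(axes, freq, phase)):
            c = np.cos(2 * np.pi * fr * x + ph)
            sh = [1, 1, 1]
            sh[ax] = shape[ax]
            mode = mode * c.reshape(sh)
        f = f + mode
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def apply_center_effect(series: ImageSeries, effect: CenterEffect) -> ImageSeries:
    """Apply one center's gain, bias field and extra Rician noise.

    Identity (bit-exact) when gain = 1, amplitude = 0 and sigma = 0.
    """
    data = series.data.astype(np.float64)
    rng = np.random.default_rng(effect.seed)
    if effect.bias_field_amplitude > 0:
        field_3d = _bias_field(data.shape[:3], effect.bias_field_amplitude, rng)
        data = data * field_3d[..., None]
    if effect.gain != 1.0:
        data = data * effect.gain
    if effect.noise_sigma > 0:
        data = _rician(data, effect.noise_sigma, rng)
    return ImageSeries(
        data=data.astype(np.float32),
        protocol=series.protocol,
        voxel_size_um=series.voxel_size_um,
        affine=series.affine,
    )


# ---------------------------------------------------------------------------
# Atlas perturbation


def perturb_labels(lv: LabelVolume, magnitude: float, seed: int = 0) -> LabelVolume:
    """Warp a parcellation through a smooth random displacement field.

    The field has RMS vector amplitude ``magnitude`` (voxels); labels are
    pulled back with nearest-neighbor interpolation, emulating inter-atlas
    delineation/registration variability. ``magnitude = 0`` is the identity.
    """
    if magnitude < 0:
        raise ValueError(f"magnitude must be >= 0, got {magnitude}")
    if magnitude == 0:
        return LabelVolume(
            labels=lv.labels.copy(),
            lut=lv.lut.copy(),
            voxel_size_um=lv.voxel_size_um.copy(),
            affine=lv.affine.copy(),
        )
    rng = np.random.default_rng(seed)
    shape = lv.labels.shape
    disp = np.stack(
        [
            ndimage.gaussian_filter(rng.normal(size=shape), sigma=3.0, mode="nearest")
            for _ in range(3)
        ]
    )
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=0)))
    if rms > 0:
        disp *= magnitude / rms
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    coords = [g + d for g, d in zip(grids, disp)]
    warped = ndimage.map_coordinates(lv.labels, coords, order=0, mode="nearest")
    return LabelVolume(
        labels=warped.astype(lv.labels.dtype),
        lut=lv.lut.copy(),
        voxel_size_um=lv.voxel_size_um.copy(),
        affine=lv.affine.copy(),
    )
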