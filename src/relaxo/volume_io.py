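"""Volumetric I/O: 4-D magnitude series and integer parcellations as NIfTI-1.

Every stage of the pipeline is file-interoperable through three objects:

* :class:`AcquisitionProtocol` — the timing vector of the acquisition
  (inversion times for an inversion-recovery T1 series, echo times for a
  multi-echo T2 series) plus the repetition time, all in milliseconds.
* :class:`ImageSeries` — a 4-D non-negative magnitude grid ``(x, y, z, t)``
  with voxel geometry and its protocol. Stored on disk as a NIfTI-1 volume
  (float32) plus a flat JSON sidecar holding ``modality``, ``times_ms`` and
  ``tr_ms``.
* :class:`LabelVolume` — a 3-D integer parcellation (0 = background) with a
  label lookup table. Stored as a uint16 NIfTI-1 volume plus a TSV LUT with
  header ``label_id<TAB>region_name<TAB>hemisphere``.

Volumes are assumed co-registered upstream; no reorientation or resampling
is performed here. Voxel indices are 0-based; world coordinates come from
the NIfTI affine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "AcquisitionProtocol",
    "ImageSeries",
    "LabelVolume",
    "read_series",
    "write_series",
    "read_labels",
    "write_labels",
]

LUT_COLUMNS = ("label_id", "region_name", "hemisphere")
HEMISPHERES = ("L", "R", "none")


class Modality(str, Enum):
    """Acquisition family: inversion-recovery T1 or multi-echo T2."""

    IR_T1 = "IR_T1"
    MULTIECHO_T2 = "MULTIECHO_T2"


def _default_affine(voxel_size_um: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(voxel_size_um, dtype=float) / 1000.0)
    return aff


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sampling times (TI or TE) and repetition time of one series, in ms.

    ``times_ms`` must be strictly increasing, positive, and hold at least
    three points (three-parameter fits need >= 3 samples). ``tr_ms`` only
    has to be positive: a multi-echo spin-echo train legitimately uses a TR
    shorter than its last echo time.
    """

    modality: Modality
    times_ms: tuple[float, ...]
    tr_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        times = tuple(float(t) for t in self.times_ms)
        object.__setattr__(self, "times_ms", times)
        if len(times) < 3:
            raise ValueError(f"protocol needs >= 3 time points, got {len(times)}")
        arr = np.asarray(times)
        if not np.all(arr > 0):
            raise ValueError("all sampling times must be > 0 ms")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if not self.tr_ms > 0:
            raise ValueError(f"tr_ms must be > 0, got {self.tr_ms}")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.times_ms, dtype=float)

    def __len__(self) -> int:
        return len(self.times_ms)


@dataclass
class ImageSeries:
    """4-D magnitude image grid ``(x, y, z, t)`` plus protocol and geometry."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size_um: np.ndarray = field(
        default_factory=lambda: np.array([211.0, 211.0, 424.0])
    )
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.voxel_size_um = np.asarray(self.voxel_size_um, dtype=float).reshape(3)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_um)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4-D, got ndim={self.data.ndim}")
        if any(s == 0 for s in self.data.shape):
            raise ValueError(f"series has an empty extent: shape={self.data.shape}")
        nt, nprot = self.data.shape[3], len(self.protocol)
        if nt != nprot:
            raise ValueError(
                f"4th dimension length {nt} != number of protocol times {nprot}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("series contains negative values (magnitude expected)")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3-D integer parcellation (0 = background) with a label lookup table.

    ``lut`` is a DataFrame with columns ``label_id``, ``region_name``,
    ``hemisphere`` (one of ``L``, ``R``, ``none``). Every nonzero label in
    the grid must appear in the LUT; LUT ids are unique and positive.
    """

    labels: np.ndarray
    lut: pd.DataFrame
    voxel_size_um: np.ndarray = field(
        default_factory=lambda: np.array([211.0, 211.0, 424.0])
    )
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if np.issubdtype(labels.dtype, np.floating) and np.all(
                labels == np.round(labels)
            ):
                labels = labels.astype(np.uint16)
            else:
                raise ValueError(f"labels must be integer-typed, got {labels.dtype}")
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got ndim={labels.ndim}")
        self.labels = labels
        self.voxel_size_um = np.asarray(self.voxel_size_um, dtype=float).reshape(3)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_um)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

        lut = pd.DataFrame(self.lut)
        missing = set(LUT_COLUMNS) - set(lut.columns)
        if missing:
            raise ValueError(f"lut missing columns: {sorted(missing)}")
        lut = lut.loc[:, list(LUT_COLUMNS)].copy()
        lut["label_id"] = lut["label_id"].astype(int)
        lut["region_name"] = lut["region_name"].astype(str)
        lut["hemisphere"] = lut["hemisphere"].astype(str)
        if lut["label_id"].duplicated().any():
            dup = lut.loc[lut["label_id"].duplicated(), "label_id"].tolist()
            raise ValueError(f"duplicate lut label ids: {dup}")
        if (lut["label_id"] <= 0).any():
            raise ValueError("lut label ids must be > 0")
        bad_hemi = set(lut["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"invalid hemisphere values: {sorted(bad_hemi)}")
        self.lut = lut.sort_values("label_id").reset_index(drop=True)

        present = set(np.unique(self.labels)) - {0}
        known = set(self.lut["label_id"])
        orphans = sorted(present - known)
        if orphans:
            raise ValueError(f"labels present in grid but absent from lut: {orphans}")

    @property
    def label_ids(self) -> np.ndarray:
        return self.lut["label_id"].to_numpy()

    def region_name(self, label_id: int) -> str:
        row = self.lut.loc[self.lut["label_id"] == label_id, "region_name"]
        if row.empty:
            raise KeyError(f"label {label_id} not in lut")
        return str(row.iloc[0])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um / 1000.0))


# ---------------------------------------------------------------------------
# Series I/O


def _load_sidecar(sidecar_path: str | Path) -> AcquisitionProtocol:
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    with open(sidecar_path) as fh:
        doc = json.load(fh)
    for key in ("modality", "times_ms", "tr_ms"):
        if key not in doc:
            raise KeyError(f"sidecar {sidecar_path} missing key '{key}'")
    return AcquisitionProtocol(
        modality=Modality(doc["modality"]),
        times_ms=tuple(float(t) for t in doc["times_ms"]),
        tr_ms=float(doc["tr_ms"]),
    )


def read_series(volume_path: str | Path, sidecar_path: str | Path) -> ImageSeries:
    """Read a 4-D NIfTI-1 magnitude series plus its JSON timing sidecar."""
    protocol = _load_sidecar(sidecar_path)
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 4-D volume, got ndim={data.ndim}")
    if data.shape[3] != len(protocol):
        raise ValueError(
            f"{volume_path}: volume has {data.shape[3]} time frames but the "
            f"sidecar lists {len(protocol)} times"
        )
    zooms = img.header.get_zooms()[:3]
    voxel_size_um = np.asarray(zooms, dtype=float) * 1000.0
    return ImageSeries(
        data=data, protocol=protocol, voxel_size_um=voxel_size_um, affine=img.affine
    )


def write_series(
    series: ImageSeries, volume_path: str | Path, sidecar_path: str | Path
) -> None:
    """Persist a series as float32 NIfTI-1 plus JSON sidecar (inverts read)."""
    if not np.all(np.isfinite(series.data)):
        raise ValueError("refusing to write series with non-finite values")
    if any(s == 0 for s in series.data.shape):
        raise ValueError(f"refusing to write empty-extent series: {series.data.shape}")
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_size_um / 1000.0) + (1.0,))
    nib.save(img, str(volume_path))
    doc = {
        "modality": series.protocol.modality.value,
        "times_ms": list(series.protocol.times_ms),
        "tr_ms": series.protocol.tr_ms,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Label I/O


def read_labels(volume_path: str | Path, lut_path: str | Path) -> LabelVolume:
    """Read an integer-typed NIfTI-1 parcellation plus its TSV lookup table."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if np.all(data == np.round(data)):
            data = data.astype(np.uint16)
        else:
            raise ValueError(
                f"{volume_path}: label volume must be integer-typed, "
                f"got {data.dtype} with fractional values"
            )
    lut = pd.read_csv(lut_path, sep="\t")
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(
        labels=data,
        lut=lut,
        voxel_size_um=np.asarray(zooms, dtype=float) * 1000.0,
        affine=img.affine,
    )


def write_labels(
    lv: LabelVolume, volume_path: str | Path, lut_path: str | Path
) -> None:
    """Persist a parcellation as uint16 NIfTI-1 plus TSV lookup table."""
    if lv.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed uint16 range")
    img = nib.Nifti1Image(lv.labels.astype(np.uint16), lv.affine)
    img.header.set_zooms(tuple(lv.voxel_size_um / 1000.0))
    nib.save(img, str(volume_path))
    lv.lut.to_csv(lut_path, sep="\t", index=False)
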