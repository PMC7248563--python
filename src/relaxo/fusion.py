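"""Multi-atlas maximum-probability label fusion and overlap metrics.

Fusion consumes a stack of co-registered hard parcellations (an
:class:`AtlasSet`) and selects, at each voxel, the label with the most
votes — the "maximum probability" rule with vote fraction as the label
probability. Background (label 0) participates as a regular candidate;
ties break deterministically to the smallest label id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import LabelVolume

__all__ = ["AtlasSet", "fuse_max_probability", "dice_score", "parcel_volumes"]


@dataclass
class AtlasSet:
    """Co-registered atlas parcellations sharing one grid and one LUT."""

    atlases: list[LabelVolume]

    def __post_init__(self) -> None:
        if len(self.atlases) < 1:
            raise ValueError("need at least one atlas")
        ref = self.atlases[0]
        for i, a in enumerate(self.atlases[1:], start=1):
            if a.labels.shape != ref.labels.shape:
                raise ValueError(
                    f"atlas {i} shape {a.labels.shape} != atlas 0 shape "
                    f"{ref.labels.shape}"
                )
            if not a.lut.equals(ref.lut):
                raise ValueError(f"atlas {i} lut differs from atlas 0")

    @property
    def n_atlases(self) -> int:
        return len(self.atlases)


def fuse_max_probability(atlas_set: AtlasSet) -> LabelVolume:
    """Per-voxel plurality vote over hard labels (ties -> smallest id)."""
    ref = atlas_set.atlases[0]
    stack = np.stack([a.labels for a in atlas_set.atlases])  # (n, x, y, z)
    candidates = np.unique(stack)
    if 0 not in candidates:
        candidates = np.concatenate([[0], candidates])
    candidates = np.sort(candidates)

    counts = np.zeros((len(candidates),) + ref.labels.shape, dtype=np.int32)
    for i, lab in enumerate(candidates):
        counts[i] = (stack == lab).sum(axis=0)
    # argmax returns the first (smallest-id) maximum: the tie-break rule
    winner = candidates[np.argmax(counts, axis=0)]
    return LabelVolume(
        labels=winner.astype(ref.labels.dtype),
        lut=ref.lut.copy(),
        voxel_size_um=ref.voxel_size_um.copy(),
        affine=ref.affine.copy(),
    )


def dice_score(a: LabelVolume, b: LabelVolume, label_id: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of one label's binary masks.

    Defined as 1.0 when the label is absent from both volumes (a region
    missing from both parcellations is perfect agreement, not 0/0).
    """
    if a.labels.shape != b.labels.shape:
        raise ValueError(
            f"grid mismatch: {a.labels.shape} vs {b.labels.shape}"
        )
    ma = a.labels == label_id
    mb = b.labels == label_id
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(ma & mb)) / denom


def parcel_volumes(lv: LabelVolume) -> pd.DataFrame:
    """Voxel counts and physical volumes per LUT entry (zero counts kept)."""
    ids, counts = np.unique(lv.labels, return_counts=True)
    count_map = dict(zip(ids.tolist(), counts.tolist()))
    rows = []
    for r in lv.lut.itertuples():
        n = int(count_map.get(int(r.label_id), 0))
        rows.append(
            {
                "label_id": int(r.label_id),
                "region_name": r.region_name,
                "voxel_count": n,
                "volume_mm3": n * lv.voxel_volume_mm3,
            }
        )
    return pd.DataFrame(rows)
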