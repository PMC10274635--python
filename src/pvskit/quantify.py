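"""ROI construction, PVS volume fractions and the IQR outlier filter.

The centrum semiovale is defined as a union of parcellation labels (for
real data, atlas white-matter regions; for phantoms, the "CSO-like"
block); the basal ganglia likewise.  The PVS volume fraction of a region
is the segmented PVS volume inside the ROI divided by the ROI volume.
Per-subject fractions beyond quartiles +/- k*IQR (k=1.5, quartiles by
linear-interpolation/type-7 quantiles) are flagged as outliers; a
subject flagged in either region is excluded from all models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROITable",
    "RegionMetrics",
    "build_region_mask",
    "pvs_volume_fraction",
    "iqr_outlier_filter",
    "dice_coefficient",
]


@dataclass
class ROITable:
    """Mapping of parcellation label IDs to named regions and groups.

    ``entries`` is a DataFrame with columns ``label_id`` (unique int),
    ``region_name`` (str) and ``group`` (``"CSO"``, ``"BG"`` or
    ``"other"``).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"label_id", "region_name", "group"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"ROITable missing columns: {sorted(missing)}")
        if self.entries["label_id"].duplicated().any():
            raise ValueError("label_ids must be unique")

    @classmethod
    def from_csv(cls, path) -> "ROITable":
        return cls(pd.read_csv(path))

    def labels_for(self, group: str) -> list[int]:
        sel = self.entries.loc[self.entries["group"] == group, "label_id"]
        return [int(v) for v in sel]

    @classmethod
    def phantom_default(cls) -> "ROITable":
        """Table for synthetic phantoms: label 1 CSO-like, label 2 BG-like."""
        return cls(pd.DataFrame({
            "label_id": [1, 2],
            "region_name": ["cso_like_block", "bg_like_block"],
            "group": ["CSO", "BG"],
        }))


@dataclass
class RegionMetrics:
    """PVS volume accounting for one subject and region."""

    subject_id: str
    region: str
    pvs_volume_mm3: float
    roi_volume_mm3: float
    pvs_vf: float


def build_region_mask(parcellation: np.ndarray, table: ROITable, group: str) -> np.ndarray:
    """Union mask of all parcellation labels assigned to ``group``.

    A label listed in the table but absent from the volume triggers a
    warning, not an error (regions can be empty in a given subject).
    """
    labels = table.labels_for(group)
    if not labels:
        raise ValueError(f"no labels defined for group {group!r}")
    present = np.unique(parcellation)
    for lab in labels:
        if lab not in present:
            warnings.warn(f"label {lab} ({group}) absent from parcellation volume",
                          stacklevel=2)
    return np.isin(parcellation, labels)


def pvs_volume_fraction(
    pvs_mask: np.ndarray,
    roi_mask: np.ndarray,
    voxel_dims: tuple[float, float, float],
    subject_id: str = "",
    region: str = "",
) -> RegionMetrics:
    """PVS volume fraction of an ROI: in-ROI PVS volume / ROI volume.

    PVS voxels outside the ROI never count.  Raises on an empty ROI.
    """
    if pvs_mask.shape != roi_mask.shape:
        raise ValueError("masks are not on the same grid")
    roi_n = int(np.count_nonzero(roi_mask))
    if roi_n == 0:
        raise ValueError("ROI mask is empty")
    voxel_vol = float(np.prod(voxel_dims))
    pvs_n = int(np.count_nonzero(pvs_mask & roi_mask))
    return RegionMetrics(
        subject_id=subject_id,
        region=region,
        pvs_volume_mm3=pvs_n * voxel_vol,
        roi_volume_mm3=roi_n * voxel_vol,
        pvs_vf=pvs_n / roi_n,
    )


def iqr_outlier_filter(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass IQR fence: flag v outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear-interpolation quantiles (Hyndman-Fan type 7,
    numpy's default), which matters on small samples.  Returns (kept
    indices, flagged indices).  The filter is deliberately single-pass:
    re-applying it to its own kept set can flag further values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 4 or not np.all(np.isfinite(arr)):
        raise ValueError("need at least 4 finite values")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # type 7 / linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flagged = np.flatnonzero((arr < lo) | (arr > hi))
    kept = np.setdiff1d(np.arange(arr.size), flagged)
    return kept, flagged


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
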