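"""Segmentation performance metrics.

Dice overlap between masks, physical mask volumes, white-matter-normalized
modal intensities, and the per-group volume-versus-intensity regressions
used to probe how image contrast influences segmentation volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyMaskError, MeshSegError
from .mesh import VoxelMask, erode_mask
from .profiles import modal_intensity

__all__ = [
    "SubjectRecord",
    "dice_score",
    "mask_volume",
    "normalized_modal_intensity",
    "intersection_eroded",
    "group_intensity_regression",
]

GROUPS = ("young", "middle-aged", "elderly")


@dataclass
class SubjectRecord:
    """Per-subject measurements for cohort-level analyses."""

    subject_id: str
    group: str
    volumes: dict = field(default_factory=dict)  # structure -> mm^3
    intensities: dict = field(default_factory=dict)  # (structure, modality) -> value

    def __post_init__(self):
        if self.group not in GROUPS:
            raise MeshSegError(f"group must be one of {GROUPS}, got {self.group!r}")
        for v in self.volumes.values():
            if v < 0:
                raise MeshSegError("volumes must be non-negative")


def dice_score(a: VoxelMask, b: VoxelMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two masks on the same grid."""
    if a.shape != b.shape or not np.allclose(a.affine, b.affine):
        raise MeshSegError("dice_score: masks are on different grids")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        raise EmptyMaskError("dice_score: both masks are empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def mask_volume(mask: VoxelMask) -> float:
    """Physical volume in mm^3: voxel count times |det| of the affine 3x3 block."""
    return mask.count() * mask.voxel_volume()


def intersection_eroded(a: VoxelMask, b: VoxelMask) -> VoxelMask:
    """Intersection of two raters' masks followed by one pass of 3x3x3 box
    erosion — the region used for intensity measurements (intersection first,
    then erosion: the conservative order)."""
    if a.shape != b.shape:
        raise MeshSegError("masks are on different grids")
    return erode_mask(VoxelMask(np.logical_and(a.data, b.data), a.affine))


def normalized_modal_intensity(volume: np.ndarray, structure_mask: VoxelMask,
                               wm_mask: VoxelMask | None = None,
                               mode: str = "relative") -> float:
    """Representative structure intensity, optionally normalized.

    "relative": modal intensity inside the structure divided by the mean
    white-matter intensity (removes arbitrary global scaling of
    T2*-weighted data). "absolute": the modal intensity itself (quantitative
    modalities such as QSM have no arbitrary scaling and are not normalized).
    """
    m = modal_intensity(volume, structure_mask)
    if mode == "absolute":
        return m
    if mode != "relative":
        raise MeshSegError("mode must be 'relative' or 'absolute'")
    if wm_mask is None or wm_mask.count() == 0:
        raise EmptyMaskError("relative normalization requires a non-empty WM mask")
    wm_mean = float(np.asarray(volume, float)[wm_mask.data].mean())
    if abs(wm_mean) < 1e-12:
        raise MeshSegError("white-matter mean intensity is zero")
    return m / wm_mean


def group_intensity_regression(records: list, structure: str, modality: str,
                               alpha: float = 0.05) -> pd.DataFrame:
    """OLS of segmentation volume on normalized structure intensity.

    One fit per group plus a pooled fit across all subjects. Returns a
    DataFrame with slope, intercept, two-sided slope p-value, n, and a
    significance flag at `alpha`. Requires >= 3 subjects per fitted line and
    a non-constant predictor.
    """
    rows = []
    by_group = {}
    for r in records:
        x = r.intensities.get((structure, modality))
        y = r.volumes.get(structure)
        if x is None or y is None:
            continue
        by_group.setdefault(r.group, []).append((x, y))
    pooled = [xy for g in by_group.values() for xy in g]
    fits = list(by_group.items()) + [("pooled", pooled)]
    for name, xy in fits:
        if len(xy) < 3:
            raise MeshSegError(
                f"group_intensity_regression: need >= 3 subjects per line, "
                f"{name!r} has {len(xy)}")
        x, y = np.array(xy).T
        if np.ptp(x) < 1e-12:
            raise MeshSegError(f"constant predictor in group {name!r}")
        fit = stats.linregress(x, y)
        rows.append({
            "group": name, "n": len(xy), "slope": fit.slope,
            "intercept": fit.intercept, "p_value": fit.pvalue,
            "significant": fit.pvalue <= alpha,
        })
    return pd.DataFrame(rows)
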