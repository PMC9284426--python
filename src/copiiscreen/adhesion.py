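"""Focal-adhesion quantification from vinculin-stained z-stacks.

Focal adhesions live in the single optical plane where the cell touches the
substrate, so quantification starts with autofocus: the in-focus slice is
the one maximizing the *normalized variance* (variance / mean), a standard
autofocus metric that is large when sharp high-contrast structures are
present and insensitive to overall brightness.  Adhesions are then
segmented in 2D by thresholding the maximum projection of three slices
centered on that plane (clamped at stack edges), and the total area, count,
mean size and total intensity are reported, normalized per cell by the
number of segmented nuclei.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import relabel_sequential

from .spot3d import VolumeStack

__all__ = [
    "FAResult",
    "focus_metrics",
    "select_focus_plane",
    "fa_segment",
    "fa_stats",
    "quantify_adhesions",
    "condition_summary",
]

DEFAULT_MIN_CELLS_PER_CONDITION = 50


@dataclass(frozen=True)
class FAResult:
    """Adhesion statistics of one imaged field.

    Areas are in pixels (scale by pixel_size**2 for micrometres squared).
    Per-cell values divide by the nucleus count and are NaN when no nuclei
    were found.
    """

    focus_plane: int
    fa_count: int
    total_fa_area: float
    total_fa_intensity: float
    mean_fa_size: float
    nuclei_count: int
    per_cell_area: float
    per_cell_count: float
    per_cell_total_intensity: float
    focus_flagged: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def focus_metrics(stack: VolumeStack | np.ndarray, *, channel: str = "vinculin") -> np.ndarray:
    """Normalized variance (variance / mean) of every optical slice."""
    vol = stack[channel] if isinstance(stack, VolumeStack) else np.asarray(stack, float)
    means = vol.mean(axis=(1, 2))
    variances = vol.var(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        metric = np.where(means > 0, variances / means, 0.0)
    return metric


def select_focus_plane(stack: VolumeStack | np.ndarray, *, channel: str = "vinculin") -> int:
    """Index of the slice with the largest normalized variance.

    Ties break to the lowest index; an all-zero stack has no focus
    information and yields 0.
    """
    metric = focus_metrics(stack, channel=channel)
    return int(np.argmax(metric))


def fa_segment(
    stack: VolumeStack | np.ndarray,
    plane: int,
    *,
    channel: str = "vinculin",
    threshold: float | None = None,
    min_size: int = 5,
) -> np.ndarray:
    """Label adhesions in the 3-slice maximum projection around ``plane``.

    The projection spans ``[plane-1, plane+1]`` clamped to the stack, which
    captures adhesions straddling the focus plane while excluding
    cytoplasmic staining elsewhere.  Threshold: Otsu by default (invariant
    to positive intensity rescaling); regions below ``min_size`` pixels are
    dropped as noise specks.
    """
    vol = stack[channel] if isinstance(stack, VolumeStack) else np.asarray(stack, float)
    if not 0 <= plane < vol.shape[0]:
        raise ValueError(f"plane {plane} outside stack of depth {vol.shape[0]}")
    lo, hi = max(0, plane - 1), min(vol.shape[0], plane + 2)
    projection = vol[lo:hi].max(axis=0)
    if projection.max() == projection.min():
        return np.zeros(projection.shape, dtype=np.int32)
    t = float(threshold) if threshold is not None else float(threshold_otsu(projection))
    mask = projection > t
    mask = remove_small_objects(mask, max_size=max(0, min_size - 1))
    from scipy import ndimage as ndi

    labels, _ = ndi.label(mask)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def fa_stats(
    fa_labels: np.ndarray,
    nuclei: np.ndarray,
    intensity: np.ndarray,
    *,
    focus_plane: int = 0,
    focus_flagged: bool = False,
) -> FAResult:
    """Area/count/size/intensity statistics, normalized per cell.

    The cell number is the nucleus count from the DNA channel; per-cell
    fields are totals divided by that count, NaN when it is zero.  The sum
    of individual adhesion areas equals the reported total area.
    """
    fa_labels = np.asarray(fa_labels)
    intensity = np.asarray(intensity, dtype=float)
    n_fa = int(fa_labels.max())
    total_area = float(np.count_nonzero(fa_labels))
    total_int = float(intensity[fa_labels > 0].sum()) if n_fa else 0.0
    nuclei_count = int(np.asarray(nuclei).max())
    per = float(nuclei_count) if nuclei_count > 0 else math.nan
    return FAResult(
        focus_plane=int(focus_plane),
        fa_count=n_fa,
        total_fa_area=total_area,
        total_fa_intensity=total_int,
        mean_fa_size=total_area / n_fa if n_fa else 0.0,
        nuclei_count=nuclei_count,
        per_cell_area=total_area / per,
        per_cell_count=n_fa / per,
        per_cell_total_intensity=total_int / per,
        focus_flagged=focus_flagged,
    )


def quantify_adhesions(
    stack: VolumeStack,
    *,
    fa_channel: str = "vinculin",
    nucleus_channel: str = "nucleus",
    threshold: float | None = None,
    min_size: int = 5,
) -> FAResult:
    """Full per-field adhesion pipeline: focus, segment, count, normalize."""
    from .imagequant import segment_nuclei

    vol = stack[fa_channel]
    flagged = bool(vol.max() == 0)
    plane = select_focus_plane(stack, channel=fa_channel)
    labels = fa_segment(stack, plane, channel=fa_channel, threshold=threshold, min_size=min_size)
    lo, hi = max(0, plane - 1), min(vol.shape[0], plane + 2)
    projection = vol[lo:hi].max(axis=0)
    nuc = stack[nucleus_channel]
    nuc_img = nuc[plane] if nuc.ndim == 3 else nuc
    nuclei = segment_nuclei(nuc_img)
    return fa_stats(labels, nuclei, projection, focus_plane=plane, focus_flagged=flagged)


def condition_summary(
    results: Sequence[FAResult],
    *,
    min_cells: int = DEFAULT_MIN_CELLS_PER_CONDITION,
) -> dict:
    """Condition-level adhesion summary, refused below ``min_cells`` cells."""
    n_cells = int(sum(r.nuclei_count for r in results))
    ok = n_cells >= min_cells
    frame = pd.DataFrame([r.to_dict() for r in results])
    return {
        "n_images": len(results),
        "n_cells": n_cells,
        "min_cells": int(min_cells),
        "ok": ok,
        "mean_fa_count": float(frame["fa_count"].mean()) if ok else math.nan,
        "mean_fa_size": float(frame["mean_fa_size"].mean()) if ok else math.nan,
        "mean_per_cell_area": float(frame["per_cell_area"].mean()) if ok else math.nan,
        "mean_per_cell_intensity": float(frame["per_cell_total_intensity"].mean())
        if ok
        else math.nan,
    }
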