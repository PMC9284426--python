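"""3D quantification of punctate structures (ER exit sites, COPI carriers).

Puncta are diffraction-limited bright spots in confocal stacks.  The
pipeline is: 3D median filtering for noise suppression and local-background
subtraction; seed detection by a local-maximum filter; seeded watershed
segmentation with separation of touching structures; exclusion of large
bright clusters (the Golgi complex accumulates the same markers but is not
a punctum); and per-cell statistics — the number of structures per cell,
their integrated intensity, and the integrated intensity of the whole cell.

Default structuring elements are isotropic; when a stack declares a z
spacing, z radii are scaled by (xy pixel / z spacing) so that physical
neighborhoods stay roughly spherical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import relabel_sequential, watershed
import tifffile

__all__ = [
    "VolumeStack",
    "SpotStats",
    "read_stack",
    "preprocess_stack",
    "estimate_noise_sigma",
    "auto_seed_threshold",
    "detect_seeds",
    "segment_spots",
    "exclude_large_clusters",
    "per_cell_spot_stats",
    "condition_summary",
]

DEFAULT_MIN_CELLS_PER_CONDITION = 100


@dataclass(frozen=True)
class VolumeStack:
    """Named, co-registered 3D intensity channels (z, y, x)."""

    channels: dict[str, np.ndarray]
    z_spacing: float | None = None  # micrometres, if known
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(v).shape for name, v in self.channels.items()}
        if not shapes:
            raise ValueError("a stack needs at least one channel")
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name, vol in self.channels.items():
            arr = np.asarray(vol, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def read_stack(
    path: str | Path, channel_names: Sequence[str], z_spacing: float | None = None
) -> VolumeStack:
    """Read a (C, Z, Y, X) or (Z, Y, X) TIFF as a :class:`VolumeStack`."""
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[0] != len(channel_names):
        raise ValueError(f"{path}: cannot map shape {arr.shape} onto channels {channel_names}")
    return VolumeStack(
        channels={name: arr[i] for i, name in enumerate(channel_names)}, z_spacing=z_spacing
    )


def _z_scaled_size(radius: int, stack: VolumeStack | None) -> tuple[int, int, int]:
    """Isotropic filter size, with the z extent shrunk for anisotropic stacks."""
    rz = radius
    if stack is not None and stack.z_spacing and stack.pixel_size:
        rz = max(1, int(round(radius * stack.pixel_size / stack.z_spacing)))
    return (2 * rz + 1, 2 * radius + 1, 2 * radius + 1)


def preprocess_stack(
    stack: VolumeStack | np.ndarray,
    *,
    channel: str | None = None,
    noise_radius: int = 1,
    background_radius: int = 4,
) -> np.ndarray:
    """Median-filter a channel and subtract its local median background.

    The small-radius median suppresses shot noise; the large-radius median
    estimates the smooth local background (cytosolic haze, uneven
    illumination), which is subtracted and the result clipped at zero.  A
    constant stack comes out identically zero.
    """
    if noise_radius <= 0 or background_radius <= 0:
        raise ValueError("filter radii must be positive")
    if background_radius <= noise_radius:
        raise ValueError("background_radius must exceed noise_radius")
    vol_stack = stack if isinstance(stack, VolumeStack) else None
    if isinstance(stack, VolumeStack):
        if channel is None:
            channel = next(iter(stack.channels))
        vol = stack[channel]
    else:
        vol = np.asarray(stack, dtype=float)
    denoised = ndi.median_filter(vol, size=_z_scaled_size(noise_radius, vol_stack))
    background = ndi.median_filter(denoised, size=_z_scaled_size(background_radius, vol_stack))
    return np.clip(denoised - background, 0.0, None)


def estimate_noise_sigma(vol: np.ndarray) -> float:
    """Robust noise scale of a (signed) residual volume.

    Median absolute deviation about the median, scaled to the normal sd;
    insensitive to the sparse bright structures the stacks are made of.
    """
    vol = np.asarray(vol, dtype=float)
    med = np.median(vol)
    mad = np.median(np.abs(vol - med))
    return float(1.4826 * mad)


def auto_seed_threshold(
    stack: VolumeStack | np.ndarray,
    *,
    channel: str | None = None,
    noise_radius: int = 1,
    background_radius: int = 4,
    k: float = 7.0,
) -> float:
    """Detection threshold ``k`` noise-sd above zero in the *filtered* volume.

    The relevant noise scale is that of the preprocessed (median-filtered,
    background-subtracted) volume, estimated robustly from its unclipped
    residual — raw shot noise overstates it several-fold because the median
    filter suppresses it.
    """
    vol_stack = stack if isinstance(stack, VolumeStack) else None
    if isinstance(stack, VolumeStack):
        if channel is None:
            channel = next(iter(stack.channels))
        vol = stack[channel]
    else:
        vol = np.asarray(stack, dtype=float)
    denoised = ndi.median_filter(vol, size=_z_scaled_size(noise_radius, vol_stack))
    background = ndi.median_filter(denoised, size=_z_scaled_size(background_radius, vol_stack))
    residual = denoised - background  # signed, not clipped
    return float(k * estimate_noise_sigma(residual))


def detect_seeds(
    vol: np.ndarray,
    min_seed_intensity: float,
    *,
    neighborhood: int = 1,
) -> np.ndarray:
    """Coordinates of local maxima above threshold in a preprocessed volume.

    A voxel is a seed when it attains the maximum of its
    (2*neighborhood+1)^3 neighborhood and exceeds ``min_seed_intensity``;
    plateaus contribute a single seed.  Raising the threshold can only
    remove seeds, never add them.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.size == 0 or vol.max() < min_seed_intensity:
        return np.empty((0, 3), dtype=int)
    coords = peak_local_max(
        vol,
        min_distance=neighborhood,
        threshold_abs=float(min_seed_intensity),
        exclude_border=False,
    ).astype(int)
    if len(coords) < 2:
        return coords
    # median-filtered volumes carry exact ties: adjacent equal-valued voxels
    # form plateaus that peak_local_max reports in full.  Keep one seed per
    # plateau, brightest first.
    order = np.argsort(-vol[tuple(coords.T)], kind="stable")
    kept: list[np.ndarray] = []
    for c in coords[order]:
        if all(np.max(np.abs(c - k)) > neighborhood for k in kept):
            kept.append(c)
    return np.array(kept, dtype=int)


def segment_spots(
    vol: np.ndarray,
    seeds: np.ndarray,
    *,
    mask_threshold: float | None = None,
    min_seed_intensity: float | None = None,
    merge_saddle_ratio: float = 0.7,
) -> np.ndarray:
    """Watershed segmentation of puncta from seed coordinates.

    The segmentation mask keeps voxels above ``mask_threshold`` (default:
    half of ``min_seed_intensity`` when given, else half the dimmest seed's
    intensity); touching structures are split along the watershed lines
    between their seeds.  One label per retained seed, no seeds -> empty
    mask.

    Shot noise can split a single punctum's peak into two local maxima, so
    adjacent labels are re-merged when the intensity saddle on their shared
    interface exceeds ``merge_saddle_ratio`` times the dimmer peak — a real
    pair of touching structures keeps a deep valley between its maxima,
    a noise-split peak does not.  Set the ratio to 1 to disable merging.
    """
    vol = np.asarray(vol, dtype=float)
    labels = np.zeros(vol.shape, dtype=np.int32)
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size == 0:
        return labels
    if mask_threshold is None:
        base = (
            float(min_seed_intensity)
            if min_seed_intensity is not None
            else float(min(vol[tuple(c)] for c in seeds))
        )
        mask_threshold = 0.5 * base
    mask = vol > mask_threshold
    markers = np.zeros(vol.shape, dtype=np.int32)
    for i, c in enumerate(seeds, start=1):
        markers[tuple(c)] = i
        mask[tuple(c)] = True  # a seed always belongs to its own structure
    labels = watershed(-vol, markers, mask=mask).astype(np.int32)
    if merge_saddle_ratio < 1.0 and labels.max() > 1:
        labels = _merge_noise_split_labels(labels, vol, merge_saddle_ratio)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def _merge_noise_split_labels(
    labels: np.ndarray, vol: np.ndarray, saddle_ratio: float
) -> np.ndarray:
    """Merge adjacent labels without a deep intensity valley between them."""
    n = int(labels.max())
    peaks = ndi.maximum(vol, labels, np.arange(1, n + 1))
    saddles: dict[tuple[int, int], float] = {}
    for axis in range(labels.ndim):
        lo = [slice(None)] * labels.ndim
        hi = [slice(None)] * labels.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a, b = labels[tuple(lo)], labels[tuple(hi)]
        va, vb = vol[tuple(lo)], vol[tuple(hi)]
        touch = (a > 0) & (b > 0) & (a != b)
        if not touch.any():
            continue
        pa, pb = a[touch], b[touch]
        sv = np.minimum(va[touch], vb[touch])
        for la, lb, s in zip(pa.ravel(), pb.ravel(), sv.ravel()):
            key = (int(min(la, lb)), int(max(la, lb)))
            if s > saddles.get(key, -np.inf):
                saddles[key] = float(s)
    parent = list(range(n + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (la, lb), saddle in saddles.items():
        if saddle >= saddle_ratio * min(peaks[la - 1], peaks[lb - 1]):
            parent[find(la)] = find(lb)
    remap = np.array([0] + [find(i) for i in range(1, n + 1)], dtype=np.int32)
    return remap[labels]


def exclude_large_clusters(
    labels: np.ndarray,
    vol: np.ndarray,
    *,
    min_cluster_volume: int = 200,
    cluster_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Separate Golgi-like clusters from the spot mask.

    Bright connected regions (thresholded at ``cluster_threshold``, default
    the spot mask itself) whose volume exceeds ``min_cluster_volume`` voxels
    are returned as a separate cluster mask, and any spot label overlapping
    them is removed from the spot mask.  ``min_cluster_volume`` should
    comfortably exceed the typical punctum volume.
    """
    vol = np.asarray(vol, dtype=float)
    labels = np.asarray(labels)
    if cluster_threshold is None:
        bright = labels > 0
    else:
        bright = vol > cluster_threshold
    comps, n = ndi.label(bright)
    cluster_mask = np.zeros(vol.shape, dtype=np.int32)
    if n:
        sizes = np.bincount(comps.ravel())
        big = np.flatnonzero(sizes > min_cluster_volume)
        big = big[big != 0]
        next_id = 0
        for comp_id in big:
            next_id += 1
            cluster_mask[comps == comp_id] = next_id
    spot_labels = labels.copy()
    if cluster_mask.any():
        overlapping = np.unique(spot_labels[cluster_mask > 0])
        overlapping = overlapping[overlapping != 0]
        if overlapping.size:
            spot_labels[np.isin(spot_labels, overlapping)] = 0
        spot_labels, _, _ = relabel_sequential(spot_labels)
    return spot_labels.astype(np.int32), cluster_mask


@dataclass(frozen=True)
class SpotStats:
    """Per-cell puncta statistics plus the unassigned-spot count."""

    per_cell: pd.DataFrame  # cell_id, structure_count, spot_intensity, cell_intensity
    n_unassigned: int

    @property
    def total_spots(self) -> int:
        return int(self.per_cell["structure_count"].sum()) + self.n_unassigned


def per_cell_spot_stats(
    spot_labels: np.ndarray,
    cells: np.ndarray,
    vol: np.ndarray,
) -> SpotStats:
    """Assign each punctum to the cell containing its centroid and summarize.

    ``cells`` may be a 3D label mask or a 2D projected mask (applied to
    every slice).  Each cell row reports its structure count, the integrated
    intensity of its puncta, and the integrated intensity of its entire
    region.  Puncta whose centroid falls in the background are counted as
    unassigned.
    """
    vol = np.asarray(vol, dtype=float)
    spot_labels = np.asarray(spot_labels)
    cells = np.asarray(cells)
    cells3d = cells if cells.ndim == 3 else np.broadcast_to(cells, vol.shape)
    n_cells = int(cells.max())
    n_spots = int(spot_labels.max())
    counts = np.zeros(n_cells + 1, dtype=int)
    spot_intensity = np.zeros(n_cells + 1, dtype=float)
    n_unassigned = 0
    if n_spots:
        centroids = ndi.center_of_mass(
            np.ones_like(spot_labels), spot_labels, np.arange(1, n_spots + 1)
        )
        intensities = ndi.sum_labels(vol, spot_labels, np.arange(1, n_spots + 1))
        for centroid, intensity in zip(centroids, intensities):
            zc, yc, xc = (int(round(c)) for c in centroid)
            host = int(cells3d[zc, yc, xc])
            if host == 0:
                n_unassigned += 1
            else:
                counts[host] += 1
                spot_intensity[host] += float(intensity)
    cell_totals = (
        ndi.sum_labels(vol, cells3d, np.arange(1, n_cells + 1)) if n_cells else np.array([])
    )
    per_cell = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "structure_count": counts[1:],
            "spot_intensity": spot_intensity[1:],
            "cell_intensity": np.asarray(cell_totals, dtype=float),
        }
    )
    return SpotStats(per_cell=per_cell, n_unassigned=n_unassigned)


def condition_summary(
    per_cell_tables: Sequence[pd.DataFrame],
    *,
    min_cells: int = DEFAULT_MIN_CELLS_PER_CONDITION,
) -> dict:
    """Condition-level means over cells, refused below ``min_cells`` cells.

    Pooled across images; a condition quantified on too few cells is
    reported flagged (``ok = False``) with NaN summaries rather than a
    misleading mean.
    """
    pooled = (
        pd.concat(per_cell_tables, ignore_index=True)
        if per_cell_tables
        else pd.DataFrame(columns=["structure_count", "spot_intensity", "cell_intensity"])
    )
    n = int(len(pooled))
    ok = n >= min_cells
    return {
        "n_cells": n,
        "min_cells": int(min_cells),
        "ok": ok,
        "mean_count": float(pooled["structure_count"].mean()) if ok else math.nan,
        "mean_spot_intensity": float(pooled["spot_intensity"].mean()) if ok else math.nan,
        "mean_cell_intensity": float(pooled["cell_intensity"].mean()) if ok else math.nan,
    }
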