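"""Per-cell quantification of transport assays from 2D multichannel fields.

The transport readout is a per-cell ratio of a *surface* marker (antibody
staining against an extracellular epitope of the reporter, so only the
plasma-membrane-arrived fraction is labeled) to the *total* reporter signal
(the fluorescent-protein tag).  Cells are segmented by seeding a watershed
with nuclei found in the DNA-stain channel; intensities are summed over the
whole cell region after background correction (the surface antibody labels
only surface epitopes, so the whole-cell sum *is* the surface signal).

Also here: expression binning (non / low / high) used for rescue and
cargo-load analyses, the multinucleation fraction used as a transfection-
efficiency proxy, and the leak-corrected transport index for biotin-release
(RUSH) assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import relabel_sequential, watershed
import tifffile

__all__ = [
    "ChannelField",
    "CellRecord",
    "RushIndex",
    "read_field",
    "background_correct",
    "segment_nuclei",
    "segment_cells",
    "per_cell_transport_ratio",
    "bin_cells_by_expression",
    "multinucleation_fraction",
    "rush_transport_index",
    "records_to_frame",
    "write_records_csv",
]


@dataclass(frozen=True)
class ChannelField:
    """Named, co-registered 2D intensity channels of one imaged field."""

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # micrometres per pixel, if known

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        if not shapes:
            raise ValueError("a field needs at least one channel")
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell's intensities and derived transport ratio."""

    cell_id: int
    nucleus_count: int
    total_intensity: float
    surface_intensity: float
    transport_ratio: float  # NaN when flagged
    expression_bin: str | None = None
    valid: bool = True


@dataclass(frozen=True)
class RushIndex:
    """Leak-corrected transport of a biotin-release assay condition."""

    index: float
    release_mean: float
    leak_mean: float
    n_release: int
    n_nonrelease: int

    @property
    def ok(self) -> bool:
        return math.isfinite(self.index)


def read_field(
    path: str | Path, channel_names: Sequence[str], pixel_size: float | None = None
) -> ChannelField:
    """Read a multichannel TIFF/OME-TIFF as a :class:`ChannelField`.

    The file's leading axis is taken as the channel axis and mapped onto
    ``channel_names`` in order.
    """
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {arr.shape[0]} channels in file, {len(channel_names)} names given"
        )
    return ChannelField(
        channels={name: arr[i] for i, name in enumerate(channel_names)}, pixel_size=pixel_size
    )


def background_correct(img: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Subtract the image's low-percentile intensity, clipped at zero.

    A flat camera/stain offset estimated from the darkest pixels; adding a
    uniform background to an image and re-correcting is a no-op up to that
    estimate.
    """
    img = np.asarray(img, dtype=float)
    return np.clip(img - np.percentile(img, percentile), 0.0, None)


def _threshold(img: np.ndarray, threshold: float | None) -> float | None:
    """Otsu threshold, or None when the image carries no contrast."""
    if threshold is not None:
        return float(threshold)
    if img.max() == img.min():
        return None
    return float(threshold_otsu(img))


def segment_nuclei(
    field: ChannelField | np.ndarray,
    *,
    channel: str = "nucleus",
    sigma: float = 2.0,
    threshold: float | None = None,
    min_size: int = 40,
    min_distance: int = 7,
) -> np.ndarray:
    """Label nuclei in the DNA-stain channel.

    Smoothing + global (Otsu) threshold + distance-transform watershed to
    split touching nuclei.  Returns an integer label mask (background 0,
    labels contiguous from 1); a blank field yields zero labels.
    """
    img = field[channel] if isinstance(field, ChannelField) else np.asarray(field, float)
    smoothed = ndi.gaussian_filter(img, sigma)
    t = _threshold(smoothed, threshold)
    if t is None:
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > t
    mask = remove_small_objects(mask, max_size=max(0, min_size - 1))
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=ndi.label(mask)[0], exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    labels = watershed(-distance, markers, mask=mask)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    field: ChannelField,
    nuclei: np.ndarray,
    *,
    channel: str = "total_marker",
    sigma: float = 2.0,
    threshold: float | None = None,
    merge_nucleus_distance: float | None = None,
) -> np.ndarray:
    """Partition the foreground into one cell region per nucleus (group).

    Watershed on the (inverted, smoothed) cell-marker channel seeded with the
    nucleus labels, restricted to the above-threshold foreground.  Each cell
    keeps its seed nucleus's label; cells partition the foreground (disjoint
    regions whose union is the foreground).

    ``merge_nucleus_distance`` merges nuclei whose centroids are closer than
    the given pixel distance into a single seed before the watershed:
    multinucleated cells (e.g. after knockdown of a cytokinesis regulator)
    carry adjacent nuclei inside one cytoplasm, and seeding them separately
    would wrongly split the cell.  Off by default.
    """
    img = field[channel]
    if nuclei.max() == 0:
        return np.zeros(img.shape, dtype=np.int32)
    markers = nuclei.astype(np.int32)
    if merge_nucleus_distance is not None and nuclei.max() > 1:
        centroids = ndi.center_of_mass(
            np.ones_like(nuclei), nuclei, np.arange(1, int(nuclei.max()) + 1)
        )
        centroids = np.asarray(centroids)
        # union-find over nucleus pairs closer than the merge distance
        parent = list(range(len(centroids)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(centroids)):
            for j in range(i + 1, len(centroids)):
                if np.linalg.norm(centroids[i] - centroids[j]) < merge_nucleus_distance:
                    parent[find(i)] = find(j)
        groups = {}
        remap = np.zeros(int(nuclei.max()) + 1, dtype=np.int32)
        for i in range(len(centroids)):
            root = find(i)
            groups.setdefault(root, len(groups) + 1)
            remap[i + 1] = groups[root]
        markers = remap[nuclei]
    smoothed = ndi.gaussian_filter(img, sigma)
    t = _threshold(smoothed, threshold)
    if t is None:
        # no contrast: a uniformly positive field is all foreground
        mask = np.full(img.shape, bool(img.max() > 0))
    else:
        mask = smoothed > t
    mask |= nuclei > 0
    labels = watershed(-smoothed, markers=markers, mask=mask)
    return labels.astype(np.int32)


def _nucleus_hosts(cells: np.ndarray, nuclei: np.ndarray) -> dict[int, int]:
    """Host cell of each nucleus: the cell label covering most of its pixels."""
    hosts: dict[int, int] = {}
    for label, sl in enumerate(ndi.find_objects(nuclei), start=1):
        if sl is None:
            continue
        covering = np.bincount(cells[sl][nuclei[sl] == label].ravel())
        covering[0] = 0  # never assign a nucleus to the background
        hosts[label] = int(covering.argmax()) if covering.any() else 0
    return hosts


def per_cell_transport_ratio(
    field: ChannelField,
    cells: np.ndarray,
    *,
    surface_channel: str = "surface_marker",
    total_channel: str = "total_marker",
    nuclei: np.ndarray | None = None,
    background_percentile: float = 5.0,
) -> list[CellRecord]:
    """One :class:`CellRecord` per cell label: background-corrected channel
    sums and their ratio.

    Cells whose total intensity is not positive are flagged (NaN ratio,
    ``valid=False``) and take no part in downstream spot means.  Scaling both
    channels by the same constant leaves every ratio unchanged.
    """
    surface = background_correct(field[surface_channel], background_percentile)
    total = background_correct(field[total_channel], background_percentile)
    n = int(cells.max())
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    surface_sums = ndi.sum_labels(surface, cells, idx)
    total_sums = ndi.sum_labels(total, cells, idx)
    counts: dict[int, int] = {i: 0 for i in idx}
    if nuclei is not None:
        for _, host in _nucleus_hosts(cells, nuclei).items():
            if host:
                counts[host] = counts.get(host, 0) + 1
    records = []
    for i, s, t in zip(idx, surface_sums, total_sums):
        ok = t > 0
        records.append(
            CellRecord(
                cell_id=int(i),
                nucleus_count=counts.get(int(i), 0),
                total_intensity=float(t),
                surface_intensity=float(s),
                transport_ratio=float(s / t) if ok else math.nan,
                valid=bool(ok),
            )
        )
    return records


def bin_cells_by_expression(
    records: Iterable[CellRecord],
    thresholds: tuple[float, float],
    *,
    key: str = "total_intensity",
) -> list[CellRecord]:
    """Assign each cell to a non / low / high expression bin.

    Bins are left-closed, right-open: intensity < t1 -> ``non``;
    t1 <= intensity < t2 -> ``low``; intensity >= t2 -> ``high``.
    """
    t1, t2 = float(thresholds[0]), float(thresholds[1])
    if not t1 < t2:
        raise ValueError(f"expression thresholds must satisfy t1 < t2, got ({t1}, {t2})")
    out = []
    for rec in records:
        value = float(getattr(rec, key))
        bin_ = "non" if value < t1 else ("low" if value < t2 else "high")
        out.append(replace(rec, expression_bin=bin_))
    return out


def percentile_expression_thresholds(
    records: Iterable[CellRecord], *, key: str = "total_intensity", percentiles=(33.0, 66.0)
) -> tuple[float, float]:
    """Data-driven default bin edges (33rd/66th percentile of expression)."""
    values = np.array([getattr(r, key) for r in records], dtype=float)
    t1, t2 = np.percentile(values, percentiles)
    return float(t1), float(t2)


def multinucleation_fraction(cells: np.ndarray, nuclei: np.ndarray) -> float:
    """Fraction of cells containing two or more nuclei (NaN when no cells).

    Used as a transfection-efficiency readout: knocking down a cytokinesis
    regulator multinucleates exactly the cells that took up siRNA.
    """
    n_cells = int(cells.max())
    if n_cells == 0:
        return math.nan
    per_cell = np.zeros(n_cells + 1, dtype=int)
    for _, host in _nucleus_hosts(cells, nuclei).items():
        if host:
            per_cell[host] += 1
    return float(np.mean(per_cell[1:] >= 2))


def rush_transport_index(
    release_records: Iterable[CellRecord],
    nonrelease_records: Iterable[CellRecord],
) -> RushIndex:
    """Leak-corrected transport of a synchronized-release assay.

    The non-release control measures cargo reaching the surface despite the
    retention hook (leakiness); the index is mean(release ratios) minus
    mean(non-release ratios), floored at zero, reported alongside both raw
    means.  An empty record set yields a NaN (flagged-missing) index.
    """

    def _ratios(records: Iterable[CellRecord]) -> np.ndarray:
        vals = np.array([r.transport_ratio for r in records if r.valid], dtype=float)
        return vals[np.isfinite(vals)]

    rel = _ratios(release_records)
    leak = _ratios(nonrelease_records)
    if rel.size == 0 or leak.size == 0:
        return RushIndex(math.nan, math.nan, math.nan, int(rel.size), int(leak.size))
    release_mean = float(rel.mean())
    leak_mean = float(leak.mean())
    return RushIndex(
        index=max(0.0, release_mean - leak_mean),
        release_mean=release_mean,
        leak_mean=leak_mean,
        n_release=int(rel.size),
        n_nonrelease=int(leak.size),
    )


def records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "nucleus_count": r.nucleus_count,
                "total_intensity": r.total_intensity,
                "surface_intensity": r.surface_intensity,
                "transport_ratio": r.transport_ratio,
                "expression_bin": r.expression_bin if r.expression_bin is not None else "",
                "valid": r.valid,
            }
            for r in records
        ],
        columns=[
            "cell_id",
            "nucleus_count",
            "total_intensity",
            "surface_intensity",
            "transport_ratio",
            "expression_bin",
            "valid",
        ],
    )


def write_records_csv(records: Iterable[CellRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path
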