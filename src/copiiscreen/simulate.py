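"""Ground-truth generators for every pipeline stage.

Two families of simulators:

* **Screen plates** — 384-spot chambers carrying a cytoskeleton-style siRNA
  library (848 siRNAs over 378 target genes, 4 chambers) plus positive,
  negative and transfection-QC control spots.  Per-cell transport ratios are
  generated additively on the ratio scale::

      ratio = base + gene_effect + background_effect + interaction
                   + gradient(row, col) + N(0, noise_sd),   truncated at 0

  with per-spot cell counts Poisson distributed.  The additive model is the
  simplest generative process that exercises the screen's additive hit rule;
  a smooth low-order polynomial gradient (default amplitude 20% of the base
  ratio) exercises the windowed plate normalization.  Most library
  knockdowns carry small but real main effects (default sd 0.04 ratio
  units, 8% of the base ratio): a cytoskeleton library is not inert, and
  this spot-to-spot biological spread is what the window MAD estimates in a
  real screen.

* **Microscopy fields and stacks** — 2D multichannel fields with known
  nuclei, cell territories and programmed per-cell ratios; 3D stacks with
  Gaussian puncta (and an optional large bright Golgi-like cluster) under
  Poisson + Gaussian read noise at a set SNR; and adhesion stacks with sharp
  ellipses in one designated in-focus slice and optically attenuated,
  blurred copies elsewhere.

Everything is fully deterministic given the seed, and every generator emits
its ground truth (effects, interactions, coordinates, masks) alongside the
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .plate import PlateLayout, SpotAssignment

__all__ = [
    "SyntheticTruth",
    "plate_gradient",
    "design_screen_layouts",
    "make_screen_truth",
    "simulate_plate",
    "simulate_screen",
    "PlateSim",
    "simulate_cell_field",
    "simulate_spot_stack",
    "simulate_fa_stack",
]

# Control siRNAs spotted alongside the library.  COPB1/COPG1 knockdowns give
# strong transport inhibition (positive controls); Scramble/Neg9 are
# nontargeting; INCENP knockdown gives multinucleated cells (transfection QC).
CONTROL_CYCLE = (
    ("Scramble", None, "negative"),
    ("Neg9", None, "negative"),
    ("si_COPB1", "COPB1", "positive"),
    ("si_COPG1", "COPG1", "positive"),
    ("si_INCENP", "INCENP", "transfection_qc"),
)

DEFAULT_GRADIENT_COEFFS = (1.0, 0.6, 0.8, -0.5, 0.0)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated screen: what every spot's ratio should be.

    ``gene_effects`` / ``background_effects`` / ``interactions`` are on the
    transport-ratio scale (dimensionless, like the ratio itself).
    ``interactions`` maps (target gene, background) to the extra ratio shift
    present only in the double knockdown.
    """

    seed: int
    base_ratio: float = 0.5
    noise_sd: float = 0.15
    cells_per_spot_mean: float = 200.0
    gradient_amplitude: float = 0.1
    gradient_coeffs: tuple[float, ...] = DEFAULT_GRADIENT_COEFFS
    gene_effects: dict[str, float] = field(default_factory=dict)
    background_effects: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    binucleation_baseline: float = 0.05
    binucleation_transfected: float = 0.6

    def spot_mean(self, spot: SpotAssignment, gradient: np.ndarray) -> float:
        gene = spot.target_gene
        mu = self.base_ratio
        mu += self.background_effects.get(spot.background, 0.0)
        mu += float(gradient[spot.row, spot.col])
        if gene is not None:
            mu += self.gene_effects.get(gene, 0.0)
            mu += self.interactions.get((gene, spot.background), 0.0)
        return mu

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["gradient_coeffs"] = list(self.gradient_coeffs)
        payload["interactions"] = {
            f"{gene}|{background}": value
            for (gene, background), value in sorted(self.interactions.items())
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        payload["gradient_coeffs"] = tuple(payload["gradient_coeffs"])
        payload["interactions"] = {
            tuple(key.split("|", 1)): value for key, value in payload["interactions"].items()
        }
        return cls(**payload)


def plate_gradient(
    n_rows: int,
    n_cols: int,
    amplitude: float,
    coeffs: Sequence[float] = DEFAULT_GRADIENT_COEFFS,
) -> np.ndarray:
    """Smooth low-order polynomial plate effect, zero mean, peak-to-peak
    equal to ``amplitude``.

    The shape is a fixed tilted plane plus mild curvature in normalized
    coordinates u = row/(n_rows-1), v = col/(n_cols-1):
    ``c0*u + c1*v + c2*(u-.5)^2 + c3*(u-.5)*(v-.5) + c4*(v-.5)^2``.
    """
    if amplitude == 0.0:
        return np.zeros((n_rows, n_cols))
    u = np.linspace(0.0, 1.0, n_rows)[:, None] if n_rows > 1 else np.zeros((1, 1))
    v = np.linspace(0.0, 1.0, n_cols)[None, :] if n_cols > 1 else np.zeros((1, 1))
    c0, c1, c2, c3, c4 = coeffs
    raw = c0 * u + c1 * v + c2 * (u - 0.5) ** 2 + c3 * (u - 0.5) * (v - 0.5) + c4 * (v - 0.5) ** 2
    raw = np.broadcast_to(raw, (n_rows, n_cols)).astype(float)
    span = raw.max() - raw.min()
    if span == 0.0:
        return np.zeros((n_rows, n_cols))
    g = (raw - raw.mean()) / span * amplitude
    return g


def design_screen_layouts(
    *,
    n_chambers: int = 4,
    n_rows: int = 16,
    n_cols: int = 24,
    n_sample_sirnas: int = 848,
    n_genes: int = 378,
    background: str = "control",
) -> list[PlateLayout]:
    """The screen's spotting design: the library spread over ``n_chambers``
    chambers with interleaved control spots.

    848 library siRNAs target 378 genes (2-3 independent siRNAs per gene,
    assigned round-robin).  Sample spots are distributed evenly over the
    chambers; the remaining spots cycle through the five control siRNAs so
    every chamber carries every control class.  The same spotting is reused
    for every background and replicate, as in a spotted-chamber production
    lot.
    """
    n_spots = n_chambers * n_rows * n_cols
    if n_sample_sirnas > n_spots:
        raise ValueError("library does not fit on the requested chambers")
    sirnas = [
        (f"si{i + 1:04d}", f"GENE{(i % n_genes) + 1:03d}", "sample")
        for i in range(n_sample_sirnas)
    ]
    assignments: list[tuple[str, str | None, str]] = []
    placed = 0
    control_i = 0
    for i in range(n_spots):
        # Bresenham-style interleave: spread the library evenly, fill the
        # rest with cycling controls.
        if placed < n_sample_sirnas and (i * n_sample_sirnas) // n_spots >= placed:
            assignments.append(sirnas[placed])
            placed += 1
        else:
            assignments.append(CONTROL_CYCLE[control_i % len(CONTROL_CYCLE)])
            control_i += 1
    layouts = []
    for chamber in range(n_chambers):
        spots = []
        for j in range(n_rows * n_cols):
            sirna_id, gene, role = assignments[chamber * n_rows * n_cols + j]
            spots.append(
                SpotAssignment(
                    row=j // n_cols,
                    col=j % n_cols,
                    sirna_id=sirna_id,
                    target_gene=gene,
                    control_role=role,
                    background=background,
                )
            )
        layouts.append(
            PlateLayout.from_spots(
                f"C{chamber + 1}", spots, background=background, n_rows=n_rows, n_cols=n_cols
            )
        )
    return layouts


def make_screen_truth(
    seed: int,
    *,
    n_genes: int = 378,
    library_effect_sd: float = 0.0,
    n_planted: int = 0,
    interaction_effect: float = -0.25,
    planted_single_max: float = 0.05,
    positive_control_effect: float = -0.3,
    base_ratio: float = 0.5,
    noise_sd: float = 0.15,
    cells_per_spot_mean: float = 200.0,
    gradient_amplitude: float | None = None,
    backgrounds: Sequence[str] = ("SEC23A", "SEC23B"),
) -> SyntheticTruth:
    """Draw a screen ground truth with planted synergistic pairs.

    The default emulates a titrated screen in which no single knockdown
    moves transport appreciably: unplanted library genes are inert
    (``library_effect_sd = 0``), planted genes carry weak single effects
    (uniform within +/- ``planted_single_max`` ratio units), and only the
    ``n_planted`` (gene, background) pairs carry an ``interaction_effect``
    present in the double knockdown alone.  Background single effects are
    small (-0.02), mirroring conditions chosen such that the suspension
    knockdown alone does not move transport.

    Set ``library_effect_sd`` > 0 to add normal library-wide main-effect
    spread.  Beware: once genes carry persistent single effects beyond the
    strong-effect threshold (in window-MAD units), the additivity-difference
    hit rule loses specificity — see the methods notes on the false-positive
    behavior of the rule under strong-effector libraries.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    if library_effect_sd > 0:
        effects = dict(zip(genes, rng.normal(0.0, library_effect_sd, size=n_genes)))
    else:
        effects = dict.fromkeys(genes, 0.0)
    effects["COPB1"] = positive_control_effect
    effects["COPG1"] = positive_control_effect
    effects["INCENP"] = 0.0
    interactions: dict[tuple[str, str], float] = {}
    if n_planted:
        chosen = rng.choice(n_genes, size=n_planted, replace=False)
        for k, gi in enumerate(chosen):
            gene = genes[int(gi)]
            effects[gene] = float(rng.uniform(-planted_single_max, planted_single_max))
            interactions[(gene, backgrounds[k % len(backgrounds)])] = interaction_effect
    if gradient_amplitude is None:
        gradient_amplitude = 0.2 * base_ratio
    return SyntheticTruth(
        seed=int(seed),
        base_ratio=base_ratio,
        noise_sd=noise_sd,
        cells_per_spot_mean=cells_per_spot_mean,
        gradient_amplitude=gradient_amplitude,
        gene_effects={k: float(v) for k, v in effects.items()},
        background_effects={"control": 0.0, "SEC23A": -0.02, "SEC23B": -0.02},
        interactions=interactions,
    )


def simulate_plate(
    layout: PlateLayout,
    truth: SyntheticTruth,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Per-cell transport-ratio table for one chamber.

    Columns ``row, col, cell_id, ratio, nucleus_count``; join the layout on
    (row, col) for identities.  Cells on transfection-QC spots are
    binucleated with probability ``truth.binucleation_transfected`` (the
    knockdown phenotype), all other cells at the mitotic baseline.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gradient = plate_gradient(
        layout.n_rows, layout.n_cols, truth.gradient_amplitude, truth.gradient_coeffs
    )
    spots = sorted(layout.spots, key=lambda s: (s.row, s.col))
    mus = np.array([truth.spot_mean(s, gradient) for s in spots])
    counts = rng.poisson(truth.cells_per_spot_mean, size=len(spots))
    total = int(counts.sum())
    ratio = np.clip(np.repeat(mus, counts) + rng.normal(0.0, truth.noise_sd, size=total), 0.0, None)
    p_binu = np.array(
        [
            truth.binucleation_transfected
            if s.control_role == "transfection_qc"
            else truth.binucleation_baseline
            for s in spots
        ]
    )
    nucleus_count = 1 + rng.binomial(1, np.repeat(p_binu, counts))
    frame = pd.DataFrame(
        {
            "row": np.repeat([s.row for s in spots], counts).astype(np.int16),
            "col": np.repeat([s.col for s in spots], counts).astype(np.int16),
            "cell_id": np.concatenate([np.arange(n) for n in counts]) if total else np.array([], int),
            "ratio": ratio,
            "nucleus_count": nucleus_count.astype(np.int8),
        }
    )
    frame.attrs["chamber_id"] = layout.chamber_id
    frame.attrs["background"] = layout.background
    return frame


@dataclass(frozen=True)
class PlateSim:
    """One simulated plate of a screen run."""

    background: str
    replicate: int
    layout: PlateLayout
    cells: pd.DataFrame


def simulate_screen(
    truth: SyntheticTruth,
    *,
    layouts: Sequence[PlateLayout] | None = None,
    backgrounds: Sequence[str] = ("control", "SEC23A", "SEC23B"),
    n_replicates: int = 5,
    seed: int | None = None,
) -> Iterator[PlateSim]:
    """Yield every plate of a replicated multi-background screen, lazily.

    Plates are keyed (background, replicate, chamber); per-plate randomness
    derives from ``(seed, background index, replicate, chamber index)`` so a
    rerun with the same seed is bit-identical, and plates are independent.
    """
    if layouts is None:
        layouts = design_screen_layouts()
    if seed is None:
        seed = truth.seed
    for bg_i, background in enumerate(backgrounds):
        for replicate in range(n_replicates):
            for ch_i, layout in enumerate(layouts):
                plate_layout = layout.with_background(background)
                rng = np.random.default_rng([int(seed), bg_i, replicate, ch_i])
                yield PlateSim(
                    background=background,
                    replicate=replicate,
                    layout=plate_layout,
                    cells=simulate_plate(plate_layout, truth, rng),
                )


# ---------------------------------------------------------------------------
# Microscopy simulators
# ---------------------------------------------------------------------------


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: Sequence[int],
    margin: float,
    min_distance: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample ``n`` points at pairwise distance >= min_distance."""
    centers: list[np.ndarray] = []
    lo = np.full(len(shape), margin)
    hi = np.asarray(shape, float) - margin
    if np.any(hi <= lo):
        raise ValueError("margin too large for the requested shape")
    for _ in range(max_tries):
        if len(centers) == n:
            break
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) >= min_distance for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise RuntimeError(f"could not place {n} objects at separation {min_distance}")
    return np.array(centers)


def simulate_cell_field(
    *,
    n_cells: int = 8,
    shape: tuple[int, int] = (256, 256),
    ratios: Sequence[float] | None = None,
    binucleation_fraction: float = 0.0,
    nucleus_radius: float = 8.0,
    cell_radius: float = 28.0,
    offset: float = 20.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> tuple["ChannelField", dict]:
    """A 2D multichannel field with known cells and programmed ratios.

    Channels: ``nucleus`` (stained nuclei), ``total_marker`` (per-cell
    uniform expression level) and ``surface_marker`` (= programmed ratio x
    total, per cell).  A constant camera offset and Gaussian noise are added
    to every channel, so background correction is exercised.  The truth dict
    carries the label masks, per-cell programmed ratios and binucleation
    flags.
    """
    from .imagequant import ChannelField  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    # non-overlapping cell territories: disk centers at > 2 radii
    centers = _place_centers(rng, n_cells, shape, cell_radius * 0.8, cell_radius * 2.15)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist2 = np.stack([(yy - c[0]) ** 2 + (xx - c[1]) ** 2 for c in centers])
    foreground = (dist2 <= cell_radius**2).any(axis=0)
    cell_labels = np.where(foreground, dist2.argmin(axis=0) + 1, 0).astype(np.int32)

    if ratios is None:
        ratios = rng.uniform(0.2, 0.9, size=n_cells)
    ratios = np.asarray(ratios, float)
    if ratios.size != n_cells:
        raise ValueError("need one programmed ratio per cell")
    binucleated = rng.random(n_cells) < binucleation_fraction

    nuc_labels = np.zeros(shape, dtype=np.int32)
    label = 0
    nucleus_of_cell: dict[int, list[int]] = {}
    for i, c in enumerate(centers):
        offsets = (
            [np.array([0.0, 0.0])]
            if not binucleated[i]
            else [np.array([0.0, -1.3 * nucleus_radius]), np.array([0.0, 1.3 * nucleus_radius])]
        )
        nucleus_of_cell[i + 1] = []
        for off in offsets:
            label += 1
            center = c + off
            mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= nucleus_radius**2
            nuc_labels[mask] = label
            nucleus_of_cell[i + 1].append(label)

    levels = rng.uniform(120.0, 220.0, size=n_cells)
    total_clean = np.zeros(shape)
    surface_clean = np.zeros(shape)
    for i in range(n_cells):
        mask = cell_labels == i + 1
        total_clean[mask] = levels[i]
        surface_clean[mask] = levels[i] * ratios[i]

    def _finish(img: np.ndarray) -> np.ndarray:
        img = ndi.gaussian_filter(img, 1.0)
        img = img + offset + rng.normal(0.0, noise_sd, size=shape)
        return np.clip(img, 0.0, None)

    field = ChannelField(
        channels={
            "nucleus": _finish(np.where(nuc_labels > 0, 180.0, 0.0)),
            "total_marker": _finish(total_clean),
            "surface_marker": _finish(surface_clean),
        }
    )
    truth = {
        "cell_labels": cell_labels,
        "nucleus_labels": nuc_labels,
        "centers": centers,
        "ratios": ratios,
        "binucleated": binucleated,
        "nuclei_per_cell": {c: len(v) for c, v in nucleus_of_cell.items()},
        "seed": seed,
    }
    return field, truth


def simulate_spot_stack(
    *,
    n_puncta: int = 10,
    shape: tuple[int, int, int] = (28, 64, 64),
    snr: float = 10.0,
    with_cluster: bool = False,
    sigma: tuple[float, float, float] = (1.2, 1.3, 1.3),
    background_level: float = 20.0,
    read_noise_sd: float = 2.0,
    min_separation: float = 7.0,
    n_cells: int = 1,
    seed: int = 0,
) -> tuple["VolumeStack", dict]:
    """A 3D stack of Gaussian puncta under Poisson + Gaussian read noise.

    SNR is defined as peak punctum amplitude over the background noise sd
    ``sqrt(background_level + read_noise_sd^2)``.  ``with_cluster`` adds one
    large bright Golgi-like blob.  The truth records punctum centers and
    amplitudes, the cluster location, and a simple vertical-strip 2D cell
    mask splitting the field into ``n_cells`` territories.
    """
    from .spot3d import VolumeStack  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    sigma_bg = float(np.sqrt(background_level + read_noise_sd**2))
    amplitude = snr * sigma_bg
    clean = np.full(shape, background_level, dtype=float)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    margin = 5.0
    cluster_center = None
    if with_cluster:
        cluster_center = np.array([shape[0] / 2.0, shape[1] * 0.3, shape[2] * 0.7])
    centers = np.empty((0, 3))
    if n_puncta:
        # keep puncta out of the cluster footprint: a punctum inside the
        # bright Golgi-like region has no recoverable identity of its own
        tries = 0
        kept: list[np.ndarray] = []
        while len(kept) < n_puncta:
            tries += 1
            if tries > 20000:
                raise RuntimeError("could not place puncta away from the cluster")
            cand = rng.uniform(
                np.full(3, margin), np.asarray(shape, float) - margin
            )
            if cluster_center is not None and np.linalg.norm(cand - cluster_center) < 18.0:
                continue
            if all(np.linalg.norm(cand - c) >= min_separation for c in kept):
                kept.append(cand)
        centers = np.array(kept)
        for c in centers:
            clean += amplitude * np.exp(
                -(
                    (zz - c[0]) ** 2 / (2 * sigma[0] ** 2)
                    + (yy - c[1]) ** 2 / (2 * sigma[1] ** 2)
                    + (xx - c[2]) ** 2 / (2 * sigma[2] ** 2)
                )
            )
    if with_cluster:
        # a bright extended blob well away from the borders
        cluster_center = np.array([shape[0] / 2.0, shape[1] * 0.3, shape[2] * 0.7])
        csig = (2.5, 6.0, 6.0)
        clean += 1.5 * amplitude * np.exp(
            -(
                (zz - cluster_center[0]) ** 2 / (2 * csig[0] ** 2)
                + (yy - cluster_center[1]) ** 2 / (2 * csig[1] ** 2)
                + (xx - cluster_center[2]) ** 2 / (2 * csig[2] ** 2)
            )
        )
    noisy = rng.poisson(clean).astype(float) + rng.normal(0.0, read_noise_sd, size=shape)
    noisy = np.clip(noisy, 0.0, None)

    bounds = np.linspace(0, shape[2], n_cells + 1).astype(int)
    cell_mask = np.zeros(shape[1:], dtype=np.int32)
    for i in range(n_cells):
        cell_mask[:, bounds[i] : bounds[i + 1]] = i + 1
    counts = [0] * n_cells
    for c in centers:
        counts[int(cell_mask[int(round(c[1])), int(round(c[2]))]) - 1] += 1

    stack = VolumeStack(channels={"spots": noisy})
    truth = {
        "centers": centers,
        "amplitude": amplitude,
        "snr": snr,
        "background_level": background_level,
        "read_noise_sd": read_noise_sd,
        "cluster_center": cluster_center,
        "cell_mask": cell_mask,
        "counts_per_cell": counts,
        "seed": seed,
    }
    return stack, truth


def simulate_fa_stack(
    *,
    n_adhesions: int = 18,
    shape: tuple[int, int, int] = (9, 192, 192),
    focus_plane: int = 4,
    snr: float = 10.0,
    n_nuclei: int = 4,
    noise_sd: float = 3.0,
    offset: float = 10.0,
    size_scale: float = 1.0,
    seed: int = 0,
) -> tuple["VolumeStack", dict]:
    """A vinculin-like z-stack: in-focus adhesion ellipses in one slice.

    Elongated ellipses are rendered sharp in ``focus_plane``; the other
    slices carry blurred, optically attenuated copies (confocal sectioning
    rejects out-of-focus light), so the normalized variance peaks at the
    designated plane.  ``size_scale`` scales the ellipse axes (e.g. 2x mean
    size for an "enlarged adhesions" condition at sqrt(2)-scaled axes).
    The truth records per-ellipse pixel areas and the nucleus count.
    """
    from .spot3d import VolumeStack  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    if not 0 <= focus_plane < nz:
        raise ValueError("focus_plane outside the stack")
    amplitude = snr * noise_sd
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    sharp = np.zeros((ny, nx))
    areas = []
    params = []
    centers = _place_centers(rng, n_adhesions, (ny, nx), 18.0, 24.0)
    for c in centers:
        a = rng.uniform(8.0, 14.0) * np.sqrt(size_scale)
        b = rng.uniform(3.0, 5.0) * np.sqrt(size_scale)
        theta = rng.uniform(0.0, np.pi)
        dy, dx = yy - c[0], xx - c[1]
        u = dx * np.cos(theta) + dy * np.sin(theta)
        w = -dx * np.sin(theta) + dy * np.cos(theta)
        mask = (u / a) ** 2 + (w / b) ** 2 <= 1.0
        sharp[mask] = amplitude
        areas.append(int(mask.sum()))
        params.append({"center": c.tolist(), "a": a, "b": b, "theta": theta})
    stack = np.empty(shape)
    for z in range(nz):
        dz = abs(z - focus_plane)
        attenuation = float(np.exp(-(dz**2) / (2 * 0.8**2)))
        blur = 0.5 + 2.5 * dz
        stack[z] = ndi.gaussian_filter(sharp * attenuation, blur)
    stack += offset + rng.normal(0.0, noise_sd, size=shape)
    stack = np.clip(stack, 0.0, None)

    nucleus = np.zeros((ny, nx))
    nuc_centers = _place_centers(rng, n_nuclei, (ny, nx), 16.0, 40.0)
    for c in nuc_centers:
        nucleus[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= 10.0**2] = 180.0
    nucleus_stack = np.repeat(
        np.clip(
            ndi.gaussian_filter(nucleus, 1.0) + offset + rng.normal(0.0, noise_sd, size=(ny, nx)),
            0.0,
            None,
        )[None],
        nz,
        axis=0,
    )

    vol = VolumeStack(channels={"vinculin": stack, "nucleus": nucleus_stack})
    truth = {
        "focus_plane": focus_plane,
        "areas": areas,
        "total_area": int(np.sum(sharp > 0)),
        "count": n_adhesions,
        "ellipses": params,
        "n_nuclei": n_nuclei,
        "nucleus_centers": nuc_centers,
        "amplitude": amplitude,
        "seed": seed,
    }
    return vol, truth
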