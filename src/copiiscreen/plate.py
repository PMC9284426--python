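"""Spotted-chamber plate layouts for solid-phase siRNA screens.

A *chamber* is a rectangular grid of dried siRNA spots onto which cells are
plated; each cell landing on a spot takes up that spot's siRNA (reverse
transfection).  The screens this package targets use 384 spots per chamber.
The grid shape is a convention, not a physical constraint: the default is
16 rows x 24 columns, row-major, 0-based.

On top of the spotted grid, a whole chamber can carry a *background*
knockdown: a second siRNA (here SEC23A, SEC23B, or a nontargeting control)
transfected in suspension at plating time, so every spot on the chamber is a
double knockdown of (spot siRNA, background siRNA).  The background is a
chamber-level property and is denormalized onto every spot at load time.

Control roles
-------------
``positive``        siRNAs with a known strong transport phenotype (e.g. COPB1,
                    COPG1 coatomer subunits) used to gate plate quality.
``negative``        nontargeting siRNAs (e.g. Scramble, Neg9); their scores
                    should sit near zero.
``transfection_qc`` an siRNA whose knockdown produces multinucleated cells
                    (e.g. INCENP), read out as a transfection-efficiency proxy.
``sample``          library siRNAs under study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CONTROL_ROLES",
    "BACKGROUNDS",
    "LayoutError",
    "SpotAssignment",
    "PlateLayout",
    "ReplicateSet",
    "DesignReport",
    "load_layout",
    "save_layout",
    "validate_design",
]

CONTROL_ROLES = frozenset({"positive", "negative", "transfection_qc", "sample"})
BACKGROUNDS = frozenset({"SEC23A", "SEC23B", "control"})

_LAYOUT_COLUMNS = ["row", "col", "sirna_id", "target_gene", "control_role", "background"]


class LayoutError(ValueError):
    """Raised when a layout file or in-memory layout violates an invariant."""


@dataclass(frozen=True)
class SpotAssignment:
    """One spot of a spotted chamber: grid position plus siRNA identity."""

    row: int
    col: int
    sirna_id: str
    target_gene: str | None = None
    control_role: str = "sample"
    background: str = "control"

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise LayoutError(f"spot coordinates must be non-negative, got ({self.row}, {self.col})")
        if self.control_role not in CONTROL_ROLES:
            raise LayoutError(
                f"unknown control_role {self.control_role!r}; expected one of {sorted(CONTROL_ROLES)}"
            )
        if self.background not in BACKGROUNDS:
            raise LayoutError(
                f"unknown background {self.background!r}; expected one of {sorted(BACKGROUNDS)}"
            )
        # Negative controls are by definition nontargeting; positive and
        # transfection-QC controls do target a gene (their control identity).
        if self.control_role == "negative" and self.target_gene not in (None, ""):
            raise LayoutError(
                f"negative control spot ({self.row}, {self.col}) must not carry a target gene"
            )


@dataclass(frozen=True)
class PlateLayout:
    """A full chamber grid: ``n_rows * n_cols`` spots, unique coordinates."""

    chamber_id: str
    n_rows: int
    n_cols: int
    background: str
    spots: tuple[SpotAssignment, ...]
    _index: Mapping[tuple[int, int], SpotAssignment] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise LayoutError(f"unknown background {self.background!r}")
        if len(self.spots) != self.n_rows * self.n_cols:
            raise LayoutError(
                f"chamber {self.chamber_id}: {len(self.spots)} spots for a "
                f"{self.n_rows}x{self.n_cols} grid (expected {self.n_rows * self.n_cols})"
            )
        index: dict[tuple[int, int], SpotAssignment] = {}
        for spot in self.spots:
            if spot.row >= self.n_rows or spot.col >= self.n_cols:
                raise LayoutError(
                    f"chamber {self.chamber_id}: spot ({spot.row}, {spot.col}) outside "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
            if (spot.row, spot.col) in index:
                raise LayoutError(
                    f"chamber {self.chamber_id}: duplicate spot coordinate ({spot.row}, {spot.col})"
                )
            if spot.background != self.background:
                raise LayoutError(
                    f"chamber {self.chamber_id}: spot ({spot.row}, {spot.col}) background "
                    f"{spot.background!r} != chamber background {self.background!r}"
                )
            index[(spot.row, spot.col)] = spot
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_spots(
        cls,
        chamber_id: str,
        spots: Iterable[SpotAssignment],
        *,
        background: str = "control",
        n_rows: int | None = None,
        n_cols: int | None = None,
    ) -> "PlateLayout":
        """Build a layout, denormalizing the chamber background onto spots.

        Grid dimensions default to ``max coordinate + 1``.
        """
        spots = tuple(replace(s, background=background) for s in spots)
        if not spots:
            raise LayoutError(f"chamber {chamber_id}: no spots")
        if n_rows is None:
            n_rows = max(s.row for s in spots) + 1
        if n_cols is None:
            n_cols = max(s.col for s in spots) + 1
        return cls(chamber_id, n_rows, n_cols, background, spots)

    def spot_at(self, row: int, col: int) -> SpotAssignment:
        return self._index[(row, col)]

    def get(self, row: int, col: int) -> SpotAssignment | None:
        return self._index.get((row, col))

    def with_background(self, background: str) -> "PlateLayout":
        """The same spotting run on a chamber with a different suspension siRNA."""
        spots = tuple(replace(s, background=background) for s in self.spots)
        return PlateLayout(self.chamber_id, self.n_rows, self.n_cols, background, spots)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "row": s.row,
                "col": s.col,
                "sirna_id": s.sirna_id,
                "target_gene": s.target_gene if s.target_gene is not None else "",
                "control_role": s.control_role,
                "background": s.background,
            }
            for s in sorted(self.spots, key=lambda s: (s.row, s.col))
        ]
        return pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)

    def save(self, path: str | Path) -> Path:
        return save_layout(self, path)


@dataclass(frozen=True)
class ReplicateSet:
    """Transport scores of one (siRNA, background) condition across replicates.

    Aggregation (the median score) is defined only for >= 3 biological
    replicates; fewer replicates exclude the condition from hit calling.
    """

    condition_key: tuple[str, str]
    replicate_scores: tuple[float, ...]

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_scores)


def save_layout(layout: PlateLayout, path: str | Path) -> Path:
    """Write a layout as CSV (flat table) or JSON (nested), chosen by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "chamber_id": layout.chamber_id,
            "n_rows": layout.n_rows,
            "n_cols": layout.n_cols,
            "background": layout.background,
            "spots": layout.to_frame().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        frame = layout.to_frame()
        frame.insert(0, "chamber_id", layout.chamber_id)
        frame.to_csv(path, index=False)
    return path


def _layout_from_frame(frame: pd.DataFrame, chamber_id: str, source: str) -> PlateLayout:
    missing = [c for c in ("row", "col", "sirna_id") if c not in frame.columns]
    if missing:
        raise LayoutError(f"{source}: missing required columns {missing}")
    backgrounds = (
        set(frame["background"].astype(str)) if "background" in frame.columns else {"control"}
    )
    if len(backgrounds) != 1:
        raise LayoutError(f"{source}: background must be constant per chamber, got {sorted(backgrounds)}")
    background = backgrounds.pop()
    try:
        spots = []
        for rec in frame.to_dict(orient="records"):
            gene = rec.get("target_gene")
            if gene is None or (isinstance(gene, float) and pd.isna(gene)) or gene == "":
                gene = None
            spots.append(
                SpotAssignment(
                    row=int(rec["row"]),
                    col=int(rec["col"]),
                    sirna_id=str(rec["sirna_id"]),
                    target_gene=None if gene is None else str(gene),
                    control_role=str(rec.get("control_role", "sample")),
                    background=background,
                )
            )
    except (TypeError, ValueError) as exc:
        raise LayoutError(f"{source}: could not parse spot table: {exc}") from exc
    return PlateLayout.from_spots(chamber_id, spots, background=background)


def load_layout(path: str | Path, dialect: str | None = None) -> PlateLayout:
    """Load a chamber layout from CSV or JSON.

    The CSV dialect is a flat table with header columns
    ``chamber_id,row,col,sirna_id,target_gene,control_role,background``
    (``chamber_id`` optional, defaulting to the file stem).  The JSON dialect
    mirrors it with chamber metadata at the top level.  Row/col are 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise LayoutError(f"layout file not found: {path}")
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise LayoutError(f"{path}: invalid JSON layout: {exc}") from exc
        frame = pd.DataFrame(payload.get("spots", []))
        if frame.empty:
            raise LayoutError(f"{path}: JSON layout has no spots")
        if "background" not in frame.columns:
            frame["background"] = payload.get("background", "control")
        layout = _layout_from_frame(frame, str(payload.get("chamber_id", path.stem)), str(path))
        declared = (payload.get("n_rows"), payload.get("n_cols"))
        if declared != (None, None) and declared != (layout.n_rows, layout.n_cols):
            raise LayoutError(
                f"{path}: declared grid {declared} does not match spots "
                f"({layout.n_rows}, {layout.n_cols})"
            )
        return layout
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise LayoutError(f"{path}: empty layout file") from exc
    if frame.empty:
        raise LayoutError(f"{path}: layout table has no rows")
    if "chamber_id" in frame.columns:
        ids = set(frame["chamber_id"].astype(str))
        if len(ids) != 1:
            raise LayoutError(f"{path}: expected a single chamber per file, got {sorted(ids)}")
        chamber_id = ids.pop()
        frame = frame.drop(columns=["chamber_id"])
    else:
        chamber_id = path.stem
    return _layout_from_frame(frame, chamber_id, str(path))


@dataclass(frozen=True)
class DesignReport:
    """Per-chamber control coverage of a screen design (report-only)."""

    per_chamber: pd.DataFrame
    n_unique_sample_sirnas: int
    flagged_chambers: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flagged_chambers


def validate_design(layouts: Sequence[PlateLayout]) -> DesignReport:
    """Count control classes per chamber and flag chambers missing any class.

    A usable chamber carries positive, negative and transfection-QC controls
    alongside the sample spots; a chamber lacking any class cannot be
    quality-controlled and is flagged (reported, never raised).
    """
    if not layouts:
        raise LayoutError("validate_design requires at least one layout")
    records = []
    flagged = []
    sample_ids: set[str] = set()
    for layout in layouts:
        counts = {role: 0 for role in CONTROL_ROLES}
        for spot in layout.spots:
            counts[spot.control_role] += 1
            if spot.control_role == "sample":
                sample_ids.add(spot.sirna_id)
        missing = sorted(
            role for role in ("positive", "negative", "transfection_qc") if counts[role] == 0
        )
        if missing:
            flagged.append(layout.chamber_id)
        records.append(
            {
                "chamber_id": layout.chamber_id,
                "background": layout.background,
                "n_spots": len(layout.spots),
                "n_sample": counts["sample"],
                "n_positive": counts["positive"],
                "n_negative": counts["negative"],
                "n_transfection_qc": counts["transfection_qc"],
                "missing_classes": ";".join(missing),
            }
        )
    return DesignReport(
        per_chamber=pd.DataFrame(records),
        n_unique_sample_sirnas=len(sample_ids),
        flagged_chambers=tuple(flagged),
    )
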