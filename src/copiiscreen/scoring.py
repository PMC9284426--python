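"""The screen statistic: spatially normalized transport scores.

Per spot, the readout is xi, the mean per-cell transport ratio (surface
marker intensity / total marker intensity).  To make spots comparable across
chambers and replicates and to remove smooth plate effects (illumination,
cell-density and edge gradients), xi is normalized against its local
neighborhood on the plate grid:

    score = (xi - X) / MAD

where X is the median of the transport ratios in the 5x5 window of spots
centered on the spot of interest (25 values on a full interior window, the
center included) and MAD is the median absolute deviation of the same window,
*without* the 1.4826 normal-consistency constant.  Negative scores mean
transport inhibition, positive scores acceleration.

Because the statistic is self-normalizing, it is invariant under affine
rescaling of the ratios (r -> a*r + b, a > 0): the score is a pure,
unit-free local effect size.

Edge handling truncates the window at the plate border (no mirroring — that
would fabricate data) and a minimum-window guard flags spots whose window
retains too few values to estimate a robust spread.  A window with MAD = 0 is
flagged degenerate, never returned as an infinite score.

The module also carries the replicate-aggregation rule (median score over
>= 3 biological replicates), plate quality control from control spots, and
the 2^-ddCt fold-change utility used for the qPCR follow-ups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate import PlateLayout, ReplicateSet, SpotAssignment

__all__ = [
    "FLAG_OK",
    "FLAG_LOW_CELLS",
    "FLAG_WINDOW",
    "FLAG_DEGENERATE",
    "SpotRatio",
    "WindowValues",
    "ScoreResult",
    "SpotScore",
    "QCThresholds",
    "PlateQCReport",
    "spot_ratio",
    "neighborhood_window",
    "transport_score",
    "score_plate",
    "plate_qc",
    "aggregate_replicates",
    "aggregate_replicate_sets",
    "ddct_fold_change",
]

FLAG_OK = ""
FLAG_LOW_CELLS = "low_cell_count"
FLAG_WINDOW = "insufficient_window"
FLAG_DEGENERATE = "degenerate_mad"

DEFAULT_MIN_CELLS = 20
DEFAULT_MIN_WINDOW = 12
WINDOW_HALF = 2  # 5x5 window


@dataclass(frozen=True)
class SpotRatio:
    """Per-spot summary of the per-cell transport ratios."""

    xi: float
    n_cells: int
    flag: str = FLAG_OK

    @property
    def ok(self) -> bool:
        return self.flag == FLAG_OK


@dataclass(frozen=True)
class WindowValues:
    """The xi values of a (possibly truncated) plate-grid window."""

    values: np.ndarray
    flag: str = FLAG_OK

    @property
    def ok(self) -> bool:
        return self.flag == FLAG_OK


@dataclass(frozen=True)
class ScoreResult:
    """Window median X, window MAD and the normalized transport score."""

    center: float
    mad: float
    score: float
    flag: str = FLAG_OK

    @property
    def ok(self) -> bool:
        return self.flag == FLAG_OK


@dataclass(frozen=True)
class SpotScore:
    """One scored spot: assignment, xi, window statistics, flags."""

    spot: SpotAssignment
    xi: float
    n_cells: int
    window_values: np.ndarray
    center: float
    mad: float
    score: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return not self.flags


def spot_ratio(
    ratios: Iterable[float],
    min_cells: int = DEFAULT_MIN_CELLS,
) -> SpotRatio:
    """Mean per-cell transport ratio of one spot.

    Non-finite ratios (cells flagged for zero total intensity) are excluded.
    A spot with fewer valid cells than ``min_cells`` is flagged
    ``low_cell_count`` and takes no part in scoring.
    """
    arr = np.asarray(list(ratios) if not isinstance(ratios, np.ndarray) else ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_cells:
        return SpotRatio(xi=math.nan, n_cells=int(arr.size), flag=FLAG_LOW_CELLS)
    return SpotRatio(xi=float(arr.mean()), n_cells=int(arr.size))


def neighborhood_window(
    layout: PlateLayout,
    spot: SpotAssignment,
    xi_map: Mapping[tuple[int, int], float],
    *,
    half: int = WINDOW_HALF,
    include_center: bool = True,
    exclude_controls: bool = False,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> WindowValues:
    """xi values of the (2*half+1)^2 grid window centered on ``spot``.

    The window is truncated at plate edges; spots missing from ``xi_map``
    (failed QC, no ratio) are omitted.  If fewer than ``min_window`` values
    remain the window is flagged ``insufficient_window``.  ``exclude_controls``
    drops non-sample spots from the window (off by default: the median
    tolerates sparse control outliers, and dropping them thins edge windows).
    """
    values = []
    for r in range(spot.row - half, spot.row + half + 1):
        for c in range(spot.col - half, spot.col + half + 1):
            if not (0 <= r < layout.n_rows and 0 <= c < layout.n_cols):
                continue
            if (r, c) == (spot.row, spot.col) and not include_center:
                continue
            if exclude_controls and (r, c) != (spot.row, spot.col):
                other = layout.get(r, c)
                if other is not None and other.control_role != "sample":
                    continue
            v = xi_map.get((r, c))
            if v is not None and np.isfinite(v):
                values.append(float(v))
    arr = np.asarray(values, dtype=float)
    flag = FLAG_OK if arr.size >= min_window else FLAG_WINDOW
    return WindowValues(values=arr, flag=flag)


def transport_score(xi: float, window_values: np.ndarray | Sequence[float]) -> ScoreResult:
    """Normalize one spot's xi against its window: (xi - median) / MAD.

    MAD carries no consistency constant.  MAD = 0 (all window values equal)
    is signaled with the ``degenerate_mad`` flag and a NaN score.
    """
    w = np.asarray(window_values, dtype=float)
    if w.size == 0 or not np.isfinite(xi):
        return ScoreResult(center=math.nan, mad=math.nan, score=math.nan, flag=FLAG_WINDOW)
    center = float(np.median(w))
    mad = float(np.median(np.abs(w - center)))
    if mad == 0.0:
        return ScoreResult(center=center, mad=0.0, score=math.nan, flag=FLAG_DEGENERATE)
    return ScoreResult(center=center, mad=mad, score=(float(xi) - center) / mad)


def score_plate(
    layout: PlateLayout,
    spot_table: pd.DataFrame,
    *,
    half: int = WINDOW_HALF,
    min_window: int = DEFAULT_MIN_WINDOW,
    include_center: bool = True,
    exclude_controls: bool = False,
) -> pd.DataFrame:
    """Score every spot of a chamber.

    ``spot_table`` carries one row per spot with columns ``row``, ``col``,
    ``xi`` and ``n_cells`` (optionally ``flag`` from :func:`spot_ratio`).
    Returns one row per spot of the layout with columns::

        chamber_id,row,col,sirna_id,target_gene,control_role,background,
        xi,n_cells,window_n,window_median,window_mad,score,flags

    Spots without a valid xi, with a thin window or a degenerate MAD get a
    NaN score and a semicolon-joined ``flags`` string.  The computation is
    deterministic given its inputs.
    """
    required = {"row", "col", "xi", "n_cells"}
    missing = required - set(spot_table.columns)
    if missing:
        raise ValueError(f"spot_table missing columns {sorted(missing)}")
    xi_map: dict[tuple[int, int], float] = {}
    info: dict[tuple[int, int], tuple[float, int, str]] = {}
    for rec in spot_table.to_dict(orient="records"):
        key = (int(rec["row"]), int(rec["col"]))
        flag = str(rec.get("flag", "") or "")
        xi = float(rec["xi"])
        info[key] = (xi, int(rec["n_cells"]), flag)
        if flag == FLAG_OK and np.isfinite(xi):
            xi_map[key] = xi
    rows = []
    for spot in sorted(layout.spots, key=lambda s: (s.row, s.col)):
        key = (spot.row, spot.col)
        xi, n_cells, flag = info.get(key, (math.nan, 0, FLAG_LOW_CELLS))
        flags = [flag] if flag else []
        if flags or not np.isfinite(xi):
            window_n, center, mad, score = 0, math.nan, math.nan, math.nan
            if not flags:
                flags = [FLAG_LOW_CELLS]
        else:
            window = neighborhood_window(
                layout,
                spot,
                xi_map,
                half=half,
                include_center=include_center,
                exclude_controls=exclude_controls,
                min_window=min_window,
            )
            window_n = int(window.values.size)
            if not window.ok:
                center, mad, score = math.nan, math.nan, math.nan
                flags.append(window.flag)
            else:
                res = transport_score(xi, window.values)
                center, mad, score = res.center, res.mad, res.score
                if not res.ok:
                    flags.append(res.flag)
        rows.append(
            {
                "chamber_id": layout.chamber_id,
                "row": spot.row,
                "col": spot.col,
                "sirna_id": spot.sirna_id,
                "target_gene": spot.target_gene if spot.target_gene is not None else "",
                "control_role": spot.control_role,
                "background": spot.background,
                "xi": xi,
                "n_cells": n_cells,
                "window_n": window_n,
                "window_median": center,
                "window_mad": mad,
                "score": score,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QCThresholds:
    """Numeric plate-QC conventions (the underlying criteria are qualitative:
    positive controls strongly inhibited, negatives near zero, transfection
    working).

    ``negative_rule`` is ``"median"`` (the median signed negative-control
    score sits within ``negative_abs_max`` of zero — a drift/bias check,
    robust to single noisy spots) or ``"max"`` (every individual negative
    score within the bound — far stricter, since individual windowed scores
    of null spots are unit-scale by construction).
    """

    positive_max_score: float = -1.5
    negative_abs_max: float = 0.5
    negative_rule: str = "median"
    min_transfection_fraction: float = 0.5


@dataclass(frozen=True)
class PlateQCReport:
    chamber_id: str
    positive_control_scores: tuple[float, ...]
    negative_control_scores: tuple[float, ...]
    transfection_fraction: float | None
    passed: bool
    reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "chamber_id": self.chamber_id,
            "positive_control_scores": list(self.positive_control_scores),
            "negative_control_scores": list(self.negative_control_scores),
            "transfection_fraction": self.transfection_fraction,
            "passed": self.passed,
            "reasons": list(self.reasons),
        }


def plate_qc(
    scores: pd.DataFrame,
    *,
    thresholds: QCThresholds = QCThresholds(),
    transfection_fraction: float | None = None,
) -> PlateQCReport:
    """Pass/fail a scored chamber on its control spots.

    Criteria: the median positive-control score is at or below
    ``positive_max_score`` (strong inhibition); negative-control scores sit
    within ``negative_abs_max`` of zero (rule per ``negative_rule``); and, if
    a multinucleation readout is supplied, the transfection fraction reaches
    ``min_transfection_fraction``.  A chamber lacking a control class fails
    with an explicit reason.
    """
    chamber_id = str(scores["chamber_id"].iloc[0]) if len(scores) else "?"
    pos = scores.loc[scores["control_role"] == "positive", "score"].to_numpy(dtype=float)
    neg = scores.loc[scores["control_role"] == "negative", "score"].to_numpy(dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    reasons: list[str] = []
    if pos.size == 0:
        reasons.append("no_positive_controls")
    elif float(np.median(pos)) > thresholds.positive_max_score:
        reasons.append("weak_positive_controls")
    if neg.size == 0:
        reasons.append("no_negative_controls")
    else:
        stat = (
            abs(float(np.median(neg)))
            if thresholds.negative_rule == "median"
            else float(np.abs(neg).max())
        )
        if stat > thresholds.negative_abs_max:
            reasons.append("drifting_negative_controls")
    if transfection_fraction is not None:
        if not np.isfinite(transfection_fraction):
            reasons.append("transfection_fraction_missing")
        elif transfection_fraction < thresholds.min_transfection_fraction:
            reasons.append("low_transfection")
    return PlateQCReport(
        chamber_id=chamber_id,
        positive_control_scores=tuple(float(v) for v in pos),
        negative_control_scores=tuple(float(v) for v in neg),
        transfection_fraction=(
            float(transfection_fraction) if transfection_fraction is not None else None
        ),
        passed=not reasons,
        reasons=tuple(reasons),
    )


def aggregate_replicates(
    scores: pd.DataFrame,
    *,
    by: Sequence[str] = ("sirna_id", "background"),
    score_col: str = "score",
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Median transport score per condition over biological replicates.

    One input row per (condition, replicate) spot score; NaN scores are
    dropped first.  Conditions observed in fewer than ``min_replicates``
    replicates are retained in the output with ``included = False`` and the
    exclusion reason, so downstream bookkeeping can list them.
    """
    by = list(by)
    valid = scores[np.isfinite(scores[score_col].to_numpy(dtype=float))]
    keep_cols = [c for c in ("target_gene", "control_role") if c in scores.columns]
    grouped = valid.groupby(by, sort=True)
    out = grouped[score_col].agg(median_score="median", n_replicates="size").reset_index()
    if keep_cols:
        extra = valid.groupby(by, sort=True)[keep_cols].first().reset_index(drop=True)
        out = pd.concat([out, extra], axis=1)
    out["included"] = out["n_replicates"] >= min_replicates
    out["reason"] = np.where(out["included"], "", "insufficient_replicates")
    out.loc[~out["included"], "median_score"] = np.nan
    return out


def aggregate_replicate_sets(
    sets: Iterable[ReplicateSet], *, min_replicates: int = 3
) -> pd.DataFrame:
    """`aggregate_replicates` over in-memory :class:`ReplicateSet` objects."""
    rows = [
        {
            "sirna_id": s.condition_key[0],
            "background": s.condition_key[1],
            "score": v,
        }
        for s in sets
        for v in s.replicate_scores
    ]
    return aggregate_replicates(pd.DataFrame(rows), min_replicates=min_replicates)


def ddct_fold_change(
    ct_target_treated: float,
    ct_hk_treated: float,
    ct_target_control: float,
    ct_hk_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(housekeeping) within each condition;
    ddCt = dCt(treated) - dCt(control); fold change = 2^-ddCt.
    A fold change of 1 means no change, 0.5 a halving, 2 a doubling.
    """
    cts = [ct_target_treated, ct_hk_treated, ct_target_control, ct_hk_control]
    if not all(math.isfinite(float(c)) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (float(ct_target_treated) - float(ct_hk_treated)) - (
        float(ct_target_control) - float(ct_hk_control)
    )
    return float(2.0 ** (-ddct))
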