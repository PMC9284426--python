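"""End-to-end screen and imaging orchestration with exclusion bookkeeping.

A screen analysis lives or dies by its bookkeeping: which plates failed
quality control, which spots had too few cells, which conditions missed the
replicate rule.  ``run_screen`` therefore writes, next to its result
tables, a JSON-lines log with one machine-readable record per exclusion,
and serializes the exact configuration and seed needed to regenerate the
output directory.

Pipeline: per-cell ratios -> per-spot xi -> windowed transport scores ->
plate QC (failed plates drop out of aggregation) -> median score per
(siRNA, background) over >= 3 replicates -> synergy hit calling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .adhesion import quantify_adhesions
from .adhesion import condition_summary as fa_condition_summary
from .hits import call_hits, rank_hits
from .imagequant import CellRecord, rush_transport_index
from .plate import PlateLayout, load_layout
from .scoring import (
    DEFAULT_MIN_CELLS,
    DEFAULT_MIN_WINDOW,
    QCThresholds,
    aggregate_replicates,
    plate_qc,
    score_plate,
    spot_ratio,
)
from .simulate import (
    SyntheticTruth,
    design_screen_layouts,
    make_screen_truth,
    simulate_fa_stack,
    simulate_screen,
    simulate_spot_stack,
)
from .spot3d import (
    auto_seed_threshold,
    condition_summary as spot_condition_summary,
    detect_seeds,
    exclude_large_clusters,
    per_cell_spot_stats,
    preprocess_stack,
    segment_spots,
)

__all__ = [
    "RunConfig",
    "ScreenSimConfig",
    "ConfigError",
    "run_screen",
    "run_imaging",
    "spot_table_from_cells",
    "transfection_fraction_from_cells",
]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


def _from_dict(cls, payload: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Synthetic-screen block of a run configuration."""

    n_replicates: int = 5
    n_chambers: int = 4
    n_rows: int = 16
    n_cols: int = 24
    n_sample_sirnas: int = 848
    n_genes: int = 378
    n_planted: int = 0
    interaction_effect: float = -0.25
    backgrounds: tuple[str, ...] = ("control", "SEC23A", "SEC23B")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; serialized verbatim into the output directory."""

    out_dir: str
    seed: int = 0
    simulate: ScreenSimConfig | None = None
    layout_paths: tuple[str, ...] = ()
    cell_table_paths: tuple[str, ...] = ()
    min_cells: int = DEFAULT_MIN_CELLS
    min_window: int = DEFAULT_MIN_WINDOW
    qc: QCThresholds = field(default_factory=QCThresholds)
    min_replicates: int = 3
    min_difference: float = 1.0
    signed_difference: bool = False
    inhibit_threshold: float = -1.5
    accelerate_threshold: float = 1.5

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "simulate" in payload and payload["simulate"] is not None:
            payload["simulate"] = _from_dict(ScreenSimConfig, dict(payload["simulate"]))
            if isinstance(payload["simulate"].backgrounds, list):
                payload["simulate"] = dataclasses.replace(
                    payload["simulate"], backgrounds=tuple(payload["simulate"].backgrounds)
                )
        if "qc" in payload and payload["qc"] is not None and not isinstance(payload["qc"], QCThresholds):
            payload["qc"] = _from_dict(QCThresholds, dict(payload["qc"]))
        for key in ("layout_paths", "cell_table_paths"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return _from_dict(cls, payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON config: {exc}") from exc
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload


class _RunLog:
    """JSON-lines event log; every exclusion gets a machine-readable record."""

    def __init__(self, path: Path):
        self.path = path
        self._fh = path.open("w")

    def event(self, kind: str, **fields) -> None:
        self._fh.write(json.dumps({"event": kind, **fields}, sort_keys=True) + "\n")

    def close(self) -> None:
        self._fh.close()


def spot_table_from_cells(cells: pd.DataFrame, *, min_cells: int = DEFAULT_MIN_CELLS) -> pd.DataFrame:
    """Per-spot xi table (row, col, xi, n_cells, flag) from a per-cell table."""
    rows = []
    for (row, col), group in cells.groupby(["row", "col"], sort=True):
        sr = spot_ratio(group["ratio"].to_numpy(), min_cells=min_cells)
        rows.append({"row": row, "col": col, "xi": sr.xi, "n_cells": sr.n_cells, "flag": sr.flag})
    return pd.DataFrame(rows)


def transfection_fraction_from_cells(cells: pd.DataFrame, layout: PlateLayout) -> float:
    """Fraction of multinucleated cells on the transfection-QC spots."""
    qc_coords = {
        (s.row, s.col) for s in layout.spots if s.control_role == "transfection_qc"
    }
    if not qc_coords or "nucleus_count" not in cells.columns:
        return float("nan")
    mask = [
        (r, c) in qc_coords
        for r, c in zip(cells["row"].to_numpy(), cells["col"].to_numpy())
    ]
    sub = cells.loc[mask, "nucleus_count"]
    if len(sub) == 0:
        return float("nan")
    return float((sub >= 2).mean())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _iter_plates(config: RunConfig, truth: SyntheticTruth | None):
    """Yield (background, replicate, layout, cells) from simulation or files."""
    if config.simulate is not None:
        sim = config.simulate
        layouts = design_screen_layouts(
            n_chambers=sim.n_chambers,
            n_rows=sim.n_rows,
            n_cols=sim.n_cols,
            n_sample_sirnas=sim.n_sample_sirnas,
            n_genes=sim.n_genes,
        )
        for plate in simulate_screen(
            truth,
            layouts=layouts,
            backgrounds=sim.backgrounds,
            n_replicates=sim.n_replicates,
            seed=config.seed,
        ):
            yield plate.background, plate.replicate, plate.layout, plate.cells
        return
    if not config.layout_paths or not config.cell_table_paths:
        raise ConfigError("run_screen needs either a simulate block or input paths")
    layouts = {Path(p).stem: load_layout(p) for p in config.layout_paths}
    for path in config.cell_table_paths:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"cell table not found: {path}")
        cells = pd.read_csv(path)
        required = {"chamber_id", "background", "replicate", "row", "col", "ratio"}
        missing = required - set(cells.columns)
        if missing:
            raise ConfigError(f"{path}: cell table missing columns {sorted(missing)}")
        for (chamber, background, replicate), group in cells.groupby(
            ["chamber_id", "background", "replicate"], sort=True
        ):
            if chamber not in layouts:
                raise ConfigError(f"{path}: no layout named {chamber!r} among layout_paths")
            yield str(background), int(replicate), layouts[chamber].with_background(
                str(background)
            ), group


def run_screen(config: RunConfig, *, truth: SyntheticTruth | None = None) -> Path:
    """Run the full screen pipeline into ``config.out_dir``.

    Writes ``spot_scores.csv`` (every scored spot of every plate),
    ``plate_qc.json``, ``gene_scores.csv`` (replicate-aggregated),
    ``hits.csv`` (ranked synergy hits), ``calls.csv`` (every call),
    ``config.json``, ``manifest.json`` and ``log.jsonl``.  Plates failing QC
    are excluded from aggregation and listed; the run is deterministic given
    config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "log.jsonl")
    if config.simulate is not None and truth is None:
        truth = make_screen_truth(
            config.seed,
            n_genes=config.simulate.n_genes,
            n_planted=config.simulate.n_planted,
            interaction_effect=config.simulate.interaction_effect,
            backgrounds=tuple(b for b in config.simulate.backgrounds if b != "control"),
        )
    if truth is not None:
        truth.to_json(out / "truth.json")

    all_scores = []
    qc_reports = []
    n_plates = 0
    for background, replicate, layout, cells in _iter_plates(config, truth):
        n_plates += 1
        spot_table = spot_table_from_cells(cells, min_cells=config.min_cells)
        scores = score_plate(layout, spot_table, min_window=config.min_window)
        tf = transfection_fraction_from_cells(cells, layout)
        report = plate_qc(
            scores,
            thresholds=config.qc,
            transfection_fraction=tf if np.isfinite(tf) else None,
        )
        scores.insert(0, "replicate", replicate)
        scores.insert(0, "plate_passed_qc", report.passed)
        qc_reports.append(
            {"background": background, "replicate": replicate, **report.to_dict()}
        )
        if report.passed:
            all_scores.append(scores)
        else:
            log.event(
                "plate_excluded",
                chamber_id=layout.chamber_id,
                background=background,
                replicate=replicate,
                reasons=list(report.reasons),
            )
        log.event(
            "plate_scored",
            chamber_id=layout.chamber_id,
            background=background,
            replicate=replicate,
            passed=report.passed,
            n_flagged_spots=int((scores["flags"] != "").sum()),
        )
    if not all_scores:
        log.close()
        raise ConfigError("no plates passed quality control; nothing to aggregate")
    scores = pd.concat(all_scores, ignore_index=True)
    scores.to_csv(out / "spot_scores.csv", index=False)
    (out / "plate_qc.json").write_text(json.dumps(qc_reports, indent=1, sort_keys=True))

    sample_scores = scores[scores["control_role"] == "sample"]
    gene_scores = aggregate_replicates(sample_scores, min_replicates=config.min_replicates)
    for _, r in gene_scores[~gene_scores["included"]].iterrows():
        log.event(
            "condition_excluded",
            sirna_id=str(r["sirna_id"]),
            background=str(r["background"]),
            n_replicates=int(r["n_replicates"]),
            reason=str(r["reason"]),
        )
    gene_scores.to_csv(out / "gene_scores.csv", index=False)

    # The suspension (background) siRNA covers the whole chamber, so the
    # windowed score cannot see its main effect within a plate; its single
    # score is read from the nontargeting spots on that background's plates.
    backgrounds = sorted(b for b in scores["background"].unique() if b != "control")
    single_bg = {}
    for b in backgrounds:
        neg = scores[(scores["background"] == b) & (scores["control_role"] == "negative")]
        vals = neg["score"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        single_bg[b] = float(np.median(vals)) if vals.size else float("nan")
    calls = call_hits(
        gene_scores,
        single_bg,
        min_difference=config.min_difference,
        signed=config.signed_difference,
        inhibit_threshold=config.inhibit_threshold,
        accelerate_threshold=config.accelerate_threshold,
    )
    rank_hits(calls, hits_only=False).to_csv(out / "calls.csv", index=False)
    hit_table = rank_hits(calls, hits_only=True)
    hit_table.to_csv(out / "hits.csv", index=False)
    log.event("hits_called", n_conditions=len(calls), n_hits=int(len(hit_table)))

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_plates": n_plates,
        "inputs": {
            str(p): _sha256(Path(p))
            for p in (*config.layout_paths, *config.cell_table_paths)
            if Path(p).exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.close()
    return out


def run_imaging(
    config: RunConfig,
    mode: str,
    *,
    conditions: dict | None = None,
) -> Path:
    """Imaging subpipelines on synthetic stacks: ``spots3d``, ``adhesions``
    or ``rush``.

    ``conditions`` maps a condition name to simulator keyword arguments
    (e.g. ``{"control": {"n_puncta": 10}, "kd": {"n_puncta": 4}}``); each
    condition is simulated ``n_images`` times (default 3) and quantified,
    with the per-condition minimum-cell guards applied (100 cells for
    puncta, 50 for adhesions).  Results land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "log.jsonl")
    if conditions is None:
        conditions = {"control": {}}
    summaries = {}
    if mode == "spots3d":
        for ci, (name, kwargs) in enumerate(sorted(conditions.items())):
            kwargs = dict(kwargs)
            n_images = int(kwargs.pop("n_images", 3))
            tables = []
            for i in range(n_images):
                stack, _ = simulate_spot_stack(seed=int(config.seed) * 1000 + ci * 100 + i, **kwargs)
                vol = stack["spots"]
                filtered = preprocess_stack(vol)
                threshold = auto_seed_threshold(vol)
                seeds = detect_seeds(filtered, min_seed_intensity=threshold)
                labels = segment_spots(filtered, seeds, min_seed_intensity=threshold)
                labels, _ = exclude_large_clusters(labels, filtered)
                stats = per_cell_spot_stats(labels, np.ones(vol.shape[1:], dtype=np.int32), vol)
                table = stats.per_cell.assign(condition=name, image=i)
                tables.append(table)
            pooled = pd.concat(tables, ignore_index=True)
            pooled.to_csv(out / f"spots_{name}.csv", index=False)
            summary = spot_condition_summary(tables, min_cells=100)
            summaries[name] = summary
            if not summary["ok"]:
                log.event("condition_flagged", condition=name, reason="too_few_cells", **{
                    k: summary[k] for k in ("n_cells", "min_cells")
                })
    elif mode == "adhesions":
        for ci, (name, kwargs) in enumerate(sorted(conditions.items())):
            kwargs = dict(kwargs)
            n_images = int(kwargs.pop("n_images", 3))
            results = []
            for i in range(n_images):
                stack, _ = simulate_fa_stack(seed=int(config.seed) * 1000 + ci * 100 + i, **kwargs)
                results.append(quantify_adhesions(stack))
            pd.DataFrame([r.to_dict() for r in results]).assign(condition=name).to_csv(
                out / f"adhesions_{name}.csv", index=False
            )
            summary = fa_condition_summary(results, min_cells=50)
            summaries[name] = summary
            if not summary["ok"]:
                log.event("condition_flagged", condition=name, reason="too_few_cells", **{
                    k: summary[k] for k in ("n_cells", "min_cells")
                })
    elif mode == "rush":
        rng = np.random.default_rng(config.seed)
        for name, kwargs in sorted(conditions.items()):
            release = kwargs.get("release_mean", 0.5)
            leak = kwargs.get("leak_mean", 0.1)
            n = int(kwargs.get("n_cells", 500))
            sd = float(kwargs.get("noise_sd", 0.15))
            rel = [
                CellRecord(i, 1, 1.0, max(r, 0.0), max(r, 0.0))
                for i, r in enumerate(rng.normal(release, sd, n))
            ]
            non = [
                CellRecord(i, 1, 1.0, max(r, 0.0), max(r, 0.0))
                for i, r in enumerate(rng.normal(leak, sd, n))
            ]
            idx = rush_transport_index(rel, non)
            summaries[name] = {
                "index": idx.index,
                "release_mean": idx.release_mean,
                "leak_mean": idx.leak_mean,
                "n_release": idx.n_release,
                "n_nonrelease": idx.n_nonrelease,
            }
    else:
        log.close()
        raise ConfigError(f"unknown imaging mode {mode!r}")
    (out / f"{mode}_summary.json").write_text(json.dumps(summaries, indent=1, sort_keys=True))
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    log.close()
    return out
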