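"""Strong-effector classification and synergy hit calling.

A condition's aggregated (median) transport score is classified as a strong
*inhibitor* at score <= -1.5 — a threshold anchored on coatomer/COPII
positive controls — and, by symmetry, as an *accelerator* at score >= +1.5.

A double knockdown (library gene + SEC23A or SEC23B background) is a
*synergy hit* when its score is a strong effect AND it deviates from the
additive expectation — the sum of the two single-knockdown scores — by more
than one transport-score unit.  Additivity on the score scale is the null
model of genetic non-interaction; the deviation is what the screen is after.

The difference gate uses the absolute deviation by default, capturing both
aggravating (synergistic) and alleviating (buffering) interactions; a signed
mode restricts hits to deviations in the direction of the double-knockdown
effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EFFECT_INHIBITOR",
    "EFFECT_ACCELERATOR",
    "EFFECT_NONE",
    "HitCall",
    "classify_effect",
    "call_synergy",
    "call_hits",
    "rank_hits",
]

EFFECT_INHIBITOR = "inhibitor"
EFFECT_ACCELERATOR = "accelerator"
EFFECT_NONE = "none"

DEFAULT_INHIBIT_THRESHOLD = -1.5
DEFAULT_ACCELERATE_THRESHOLD = 1.5
DEFAULT_MIN_DIFFERENCE = 1.0


@dataclass(frozen=True)
class HitCall:
    """Single vs double knockdown comparison for one (gene, background) pair."""

    gene: str
    background: str
    single_gene_score: float
    single_background_score: float
    double_score: float
    additive_expectation: float
    difference: float
    effect_class: str
    is_hit: bool
    sirna_id: str = ""
    reason: str = ""


def classify_effect(
    score: float,
    inhibit_threshold: float = DEFAULT_INHIBIT_THRESHOLD,
    accelerate_threshold: float = DEFAULT_ACCELERATE_THRESHOLD,
) -> str:
    """Strong-effector class of a transport score.

    ``score <= inhibit_threshold`` -> inhibitor; ``score >=
    accelerate_threshold`` -> accelerator; anything in between (or a
    missing/degenerate score) -> none.
    """
    if score is None or not math.isfinite(float(score)):
        return EFFECT_NONE
    score = float(score)
    if score <= inhibit_threshold:
        return EFFECT_INHIBITOR
    if score >= accelerate_threshold:
        return EFFECT_ACCELERATOR
    return EFFECT_NONE


def call_synergy(
    single_gene: float,
    single_background: float,
    double: float,
    *,
    gene: str = "",
    background: str = "",
    sirna_id: str = "",
    min_difference: float = DEFAULT_MIN_DIFFERENCE,
    signed: bool = False,
    inhibit_threshold: float = DEFAULT_INHIBIT_THRESHOLD,
    accelerate_threshold: float = DEFAULT_ACCELERATE_THRESHOLD,
) -> HitCall:
    """Call one (gene, background) pair a synergy hit or not.

    ``is_hit`` iff the double-knockdown score is a strong effect (classified
    by :func:`classify_effect`) and the deviation from additivity
    ``double - (single_gene + single_background)`` exceeds ``min_difference``
    in magnitude (default) or in the direction of the effect (``signed``).
    Any missing input score yields no call, with the reason recorded.
    """

    def _missing(x: float) -> bool:
        return x is None or not math.isfinite(float(x))

    if _missing(single_gene) or _missing(single_background) or _missing(double):
        return HitCall(
            gene=gene,
            background=background,
            sirna_id=sirna_id,
            single_gene_score=math.nan if _missing(single_gene) else float(single_gene),
            single_background_score=(
                math.nan if _missing(single_background) else float(single_background)
            ),
            double_score=math.nan if _missing(double) else float(double),
            additive_expectation=math.nan,
            difference=math.nan,
            effect_class=EFFECT_NONE,
            is_hit=False,
            reason="missing_score",
        )
    single_gene = float(single_gene)
    single_background = float(single_background)
    double = float(double)
    additive = single_gene + single_background
    difference = double - additive
    effect = classify_effect(double, inhibit_threshold, accelerate_threshold)
    if signed:
        if effect == EFFECT_INHIBITOR:
            gate = difference < -min_difference
        elif effect == EFFECT_ACCELERATOR:
            gate = difference > min_difference
        else:
            gate = False
    else:
        gate = abs(difference) > min_difference
    return HitCall(
        gene=gene,
        background=background,
        sirna_id=sirna_id,
        single_gene_score=single_gene,
        single_background_score=single_background,
        double_score=double,
        additive_expectation=additive,
        difference=difference,
        effect_class=effect,
        is_hit=(effect != EFFECT_NONE) and gate,
    )


def call_hits(
    gene_scores: pd.DataFrame,
    single_background_scores: Mapping[str, float],
    *,
    control_background: str = "control",
    min_difference: float = DEFAULT_MIN_DIFFERENCE,
    signed: bool = False,
    inhibit_threshold: float = DEFAULT_INHIBIT_THRESHOLD,
    accelerate_threshold: float = DEFAULT_ACCELERATE_THRESHOLD,
) -> list[HitCall]:
    """Synergy calls for every (siRNA, knockdown background) condition.

    ``gene_scores`` is the replicate-aggregated table (columns ``sirna_id``,
    ``background``, ``median_score``, ``included``, optionally
    ``target_gene``).  The single-gene score of an siRNA is its score on the
    ``control_background`` chambers; the single-background score comes from
    ``single_background_scores`` (one value per background, e.g. the median
    score of nontargeting spots on that background's chambers — the
    suspension siRNA is chamber-wide, so the windowed score cannot see it
    within a plate).  Conditions excluded by the replicate rule propagate as
    no-calls with reason ``missing_score``.
    """
    df = gene_scores.copy()
    if "included" in df.columns:
        df.loc[~df["included"].astype(bool), "median_score"] = np.nan
    genes = (
        df.set_index(["sirna_id", "background"])["target_gene"].to_dict()
        if "target_gene" in df.columns
        else {}
    )
    pivot = df.pivot_table(
        index="sirna_id", columns="background", values="median_score", aggfunc="first", dropna=False
    )
    calls: list[HitCall] = []
    for background in sorted(single_background_scores):
        if background not in pivot.columns:
            continue
        for sirna_id in pivot.index:
            single = (
                float(pivot.at[sirna_id, control_background])
                if control_background in pivot.columns
                else math.nan
            )
            double = float(pivot.at[sirna_id, background])
            gene = genes.get((sirna_id, background)) or genes.get(
                (sirna_id, control_background), ""
            )
            calls.append(
                call_synergy(
                    single,
                    float(single_background_scores[background]),
                    double,
                    gene=str(gene) if gene else str(sirna_id),
                    background=background,
                    sirna_id=str(sirna_id),
                    min_difference=min_difference,
                    signed=signed,
                    inhibit_threshold=inhibit_threshold,
                    accelerate_threshold=accelerate_threshold,
                )
            )
    return calls


def rank_hits(calls: Iterable[HitCall], *, hits_only: bool = True) -> pd.DataFrame:
    """Hit table ranked by effect strength.

    Sorted by |double score| descending, ties by |difference| descending,
    then gene id lexicographically.  ``hits_only=False`` ranks every call
    (the full screen table).
    """
    rows = [
        {
            "gene": c.gene,
            "sirna_id": c.sirna_id,
            "background": c.background,
            "single_gene_score": c.single_gene_score,
            "single_background_score": c.single_background_score,
            "double_score": c.double_score,
            "additive_expectation": c.additive_expectation,
            "difference": c.difference,
            "effect_class": c.effect_class,
            "is_hit": c.is_hit,
            "reason": c.reason,
        }
        for c in calls
        if c.is_hit or not hits_only
    ]
    columns = [
        "gene",
        "sirna_id",
        "background",
        "single_gene_score",
        "single_background_score",
        "double_score",
        "additive_expectation",
        "difference",
        "effect_class",
        "is_hit",
        "reason",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        return df
    df["_abs_double"] = df["double_score"].abs()
    df["_abs_diff"] = df["difference"].abs()
    df = df.sort_values(
        by=["_abs_double", "_abs_diff", "gene", "sirna_id", "background"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
    ).drop(columns=["_abs_double", "_abs_diff"])
    return df.reset_index(drop=True)
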