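"""Unit and property tests for the windowed median/MAD transport score."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from copiiscreen.plate import ReplicateSet
from copiiscreen.scoring import (
    FLAG_DEGENERATE,
    FLAG_LOW_CELLS,
    FLAG_WINDOW,
    QCThresholds,
    aggregate_replicate_sets,
    aggregate_replicates,
    ddct_fold_change,
    neighborhood_window,
    plate_qc,
    score_plate,
    spot_ratio,
    transport_score,
)

from conftest import grid_layout


def brute_force_score(xi, window):
    """Independent median/MAD oracle built on statistics.median only."""
    med = statistics.median(window)
    mad = statistics.median([abs(v - med) for v in window])
    return med, mad, (xi - med) / mad if mad else math.nan


# --- spot_ratio -----------------------------------------------------------


def test_spot_ratio_is_the_mean_of_valid_cells():
    assert spot_ratio([0.2, 0.4], min_cells=1).xi == pytest.approx(0.3)
    sr = spot_ratio([0.2, 0.4, math.nan], min_cells=2)
    assert sr.n_cells == 2 and sr.xi == pytest.approx(0.3)


def test_spot_ratio_flags_low_cell_counts():
    sr = spot_ratio(np.full(10, 0.5), min_cells=20)
    assert sr.flag == FLAG_LOW_CELLS and math.isnan(sr.xi)


def test_spot_ratio_recovers_programmed_mean(rng):
    sr = spot_ratio(rng.normal(0.5, 0.15, size=200), min_cells=20)
    assert sr.xi == pytest.approx(0.5, abs=0.02)


# --- neighborhood_window --------------------------------------------------


def full_xi_map(layout, value=lambda r, c: 1.0 + 0.01 * r + 0.001 * c):
    return {(s.row, s.col): value(s.row, s.col) for s in layout.spots}


def test_interior_window_has_25_values(small_layout):
    xi = full_xi_map(small_layout)
    win = neighborhood_window(small_layout, small_layout.spot_at(4, 5), xi)
    assert win.values.size == 25 and win.ok


def test_corner_window_truncates_to_9_and_is_flagged(small_layout):
    xi = full_xi_map(small_layout)
    win = neighborhood_window(small_layout, small_layout.spot_at(0, 0), xi)
    assert win.values.size == 9
    assert win.flag == FLAG_WINDOW  # 9 < min_window default 12


def test_window_with_many_missing_neighbors_is_flagged(small_layout):
    xi = full_xi_map(small_layout)
    center = small_layout.spot_at(4, 5)
    for r in range(2, 7):
        for c in range(3, 8):
            if (r, c) != (4, 5):
                xi.pop((r, c), None)
    win = neighborhood_window(small_layout, center, xi)
    assert win.values.size == 1 and win.flag == FLAG_WINDOW


def test_window_can_exclude_control_spots(small_layout):
    xi = full_xi_map(small_layout)
    center = small_layout.spot_at(4, 5)
    full = neighborhood_window(small_layout, center, xi)
    no_ctrl = neighborhood_window(small_layout, center, xi, exclude_controls=True)
    n_controls = sum(
        1
        for r in range(2, 7)
        for c in range(3, 8)
        if (r, c) != (4, 5) and small_layout.spot_at(r, c).control_role != "sample"
    )
    assert no_ctrl.values.size == full.values.size - n_controls


# --- transport_score ------------------------------------------------------


def test_hand_oracle_window_1_to_25():
    window = np.arange(1.0, 26.0)
    res = transport_score(19.0, window)
    assert res.center == 13.0
    assert res.mad == 6.0
    assert res.score == pytest.approx(1.0)


def test_score_is_zero_at_the_window_median():
    window = [0.1, 0.2, 0.3, 0.4, 0.5]
    assert transport_score(0.3, window).score == 0.0


def test_degenerate_mad_is_flagged_never_infinite():
    res = transport_score(1.5, np.full(25, 1.0))
    assert res.flag == FLAG_DEGENERATE
    assert math.isnan(res.score) and res.mad == 0.0


def test_score_matches_brute_force_on_random_windows(rng):
    for _ in range(1000):
        window = rng.uniform(0.1, 1.0, size=25)
        xi = float(rng.uniform(0.1, 1.0))
        res = transport_score(xi, window)
        med, mad, score = brute_force_score(xi, list(window))
        assert res.center == med and res.mad == mad and res.score == score


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    xi1=st.floats(0.01, 2.0),
    xi2=st.floats(0.01, 2.0),
    window=st.lists(st.floats(0.01, 2.0), min_size=12, max_size=25),
)
def test_score_is_strictly_increasing_in_xi(xi1, xi2, window):
    if statistics.median([abs(v - statistics.median(window)) for v in window]) == 0:
        return
    s1 = transport_score(min(xi1, xi2), window).score
    s2 = transport_score(max(xi1, xi2), window).score
    if xi1 != xi2:
        assert s2 > s1
    else:
        assert s2 == s1


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    a=st.floats(0.1, 10.0),
    b=st.floats(-5.0, 5.0),
    xi=st.floats(0.01, 2.0),
    window=st.lists(st.floats(0.01, 2.0), min_size=12, max_size=25),
)
def test_affine_equivariance_of_single_scores(a, b, xi, window):
    window = np.asarray(window)
    base = transport_score(xi, window)
    moved = transport_score(a * xi + b, a * window + b)
    if base.ok:
        assert moved.score == pytest.approx(base.score, abs=1e-9)


def test_median_breakdown_bounds_corruption_of_window_stats(rng):
    window = rng.uniform(0.4, 0.6, size=25)
    med, mad, _ = brute_force_score(0.5, list(window))
    corrupted = window.copy()
    corrupted[:4] *= 10.0  # 4 of 25 wild outliers
    med2, mad2, _ = brute_force_score(0.5, list(corrupted))
    clean = np.sort(window)
    assert clean[0] <= med2 <= clean[-1]  # median stays within the clean range
    assert mad2 <= (clean[-1] - clean[0]) * 1.0 + mad  # spread bounded by clean span


# --- score_plate ----------------------------------------------------------


def plate_table(layout, xi_fn, n_cells=200):
    return pd.DataFrame(
        [
            {"row": s.row, "col": s.col, "xi": xi_fn(s.row, s.col), "n_cells": n_cells, "flag": ""}
            for s in layout.spots
        ]
    )


def test_uniform_plate_scores_are_degenerate_flagged(small_layout):
    scores = score_plate(small_layout, plate_table(small_layout, lambda r, c: 0.5))
    valid_windows = scores[scores["flags"] != FLAG_WINDOW]
    assert (valid_windows["flags"] == FLAG_DEGENERATE).all()


def test_affine_transform_of_a_random_plate_changes_no_score(small_layout, rng):
    table = plate_table(small_layout, lambda r, c: float(rng.uniform(0.2, 0.8)))
    base = score_plate(small_layout, table)
    moved = table.copy()
    moved["xi"] = 1.7 * moved["xi"] + 0.3
    shifted = score_plate(small_layout, moved)
    both = np.isfinite(base["score"]) & np.isfinite(shifted["score"])
    assert both.sum() > 50
    assert np.allclose(base.loc[both, "score"], shifted.loc[both, "score"], atol=1e-9)


def test_single_inhibited_spot_scores_strongly_negative(small_layout, rng):
    table = plate_table(small_layout, lambda r, c: 0.5 + float(rng.normal(0, 0.01)))
    table.loc[(table["row"] == 4) & (table["col"] == 5), "xi"] = 0.1
    scores = score_plate(small_layout, table)
    spiked = scores[(scores["row"] == 4) & (scores["col"] == 5)]["score"].iloc[0]
    assert spiked < -5  # negative scores mean transport inhibition


def test_pure_gradient_plate_scores_zero_on_full_windows(small_layout):
    # a smooth plate effect is exactly what the windowed score removes: on a
    # linear gradient, every full (symmetric) window centers at its own spot.
    # Edge windows are truncated asymmetrically and retain gradient residue.
    table = plate_table(small_layout, lambda r, c: 0.5 + 0.01 * r + 0.006 * c)
    scores = score_plate(small_layout, table)
    interior = scores[scores["window_n"] == 25]
    assert len(interior) >= 20
    assert np.abs(interior["score"]).max() < 1e-9


# --- plate_qc -------------------------------------------------------------


def qc_frame(pos_scores, neg_scores):
    rows = [
        {"chamber_id": "T1", "control_role": "positive", "score": s} for s in pos_scores
    ] + [{"chamber_id": "T1", "control_role": "negative", "score": s} for s in neg_scores]
    return pd.DataFrame(rows)


def test_negative_controls_near_zero_pass():
    report = plate_qc(qc_frame([-3.0, -2.5], [0.08, -0.16]))
    assert report.passed


def test_weak_positive_controls_fail():
    report = plate_qc(qc_frame([-0.5, -0.4], [0.0, 0.1]))
    assert not report.passed and "weak_positive_controls" in report.reasons


def test_missing_control_class_fails_with_reason():
    report = plate_qc(qc_frame([], [0.0]))
    assert not report.passed and "no_positive_controls" in report.reasons


def test_drifting_negatives_fail_and_max_rule_is_stricter():
    report = plate_qc(qc_frame([-3.0], [0.9, 0.8, 0.7]))
    assert "drifting_negative_controls" in report.reasons
    loose = plate_qc(qc_frame([-3.0], [0.05, 1.2, -0.1]))
    assert loose.passed  # median rule tolerates one wild negative spot
    strict = plate_qc(
        qc_frame([-3.0], [0.05, 1.2, -0.1]), thresholds=QCThresholds(negative_rule="max")
    )
    assert not strict.passed


def test_low_transfection_fails():
    report = plate_qc(qc_frame([-3.0], [0.0]), transfection_fraction=0.2)
    assert not report.passed and "low_transfection" in report.reasons
    assert plate_qc(qc_frame([-3.0], [0.0]), transfection_fraction=0.8).passed


# --- replicate aggregation ------------------------------------------------


def test_median_over_replicates_matches_direct_computation():
    frame = pd.DataFrame(
        {
            "sirna_id": ["a"] * 5 + ["b"] * 2,
            "background": ["SEC23A"] * 7,
            "score": [-2.0, -1.8, -1.7, -1.6, 0.1, -1.0, -1.1],
        }
    )
    out = aggregate_replicates(frame)
    a = out[out["sirna_id"] == "a"].iloc[0]
    assert a["median_score"] == -1.7 and a["included"]
    b = out[out["sirna_id"] == "b"].iloc[0]
    assert not b["included"] and b["reason"] == "insufficient_replicates"
    assert math.isnan(b["median_score"])


def test_replicate_sets_aggregate_identically(rng):
    sets = [
        ReplicateSet(("a", "SEC23A"), tuple(rng.normal(0, 1, 5))),
        ReplicateSet(("b", "SEC23B"), tuple(rng.normal(0, 1, 2))),
    ]
    out = aggregate_replicate_sets(sets)
    a = out[out["sirna_id"] == "a"].iloc[0]
    assert a["median_score"] == statistics.median(sets[0].replicate_scores)
    assert not out[out["sirna_id"] == "b"]["included"].iloc[0]


# --- ddCt -----------------------------------------------------------------


@pytest.mark.parametrize(
    "cts, expected",
    [
        ((22.0, 18.0, 22.0, 18.0), 1.0),  # identical dCt -> no change
        ((22.0, 18.0, 21.0, 18.0), 0.5),  # ddCt = +1 -> halved
        ((21.0, 18.0, 22.0, 18.0), 2.0),  # ddCt = -1 -> doubled
    ],
)
def test_ddct_fold_change_worked_examples(cts, expected):
    assert ddct_fold_change(*cts) == pytest.approx(expected)


def test_ddct_rejects_non_finite_ct():
    with pytest.raises(ValueError):
        ddct_fold_change(math.nan, 18.0, 21.0, 18.0)
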