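"""Segmentation and per-cell transport quantification tests."""

import math

import numpy as np
import pytest

from copiiscreen.imagequant import (
    CellRecord,
    ChannelField,
    background_correct,
    bin_cells_by_expression,
    multinucleation_fraction,
    per_cell_transport_ratio,
    records_to_frame,
    rush_transport_index,
    segment_cells,
    segment_nuclei,
)
from copiiscreen.simulate import simulate_cell_field


def disk_field(centers, radius=8, shape=(128, 128), value=180.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


# --- nuclei ---------------------------------------------------------------


def test_five_disjoint_nuclei_give_five_labels():
    field, truth = simulate_cell_field(n_cells=5, seed=3)
    labels = segment_nuclei(field)
    assert labels.max() == 5
    assert labels.min() == 0
    assert set(np.unique(labels)) == set(range(6))  # contiguous from 1


def test_blank_field_gives_zero_labels():
    labels = segment_nuclei(np.zeros((64, 64)))
    assert labels.max() == 0


def test_touching_nuclei_are_split_by_seeded_watershed():
    img = disk_field([(40, 40), (40, 54)])  # overlapping disks, two maxima
    labels = segment_nuclei(img, min_distance=5)
    assert labels.max() == 2


# --- cells ----------------------------------------------------------------


def test_single_nucleus_in_uniform_foreground_claims_everything():
    field = ChannelField(
        channels={"total_marker": np.full((64, 64), 100.0), "nucleus": disk_field([(32, 32)], shape=(64, 64))}
    )
    nuclei = segment_nuclei(field)
    cells = segment_cells(field, nuclei)
    assert cells.max() == 1
    assert (cells > 0).all()


def test_cells_partition_the_foreground_with_one_seed_each():
    field, truth = simulate_cell_field(n_cells=6, shape=(288, 288), seed=11)
    nuclei = segment_nuclei(field)
    cells = segment_cells(field, nuclei)
    assert cells.max() == nuclei.max() == 6
    for label in range(1, 7):
        inside = np.unique(nuclei[cells == label])
        assert len(inside[inside > 0]) == 1  # exactly its seed nucleus
    # segmented territories agree with the ground-truth partition
    fg = truth["cell_labels"] > 0
    seg_fg = cells > 0
    agreement = (cells[fg & seg_fg] > 0).mean()
    assert agreement > 0.95


# --- transport ratio ------------------------------------------------------


def test_transport_ratio_is_surface_over_total():
    cells = np.zeros((32, 32), dtype=np.int32)
    cells[4:14, 4:14] = 1
    total = np.zeros((32, 32))
    surface = np.zeros((32, 32))
    total[cells == 1] = 1.0  # sums to 100
    surface[4:9, 4:14] = 1.0  # sums to 50
    field = ChannelField(channels={"total_marker": total, "surface_marker": surface})
    recs = per_cell_transport_ratio(field, cells, background_percentile=0.0)
    assert recs[0].transport_ratio == pytest.approx(0.5)


def test_zero_total_intensity_is_flagged_missing():
    cells = np.zeros((16, 16), dtype=np.int32)
    cells[2:6, 2:6] = 1
    field = ChannelField(
        channels={"total_marker": np.zeros((16, 16)), "surface_marker": np.zeros((16, 16))}
    )
    recs = per_cell_transport_ratio(field, cells, background_percentile=0.0)
    assert not recs[0].valid and math.isnan(recs[0].transport_ratio)


def test_programmed_ratios_recovered_within_tolerance():
    programmed = [0.2, 0.6, 0.9]
    field, truth = simulate_cell_field(n_cells=3, ratios=programmed, seed=7)
    nuclei = segment_nuclei(field)
    cells = segment_cells(field, nuclei)
    recs = per_cell_transport_ratio(field, cells, nuclei=nuclei)
    measured = {}
    for rec in recs:
        truth_label = np.bincount(truth["cell_labels"][cells == rec.cell_id].ravel()).argmax()
        measured[int(truth_label)] = rec.transport_ratio
    for label, expected in zip((1, 2, 3), programmed):
        assert measured[label] == pytest.approx(expected, abs=0.05)


def test_ratio_is_invariant_to_channel_rescaling():
    field, _ = simulate_cell_field(n_cells=3, seed=9)
    nuclei = segment_nuclei(field)
    cells = segment_cells(field, nuclei)
    base = per_cell_transport_ratio(field, cells)
    scaled_field = ChannelField(
        channels={name: 3.5 * img for name, img in field.channels.items()}
    )
    scaled = per_cell_transport_ratio(scaled_field, cells)
    for a, b in zip(base, scaled):
        assert b.transport_ratio == pytest.approx(a.transport_ratio, rel=1e-9)


def test_background_correction_undoes_a_uniform_offset(rng):
    img = rng.uniform(50, 60, size=(64, 64))
    corrected = background_correct(img + 200.0) - background_correct(img)
    # both corrections anchor at their own 5th percentile, so the offset cancels
    assert np.abs(corrected).max() < 1e-9


# --- expression bins ------------------------------------------------------


def rec(intensity):
    return CellRecord(1, 1, intensity, intensity / 2, 0.5)


def test_bins_are_left_closed_right_open():
    out = bin_cells_by_expression([rec(0.0), rec(10.0), rec(25.0)], thresholds=(10.0, 25.0))
    assert [r.expression_bin for r in out] == ["non", "low", "high"]


def test_bad_thresholds_raise():
    with pytest.raises(ValueError):
        bin_cells_by_expression([rec(1.0)], thresholds=(5.0, 5.0))


def test_well_separated_mixture_bins_mostly_correctly(rng):
    comps = [rng.normal(50, 10, 200), rng.normal(150, 15, 200), rng.normal(300, 30, 200)]
    records = [rec(v) for arr in comps for v in arr]
    out = bin_cells_by_expression(records, thresholds=(100.0, 225.0))
    truth = ["non"] * 200 + ["low"] * 200 + ["high"] * 200
    accuracy = np.mean([r.expression_bin == t for r, t in zip(out, truth)])
    assert accuracy >= 0.9


# --- multinucleation ------------------------------------------------------


def test_multinucleation_counts():
    cells = np.zeros((40, 100), dtype=np.int32)
    nuclei = np.zeros((40, 100), dtype=np.int32)
    for i in range(10):
        cells[5:35, i * 10 : i * 10 + 9] = i + 1
        nuclei[10:14, i * 10 + 2 : i * 10 + 5] = 2 * i + 1
        if i < 2:  # two binucleated cells
            nuclei[25:29, i * 10 + 2 : i * 10 + 5] = 2 * i + 2
    assert multinucleation_fraction(cells, nuclei) == pytest.approx(0.2)
    assert math.isnan(multinucleation_fraction(np.zeros((4, 4), int), nuclei[:4, :4]))


def test_simulated_binucleation_fraction_is_recovered():
    field, truth = simulate_cell_field(
        n_cells=10, shape=(384, 384), binucleation_fraction=0.4, seed=21
    )
    nuclei = segment_nuclei(field)
    cells = segment_cells(field, nuclei, merge_nucleus_distance=30)
    measured = multinucleation_fraction(cells, nuclei)
    assert measured == pytest.approx(float(np.mean(truth["binucleated"])), abs=0.05)


# --- RUSH -----------------------------------------------------------------


def records_with_ratios(values):
    return [CellRecord(i, 1, 1.0, v, v) for i, v in enumerate(values)]


def test_rush_full_leak_gives_zero():
    idx = rush_transport_index(records_with_ratios([0.3] * 10), records_with_ratios([0.3] * 10))
    assert idx.index == 0.0


def test_rush_subtracts_the_leak_mean():
    idx = rush_transport_index(records_with_ratios([0.5] * 10), records_with_ratios([0.1] * 10))
    assert idx.index == pytest.approx(0.4)
    assert idx.release_mean == pytest.approx(0.5) and idx.leak_mean == pytest.approx(0.1)


def test_rush_empty_set_is_flagged_missing():
    idx = rush_transport_index([], records_with_ratios([0.1]))
    assert not idx.ok


def test_rush_recovers_a_programmed_knockdown_reduction(rng):
    # knockdown reduces leak-corrected transport by 50%
    leak = 0.1
    ctrl = records_with_ratios(np.clip(rng.normal(0.5, 0.15, 500), 0, None))
    kd = records_with_ratios(np.clip(rng.normal(0.3, 0.15, 500), 0, None))
    nonrel = records_with_ratios(np.clip(rng.normal(leak, 0.15, 500), 0, None))
    ratio = rush_transport_index(kd, nonrel).index / rush_transport_index(ctrl, nonrel).index
    assert ratio == pytest.approx(0.5, abs=0.1)


def test_records_frame_round_trip_columns():
    frame = records_to_frame(records_with_ratios([0.1, 0.2]))
    assert list(frame["transport_ratio"]) == [0.1, 0.2]
    assert {"cell_id", "nucleus_count", "valid"} <= set(frame.columns)
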