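"""3D puncta pipeline tests: filtering, seeding, segmentation, exclusion."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from copiiscreen.simulate import simulate_spot_stack
from copiiscreen.spot3d import (
    auto_seed_threshold,
    condition_summary,
    detect_seeds,
    exclude_large_clusters,
    per_cell_spot_stats,
    preprocess_stack,
    segment_spots,
)


def quantify(vol):
    filtered = preprocess_stack(vol)
    threshold = auto_seed_threshold(vol)
    seeds = detect_seeds(filtered, threshold)
    labels = segment_spots(filtered, seeds, min_seed_intensity=threshold)
    labels, clusters = exclude_large_clusters(labels, filtered)
    return filtered, labels, clusters


def gaussian_blob(shape, center, sigma, amplitude):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    return amplitude * np.exp(
        -(
            (zz - center[0]) ** 2 / (2 * sigma[0] ** 2)
            + (yy - center[1]) ** 2 / (2 * sigma[1] ** 2)
            + (xx - center[2]) ** 2 / (2 * sigma[2] ** 2)
        )
    )


# --- preprocessing --------------------------------------------------------


def test_constant_stack_preprocesses_to_zero():
    out = preprocess_stack(np.full((12, 24, 24), 37.0))
    assert np.all(out == 0.0)


def test_invalid_radii_raise():
    vol = np.zeros((8, 8, 8))
    with pytest.raises(ValueError):
        preprocess_stack(vol, noise_radius=0)
    with pytest.raises(ValueError):
        preprocess_stack(vol, noise_radius=2, background_radius=2)


def test_punctum_survives_background_subtraction():
    # the 3x3x3 median trims a diffraction-limited Gaussian peak to about
    # half its amplitude (rank-14 of the 27 neighbors); what matters is that
    # the punctum stays far above the residual background and the detection
    # threshold, while the smooth gradient is removed almost completely
    shape = (20, 40, 40)
    gradient = np.linspace(10, 60, shape[2])[None, None, :] * np.ones(shape)
    punctum = gaussian_blob(shape, (10, 20, 20), (1.2, 1.3, 1.3), 80.0)
    vol = gradient + punctum
    out = preprocess_stack(vol)
    peak = out[10, 20, 20]
    assert peak > 0.45 * 80.0
    assert peak > auto_seed_threshold(vol)
    background = out[:, :, :5]
    assert background.max() <= 0.05 * peak


def test_salt_and_pepper_noise_stays_below_the_seed_threshold(rng):
    vol = np.full((16, 32, 32), 20.0)
    idx = rng.integers(0, vol.size, size=200)
    vol.ravel()[idx] = 200.0  # isolated hot voxels
    filtered = preprocess_stack(vol)
    assert filtered.max() < auto_seed_threshold(vol) + 1e-9 or detect_seeds(
        filtered, auto_seed_threshold(vol)
    ).shape[0] == 0


# --- seeds ----------------------------------------------------------------


def test_seeds_found_at_true_centers():
    stack, truth = simulate_spot_stack(n_puncta=10, snr=10, seed=4)
    filtered = preprocess_stack(stack["spots"])
    seeds = detect_seeds(filtered, auto_seed_threshold(stack["spots"]))
    assert len(seeds) == 10
    for seed in seeds:
        nearest = min(np.linalg.norm(seed - c) for c in truth["centers"])
        assert nearest <= 1.5


def test_blank_stack_gives_no_seeds():
    assert detect_seeds(np.zeros((8, 16, 16)), 1.0).shape == (0, 3)


def test_two_close_puncta_with_distinct_maxima_give_two_seeds():
    shape = (16, 32, 32)
    vol = (
        gaussian_blob(shape, (8, 16, 14), (0.7, 0.7, 0.7), 100.0)
        + gaussian_blob(shape, (8, 16, 18), (0.7, 0.7, 0.7), 100.0)
        + 1.0
    )
    seeds = detect_seeds(vol, 20.0)
    assert len(seeds) == 2


def test_raising_the_threshold_never_adds_seeds(rng):
    vol = rng.uniform(0, 50, size=(10, 20, 20))
    counts = [len(detect_seeds(vol, t)) for t in np.linspace(1, 60, 12)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# --- segmentation ---------------------------------------------------------


def test_disjoint_puncta_volumes_near_truth():
    stack, truth = simulate_spot_stack(n_puncta=10, snr=20, seed=5)
    filtered, labels, _ = quantify(stack["spots"])
    assert labels.max() == 10
    # analytic reference volume: voxels above half the peak of one punctum
    one = gaussian_blob((28, 64, 64), (14, 32, 32), (1.2, 1.3, 1.3), truth["amplitude"])
    ref = int((one > 0.5 * auto_seed_threshold(stack["spots"])).sum())
    volumes = np.bincount(labels.ravel())[1:]
    assert np.all(volumes > 0.3 * ref) and np.all(volumes < 3.0 * ref)


def test_touching_puncta_split_along_the_watershed():
    shape = (16, 32, 32)
    vol = (
        gaussian_blob(shape, (8, 16, 13), (1.0, 1.0, 1.0), 100.0)
        + gaussian_blob(shape, (8, 16, 19), (1.0, 1.0, 1.0), 100.0)
    )
    seeds = detect_seeds(vol, 20.0)
    labels = segment_spots(vol, seeds, min_seed_intensity=20.0)
    assert labels.max() == 2
    assert labels[8, 16, 13] != labels[8, 16, 19]


def test_no_seeds_gives_an_empty_mask():
    labels = segment_spots(np.zeros((8, 8, 8)), np.empty((0, 3), int))
    assert labels.max() == 0


# --- cluster exclusion ----------------------------------------------------


def test_golgi_like_cluster_is_excluded_from_spot_analysis():
    stack, truth = simulate_spot_stack(n_puncta=5, snr=10, with_cluster=True, seed=100)
    _, labels, clusters = quantify(stack["spots"])
    assert labels.max() == 5
    assert clusters.max() == 1


def test_without_clusters_the_spot_mask_is_unchanged():
    stack, _ = simulate_spot_stack(n_puncta=6, snr=10, seed=6)
    filtered = preprocess_stack(stack["spots"])
    threshold = auto_seed_threshold(stack["spots"])
    seeds = detect_seeds(filtered, threshold)
    raw = segment_spots(filtered, seeds, min_seed_intensity=threshold)
    kept, clusters = exclude_large_clusters(raw, filtered)
    assert clusters.max() == 0
    assert np.array_equal(kept > 0, raw > 0)


def test_cluster_only_stack_yields_zero_spots():
    stack, _ = simulate_spot_stack(n_puncta=0, snr=10, with_cluster=True, seed=8)
    _, labels, clusters = quantify(stack["spots"])
    assert labels.max() == 0 and clusters.max() == 1


# --- per-cell statistics --------------------------------------------------


def test_spots_assigned_to_cells_by_centroid():
    stack, truth = simulate_spot_stack(n_puncta=10, snr=10, n_cells=2, seed=9)
    _, labels, _ = quantify(stack["spots"])
    stats = per_cell_spot_stats(labels, truth["cell_mask"], stack["spots"])
    assert sorted(stats.per_cell["structure_count"]) == sorted(truth["counts_per_cell"])
    assert stats.n_unassigned == 0


def test_count_conservation_and_intensity_bound():
    stack, truth = simulate_spot_stack(n_puncta=8, snr=10, n_cells=2, seed=10)
    _, labels, _ = quantify(stack["spots"])
    stats = per_cell_spot_stats(labels, truth["cell_mask"], stack["spots"])
    assert stats.total_spots == labels.max()
    ok = stats.per_cell["spot_intensity"] <= stats.per_cell["cell_intensity"] + 1e-9
    assert ok.all()


def test_no_spots_gives_zero_counts():
    stats = per_cell_spot_stats(
        np.zeros((4, 8, 8), int), np.ones((8, 8), int), np.ones((4, 8, 8))
    )
    assert stats.per_cell["structure_count"].sum() == 0


def test_oracle_equivalence_with_connected_components():
    # on sparse noise-free stacks, the pipeline count equals plain
    # thresholded connected-component counting
    shape = (20, 40, 40)
    for centers in [[(5, 10, 10)], [(5, 10, 10), (14, 30, 28)], [(5, 10, 10), (10, 20, 20), (15, 32, 12)]]:
        vol = sum(gaussian_blob(shape, c, (1.2, 1.3, 1.3), 100.0) for c in centers)
        seeds = detect_seeds(vol, 25.0)
        labels = segment_spots(vol, seeds, min_seed_intensity=25.0)
        brute = ndi.label(vol > 12.5)[1]
        assert labels.max() == brute == len(centers)


def test_condition_summary_refuses_too_few_cells():
    stack, truth = simulate_spot_stack(n_puncta=4, snr=10, seed=11)
    _, labels, _ = quantify(stack["spots"])
    stats = per_cell_spot_stats(labels, truth["cell_mask"], stack["spots"])
    refused = condition_summary([stats.per_cell], min_cells=100)
    assert not refused["ok"] and np.isnan(refused["mean_count"])
    accepted = condition_summary([stats.per_cell] * 100, min_cells=100)
    assert accepted["ok"] and accepted["mean_count"] == pytest.approx(4.0)
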