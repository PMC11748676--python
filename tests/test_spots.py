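"""Spot detection, quantification, merging, calibration, counting."""

import numpy as np
import pytest

from telekin import (
    SpotCall,
    calibrate_single_mrna,
    choose_threshold,
    counts_from_spots,
    counts_from_total_fluorescence,
    detect_spots,
    make_cell_masks,
    quantify_spots,
    render_fish_stack,
)


@pytest.fixture(scope="module")
def sparse_image():
    """20 well-separated bright spots across 6 cells."""
    masks = make_cell_masks(6, shape=(128, 128), cell_half=(14, 14))
    counts = {1: 4, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}
    img = render_fish_stack(masks, counts, unit_intensity=20000.0,
                            brightness_sd=0.2, background=30.0, seed=10)
    return img


@pytest.fixture(scope="module")
def control_image():
    masks = make_cell_masks(6, shape=(128, 128), cell_half=(14, 14))
    return render_fish_stack(masks, {i: 0 for i in range(1, 7)},
                             background=30.0, seed=11)


def test_constant_stack_yields_no_calls():
    flat = np.full((5, 32, 32), 7.0)
    assert detect_spots(flat, threshold=0.0) == []
    assert choose_threshold(flat) == pytest.approx(7.0, rel=1e-9)


def test_control_rule_keeps_at_most_a_handful(control_image):
    thr = choose_threshold(control_image.voxels)
    assert len(detect_spots(control_image.voxels, thr)) <= 3
    strict = choose_threshold(control_image.voxels, k_max=0)
    assert detect_spots(control_image.voxels, strict) == []


def test_single_spot_detected_at_truth_voxel():
    masks = make_cell_masks(1, shape=(64, 64), cell_half=(20, 20))
    img = render_fish_stack(masks, {1: 1}, unit_intensity=20000.0,
                            brightness_sd=0.0, background=30.0, seed=12)
    z, y, x, _, _ = img.truth_spots[0]
    calls = detect_spots(img.voxels, threshold=100.0)
    assert len(calls) == 1
    assert abs(calls[0].y - y) <= 1 and abs(calls[0].x - x) <= 1
    assert abs(calls[0].z_plane - z) <= 1


def test_detection_recall_precision_with_control_threshold(sparse_image, control_image):
    # k_max=0 puts the threshold above the control's noise ceiling entirely
    thr = choose_threshold(control_image.voxels, k_max=0)
    calls = detect_spots(sparse_image.voxels, thr, cell_masks=sparse_image.cell_masks)
    truth = {(y, x) for _, y, x, _, _ in sparse_image.truth_spots}
    assert len(calls) == len(truth)  # precision 1
    matched = 0
    for y, x in truth:
        if any(abs(c.y - y) <= 1 and abs(c.x - x) <= 1 for c in calls):
            matched += 1
    assert matched == len(truth)  # recall 1


def test_detection_translation_equivariance(sparse_image):
    stack = sparse_image.voxels
    shifted = np.roll(stack, shift=(0, 5, -7), axis=(0, 1, 2))
    a = detect_spots(stack, threshold=500.0)
    b = detect_spots(shifted, threshold=500.0)
    pos_a = {(c.z_plane, c.y + 5, c.x - 7) for c in a}
    pos_b = {(c.z_plane, c.y, c.x) for c in b}
    # away from borders, every shifted call matches
    interior = {p for p in pos_a if 8 <= p[1] < 120 and 8 <= p[2] < 120}
    assert interior <= pos_b


def test_choose_threshold_monotone_in_kmax(control_image):
    spiked = control_image.voxels.copy()
    rng = np.random.default_rng(0)
    for _ in range(10):  # dim foci above background
        z, y, x = rng.integers(2, 7), rng.integers(10, 118), rng.integers(10, 118)
        spiked[z, y - 1 : y + 2, x - 1 : x + 2] += 25.0
        spiked[z, y, x] += 30.0
    thrs = [choose_threshold(spiked, k_max=k) for k in (0, 1, 3, 5, 20)]
    assert all(a >= b for a, b in zip(thrs, thrs[1:]))
    # the default rule rejects all 10 dim foci
    assert len(detect_spots(spiked, choose_threshold(spiked))) <= 3


def test_quantification_merging_geometry():
    stack = np.zeros((3, 64, 64))
    far = [SpotCall(1, 20, 10, 5.0), SpotCall(1, 20, 30, 4.0)]  # 20 px apart
    near = [SpotCall(1, 40, 20, 5.0), SpotCall(1, 40, 26, 4.0)]  # 6 px apart
    assert len(quantify_spots(stack, far)) == 2
    merged = quantify_spots(stack, near)
    assert len(merged) == 1
    assert merged[0].y == 40 and merged[0].x == 20  # brightest survives


def test_merging_idempotent_and_order_independent():
    stack = np.random.default_rng(1).poisson(10, size=(3, 64, 64)).astype(float)
    calls = [SpotCall(1, 30, 20, 9.0), SpotCall(1, 30, 27, 7.0), SpotCall(1, 30, 34, 8.0)]
    once = quantify_spots(stack, calls)
    rev = quantify_spots(stack, calls[::-1])
    assert len(once) == len(rev) == 1  # chained overlaps collapse to one
    assert once[0].integrated_intensity == pytest.approx(rev[0].integrated_intensity)
    assert (once[0].y, once[0].x) == (rev[0].y, rev[0].x)
    # already-merged calls pass through unchanged in number and position
    again = quantify_spots(stack, once)
    assert len(again) == 1
    assert (again[0].y, again[0].x) == (once[0].y, once[0].x)


def test_disc_sum_on_zero_background_is_exact():
    stack = np.zeros((1, 32, 32))
    stack[0, 10:13, 10:13] = 2.0
    calls = [SpotCall(0, 11, 11, 2.0)]
    out = quantify_spots(stack, calls)
    assert out[0].integrated_intensity == pytest.approx(18.0)  # 9 px x 2


def test_quantified_intensity_matches_rendered_brightness():
    masks = make_cell_masks(1, shape=(64, 64), cell_half=(20, 20))
    img = render_fish_stack(masks, {1: 1}, unit_intensity=50000.0,
                            brightness_sd=0.0, background=30.0, seed=13)
    _, _, _, _, brightness = img.truth_spots[0]
    calls = detect_spots(img.voxels, threshold=500.0)
    out = quantify_spots(img.voxels, calls, control_pixel_level=30.0)
    assert len(out) == 1
    assert out[0].integrated_intensity == pytest.approx(brightness, rel=0.05)


def test_calibration_mode_of_mixture():
    rng = np.random.default_rng(2)
    singles = rng.normal(100.0, 5.0, size=900)
    doublets = rng.normal(200.0, 7.0, size=100)
    cal = calibrate_single_mrna(np.concatenate([singles, doublets]), bin_width=10.0)
    assert 90.0 <= cal.unit_intensity <= 110.0
    assert cal.n_spots == 1000


def test_calibration_identical_intensities_and_homogeneity():
    vals = np.full(50, 123.0)
    cal = calibrate_single_mrna(vals, bin_width=1.0)
    assert cal.unit_intensity == pytest.approx(123.0, abs=0.5)
    rng = np.random.default_rng(3)
    base = rng.normal(100.0, 8.0, size=500)
    a = calibrate_single_mrna(base, bin_width=5.0)
    b = calibrate_single_mrna(3.0 * base, bin_width=15.0)
    assert b.unit_intensity == pytest.approx(3.0 * a.unit_intensity, rel=1e-9)


def test_counts_from_spots_basic():
    calls = [
        SpotCall(0, 1, 1, 5.0, 100.0, cell_label=1),
        SpotCall(0, 2, 2, 5.0, 100.0, cell_label=1),
        SpotCall(0, 3, 3, 5.0, 100.0, cell_label=1),
        SpotCall(0, 9, 9, 5.0, 250.0, cell_label=2),
    ]
    table = counts_from_spots(calls, unit_intensity=100.0, cell_labels=[1, 2, 3])
    by_id = dict(zip(table.df["cell_id"], table.df["mrna_count"]))
    assert by_id["cell1"] == pytest.approx(3.0)
    assert by_id["cell2"] == pytest.approx(2.5)
    assert by_id["cell3"] == 0.0


def test_end_to_end_spot_counts_correlate_with_truth():
    """High-SNR image loop: rendered per-cell counts are recovered by the
    detect -> quantify -> calibrate -> count chain with r >= 0.95."""
    masks = make_cell_masks(12, shape=(200, 200), cell_half=(14, 14))
    rng = np.random.default_rng(4)
    truth_counts = {i: int(rng.integers(0, 5)) for i in range(1, 13)}
    img = render_fish_stack(masks, truth_counts, unit_intensity=20000.0,
                            brightness_sd=0.2, background=30.0, seed=14)
    ctrl = render_fish_stack(masks, {i: 0 for i in truth_counts},
                             background=30.0, seed=15)
    calls = detect_spots(img.voxels, choose_threshold(ctrl.voxels, k_max=0),
                         cell_masks=masks)
    calls = quantify_spots(img.voxels, calls, control_pixel_level=30.0)
    cal = calibrate_single_mrna([c.integrated_intensity for c in calls])
    table = counts_from_spots(calls, cal.unit_intensity,
                              cell_labels=list(truth_counts))
    got = table.df.sort_values("cell_id", key=lambda s: s.str[4:].astype(int))
    got_counts = got["mrna_count"].to_numpy()
    want = np.array([truth_counts[i] for i in range(1, 13)])
    r = np.corrcoef(got_counts, want)[0, 1]
    assert r >= 0.95


def test_whole_cell_fluorescence_counts():
    masks = make_cell_masks(2, shape=(80, 80), cell_half=(16, 16))
    img = render_fish_stack(masks, {1: 30, 2: 0}, unit_intensity=20000.0,
                            brightness_sd=0.0, background=30.0, seed=15,
                            z_mode="center", min_separation=3.0)
    table = counts_from_total_fluorescence(
        img.voxels, masks, negative_control_level=30.0, unit_intensity=20000.0
    )
    by_id = dict(zip(table.df["cell_id"], table.df["mrna_count"]))
    assert by_id["cell1"] == pytest.approx(30.0, rel=0.10)
    assert by_id["cell2"] == pytest.approx(0.0, abs=1.0)
    half = counts_from_total_fluorescence(
        img.voxels, masks, negative_control_level=30.0, unit_intensity=40000.0
    )
    by_id_half = dict(zip(half.df["cell_id"], half.df["mrna_count"]))
    assert by_id_half["cell1"] == pytest.approx(by_id["cell1"] / 2.0, rel=1e-9)
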