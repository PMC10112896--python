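"""Tortuosity, scaffold edges, crossing, line scans, GRASP, staging."""

import numpy as np
import pytest
from scipy.integrate import quad

from vncquant.errors import ConfigurationError, DegenerateImageError, LandmarkError
from vncquant.grid import BinaryMask, VoxelGrid
from vncquant.imagecore import make_neuron_mask
from vncquant.morphometry import (
    ProfileScan,
    ablation_features,
    classify_ablation_stage,
    extract_scaffold_edge,
    grasp_extension_ratio,
    landmark_interval,
    line_scan_profile,
    medial_region_volume,
    peak_distance_from_center,
    score_midline_crossing,
    tortuosity,
    tortuosity_per_larva,
)
from vncquant.synthvnc import CIV, CIII, generate_stack

from conftest import NO_NOISE, make_small_spec

DIMS = (0.5, 0.1, 0.1)


# ------------------------------------------------------------------ tortuosity
def test_collinear_points_give_exactly_one():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0], [7.0, 0.0]])
    assert tortuosity(pts) == 1.0


def test_semicircle_gives_half_pi():
    theta = np.deg2rad(np.arange(0, 181))
    arc = np.column_stack([np.cos(theta), np.sin(theta)])
    assert tortuosity(arc) == pytest.approx(np.pi / 2, abs=1e-4)


def test_random_polyline_matches_pairwise_sum_oracle(rng):
    pts = rng.uniform(0, 10, (25, 3))
    total = sum(
        float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(len(pts) - 1)
    )
    chord = float(np.sqrt(((pts[-1] - pts[0]) ** 2).sum()))
    assert tortuosity(pts) == pytest.approx(total / chord)


def test_tortuosity_never_below_one(rng):
    for _ in range(20):
        pts = rng.uniform(0, 5, (8, 2))
        assert tortuosity(pts) >= 1.0 - 1e-9


def test_closed_path_and_degenerate_inputs_raise():
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
    with pytest.raises(ConfigurationError, match="undefined chord"):
        tortuosity(square)
    with pytest.raises(ConfigurationError):
        tortuosity(np.array([[0.0, 0.0]]))
    with pytest.raises(ConfigurationError, match="distinct"):
        tortuosity(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))


def test_per_larva_average():
    edges = [
        np.array([[0.0, 0.0], [1.0, 0.0]]),
        np.array([[0.0, 0.0], [2.0, 0.0]]),
        np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]]),
    ]
    vals = [tortuosity(e) for e in edges]
    assert tortuosity_per_larva(edges) == pytest.approx(np.mean(vals))
    assert tortuosity_per_larva(edges[:1]) == pytest.approx(vals[0])


# ------------------------------------------------------------------ scaffold edge
def test_rectangular_scaffold_edge_is_straight():
    mask = np.zeros((2, 100, 80), bool)
    mask[:, 10:90, 50:60] = True  # right-side rectangle (midline at col 40)
    edge = extract_scaffold_edge(BinaryMask(mask, DIMS), "right", midline_x=4.0)
    assert tortuosity(edge) == pytest.approx(1.0, abs=1e-9)


def test_mirrored_masks_give_mirrored_edges():
    base = np.zeros((2, 60, 81), bool)
    cols = 55 + (4 * np.sin(np.arange(60) / 6)).astype(int)
    for j, c in enumerate(cols):
        base[:, j, 52:c] = True
    mirrored = base[:, :, ::-1]
    e_r = extract_scaffold_edge(BinaryMask(base, DIMS), "right", midline_x=4.0,
                                smooth_window_um=0, resample_step_um=0)
    e_l = extract_scaffold_edge(BinaryMask(mirrored, DIMS), "left", midline_x=4.0,
                                smooth_window_um=0, resample_step_um=0)
    np.testing.assert_allclose(e_l[:, 0], (80 * 0.1) - e_r[:, 0], atol=1e-9)
    np.testing.assert_allclose(e_l[:, 1], e_r[:, 1])


def test_sinusoidal_edge_tortuosity_matches_arc_length_within_two_percent():
    amplitude, period, length = 2.0, 16.0, 48.0
    dy = dx = 0.1
    ny, nx = int(length / dy), 200
    mask = np.zeros((2, ny, nx), bool)
    y = np.arange(ny) * dy
    edge_x = 12.0 + amplitude * np.sin(2 * np.pi * y / period)
    for j in range(ny):
        mask[:, j, 40 : int(round(edge_x[j] / dx))] = True
    poly = extract_scaffold_edge(BinaryMask(mask, (0.5, dy, dx)), "right", midline_x=2.0)
    k = 2 * np.pi / period
    arc, _ = quad(lambda t: np.sqrt(1 + (amplitude * k * np.cos(k * t)) ** 2), 0, length,
                  limit=500)
    expected = arc / length
    assert tortuosity(poly) == pytest.approx(expected, rel=0.02)


def test_empty_side_raises():
    mask = np.zeros((2, 10, 20), bool)
    mask[:, :, 15:18] = True
    with pytest.raises(DegenerateImageError):
        extract_scaffold_edge(BinaryMask(mask, DIMS), "left", midline_x=1.0)


# ------------------------------------------------------------------ crossing
def test_crossing_scorer_matches_ground_truth_three_states():
    spec = make_small_spec(seed=1, noise=NO_NOISE, n_segments=3, shape=(6, 220, 140),
                           commissures=("full", "partial", "absent"))
    stack, truth = generate_stack(spec)
    mask = make_neuron_mask(stack[CIV], "otsu", 5)
    scores = score_midline_crossing(mask, truth.midline_x, truth.segment_bounds_y,
                                    spec.civ_tract_offsets)
    assert [s.crossing for s in scores] == ["crossing", "non_crossing", "non_crossing"]


def test_ciii_branch_scores_as_crossing():
    spec = make_small_spec(seed=2, noise=NO_NOISE, ciii_medial_branch=(True, False))
    stack, truth = generate_stack(spec)
    mask = make_neuron_mask(stack[CIII], "otsu", 5)
    scores = score_midline_crossing(mask, truth.midline_x, truth.segment_bounds_y,
                                    spec.ciii_tract_offsets)
    assert [s.crossing for s in scores] == ["crossing", "non_crossing"]


def test_empty_mask_scores_all_non_crossing():
    mask = BinaryMask(np.zeros((2, 40, 40), bool), DIMS)
    scores = score_midline_crossing(mask, 2.0, [(0.0, 2.0), (2.0, 4.0)], (-1.0, 1.0))
    assert all(s.crossing == "non_crossing" for s in scores)


# ------------------------------------------------------------------ medial volume
def _landmark_grid(nx=120, peak_cols=(30, 90)):
    data = np.full((2, 20, nx), 1.0)
    for c in peak_cols:
        data[:, :, c] = 100.0
    return VoxelGrid(data, DIMS)


def test_landmark_interval_finds_tract_peaks():
    assert landmark_interval(_landmark_grid(), midline_x=6.0) == (3.0, 9.0)


def test_flat_landmark_channel_raises():
    with pytest.raises(LandmarkError, match="landmark tracts undetected"):
        landmark_interval(VoxelGrid(np.full((2, 20, 120), 5.0), DIMS), midline_x=6.0)


def test_fully_medial_block_volume():
    mask = np.zeros((2, 20, 120), bool)
    mask[:1, 5:15, 50:60] = True  # 100 voxels between cols 30 and 90
    vol = medial_region_volume(BinaryMask(mask, DIMS), _landmark_grid(), midline_x=6.0)
    assert vol == pytest.approx(100 * 0.5 * 0.1 * 0.1)


def test_fully_lateral_mask_has_zero_medial_volume():
    mask = np.zeros((2, 20, 120), bool)
    mask[:, :, 100:110] = True
    assert medial_region_volume(BinaryMask(mask, DIMS), _landmark_grid(), midline_x=6.0) == 0.0


# ------------------------------------------------------------------ line scans
def test_constant_image_gives_flat_profile():
    g = VoxelGrid(np.full((3, 120, 200), 13.0), (0.5, 0.29, 0.29))
    scan = line_scan_profile(g, center_um=(200 * 0.29 / 2, 120 * 0.29 / 2))
    np.testing.assert_allclose(scan.values, 13.0)


def test_stripe_peak_found_at_its_offset():
    g = np.full((1, 120, 200), 1.0)
    g[:, :, 130] = 50.0
    grid = VoxelGrid(g, (0.5, 0.29, 0.29))
    center = (100 * 0.29, 60 * 0.29)
    scan = line_scan_profile(grid, center)
    assert scan.positions[np.argmax(scan.values)] == pytest.approx(30 * 0.29)


def test_profile_equals_per_column_mean_oracle(rng):
    data = rng.uniform(0, 50, (2, 120, 200))
    grid = VoxelGrid(data, (0.5, 0.29, 0.29))
    scan = line_scan_profile(grid, (100 * 0.29, 60 * 0.29), z_plane=1)
    half_cols, half_rows = round(35.0 / 0.29 / 2), round(20.0 / 0.29 / 2)
    rect = data[1, 60 - half_rows:60 + half_rows, 100 - half_cols:100 + half_cols + 1]
    np.testing.assert_allclose(scan.values, [rect[:, i].mean() for i in range(rect.shape[1])])
    assert len(scan.positions) == 2 * half_cols + 1
    assert abs(scan.positions[0] + scan.positions[-1]) <= scan.pixel_pitch


def test_scan_rectangle_out_of_bounds_raises():
    g = VoxelGrid(np.zeros((1, 50, 50)) + 1.0, (0.5, 0.29, 0.29))
    with pytest.raises(ConfigurationError, match="out of image bounds"):
        line_scan_profile(g, (2.0, 7.0))


def test_peak_distance_and_tie_rule():
    scan = ProfileScan(np.array([-5.0, 0.0, 5.0]), np.array([1.0, 0.0, 2.0]), 1.0)
    assert peak_distance_from_center(scan) == 5.0
    tie = ProfileScan(np.array([-3.0, 0.0, 3.0, 6.0]), np.array([9.0, 0.0, 9.0, 1.0]), 1.0)
    assert peak_distance_from_center(tie) == 3.0


# ------------------------------------------------------------------ GRASP
def _grasp_grid(signal_cols):
    data = np.full((1, 40, 140), 2.0)
    # signal fills part of the ROI's y-extent so the within-ROI Otsu
    # threshold sees both classes
    data[0, 10:30, signal_cols] = 80.0
    return VoxelGrid(data, DIMS)


ROI = {"x_medial": 2.0, "x_lateral": 12.0, "y0": 0.5, "y1": 3.5, "z": 0}


def test_grasp_spanning_whole_roi_is_one():
    mean, ratios = grasp_extension_ratio(_grasp_grid(slice(20, 120)), [ROI])
    assert mean == pytest.approx(1.0, abs=0.01)


def test_grasp_confined_to_lateral_quarter_is_a_quarter():
    mean, _ = grasp_extension_ratio(_grasp_grid(slice(95, 120)), [ROI])
    assert mean == pytest.approx(0.25, abs=0.01)


def test_roi_without_signal_contributes_zero():
    grid = VoxelGrid(np.full((1, 40, 140), 2.0), DIMS)
    mean, ratios = grasp_extension_ratio(grid, [ROI])
    assert mean == 0.0 and ratios == [0.0]


def test_grasp_ratio_bounded_and_averaged():
    g = _grasp_grid(slice(60, 120))
    mean, ratios = grasp_extension_ratio(g, [ROI, ROI])
    assert 0.0 <= mean <= 1.0 and mean == pytest.approx(np.mean(ratios))


# ------------------------------------------------------------------ staging
@pytest.mark.parametrize(
    "features,stage",
    [
        ((0, True, True), "intact"),
        ((1, True, True), "intact"),
        ((2, True, True), "blebbed"),
        ((3, True, True), "blebbed"),
        ((0, True, False), "ablated"),
        ((5, False, False), "ablated"),
    ],
)
def test_stage_classification_rule(features, stage):
    assert classify_ablation_stage(*features) == stage


def test_ablation_features_recover_staged_segments():
    from vncquant.synthvnc import SegmentStage

    spec = make_small_spec(
        seed=9,
        n_segments=3,
        shape=(6, 220, 140),
        civ_stages=(
            SegmentStage("intact", 0, ()),
            SegmentStage("blebbed", 3, ()),
            SegmentStage("ablated", 0, ("left",)),
        ),
    )
    stack, truth = generate_stack(spec)
    feats = ablation_features(stack[CIV], truth.segment_bounds_y, truth.midline_x,
                              spec.civ_tract_offsets, spec.intensity_levels[CIV])
    assert [classify_ablation_stage(*f) for f in feats] == ["intact", "blebbed", "ablated"]
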