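"""Peak detection, merging, matching, and parameter-search behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vncquant.errors import ConfigurationError
from vncquant.grid import VoxelGrid
from vncquant.puncta import (
    DetectionParams,
    Punctum,
    PunctaSet,
    count_in_rois,
    detect_puncta,
    match_detections,
    optimize_params,
    puncta_density,
)

DIMS = (0.5, 0.1, 0.1)  # (dz, dy, dx) µm


def render_spots(centers_um, amplitudes, sigma_um, shape=(8, 80, 80),
                 background=0.0, seed=None, noise_sd=0.0):
    """Independent spot renderer for detector tests (full, untruncated
    Gaussians, unlike the generator's 3-sigma support)."""
    dz, dy, dx = DIMS
    zz = np.arange(shape[0])[:, None, None] * dz
    yy = np.arange(shape[1])[None, :, None] * dy
    xx = np.arange(shape[2])[None, None, :] * dx
    img = np.full(shape, background, dtype=float)
    for (x, y, z), a in zip(centers_um, amplitudes):
        img += a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2) / (2 * sigma_um**2))
    if noise_sd:
        img += np.random.default_rng(seed).normal(0, noise_sd, shape)
    return VoxelGrid(np.clip(img, 0, None), DIMS)


PERMISSIVE = DetectionParams(blur_sigma_um=0.0, background_method="absolute",
                             background_param=5.0, min_peak_height=0.0, min_size=1)


def test_single_spot_detected_within_one_voxel():
    center = (4.05, 3.95, 2.1)
    g = render_spots([center], [100.0], 0.2)
    found = detect_puncta(g, PERMISSIVE)
    assert len(found) == 1
    cx, cy, cz = found.peaks[0].centroid_um
    assert abs(cx - center[0]) <= DIMS[2]
    assert abs(cy - center[1]) <= DIMS[1]
    assert abs(cz - center[2]) <= DIMS[0]


def test_two_peaks_split_then_merge_by_saddle_height():
    """Two spots with a low saddle: separate at small min_peak_height, a
    single punctum once min_peak_height exceeds the spot amplitude."""
    centers = [(3.0, 2.75, 2.0), (3.0, 5.25, 2.0)]  # 2.5 µm apart, sigma 0.5
    g = render_spots(centers, [100.0, 100.0], 0.5)
    split = detect_puncta(g, DetectionParams(
        blur_sigma_um=0.0, background_method="absolute", background_param=5.0,
        min_peak_height=20.0, min_size=1))
    assert len(split) == 2
    merged = detect_puncta(g, DetectionParams(
        blur_sigma_um=0.0, background_method="absolute", background_param=5.0,
        min_peak_height=150.0, min_size=1))
    assert len(merged) == 1


def test_background_at_or_above_max_yields_empty_set():
    g = render_spots([(3, 3, 2)], [50.0], 0.3)
    out = detect_puncta(g, DetectionParams(background_method="absolute",
                                           background_param=1000.0))
    assert len(out) == 0


def test_count_never_increases_with_stricter_params():
    rng = np.random.default_rng(4)
    centers = [(rng.uniform(1, 7), rng.uniform(1, 7), rng.uniform(1, 3)) for _ in range(12)]
    g = render_spots(centers, rng.uniform(60, 140, 12), 0.25, seed=1, noise_sd=3.0)
    for vary, values in (
        ("min_peak_height", [0.0, 10.0, 40.0, 90.0, 200.0]),
        ("min_size", [1, 3, 6, 12, 40]),
    ):
        counts = [
            len(detect_puncta(g, DetectionParams(
                blur_sigma_um=0.1, background_method="absolute", background_param=10.0,
                **{vary: v})))
            for v in values
        ]
        assert counts == sorted(counts, reverse=True), (vary, counts)


def test_detection_is_translation_equivariant():
    g = render_spots([(2.0, 2.0, 1.0), (5.0, 4.0, 2.5)], [90.0, 120.0], 0.2)
    found = detect_puncta(g, PERMISSIVE)
    shift_vox = (1, 7, 5)  # (z, y, x)
    shifted_img = np.roll(g.data, shift_vox, axis=(0, 1, 2))
    found_shifted = detect_puncta(VoxelGrid(shifted_img, DIMS), PERMISSIVE)
    delta = np.array([shift_vox[2] * DIMS[2], shift_vox[1] * DIMS[1], shift_vox[0] * DIMS[0]])
    np.testing.assert_allclose(found_shifted.centroids, found.centroids + delta, atol=1e-9)


def test_connectivity_and_param_validation():
    with pytest.raises(ConfigurationError):
        DetectionParams(connectivity=18).validate()
    with pytest.raises(ConfigurationError):
        DetectionParams(min_size=0).validate()


# ------------------------------------------------------------------ matching
def as_puncta_set(points, intensities=None) -> PunctaSet:
    pts = np.atleast_2d(points)
    if intensities is None:
        intensities = np.arange(len(pts), 0, -1, dtype=float)
    peaks = [Punctum(tuple(p), float(i), 1) for p, i in zip(pts, intensities)]
    peaks.sort(key=lambda p: -p.peak_intensity)
    return PunctaSet(peaks)


def test_perfect_detection_scores_unity():
    truth = np.array([[1.0, 1.0, 1.0], [3.0, 2.0, 1.0]])
    m = match_detections(as_puncta_set(truth), truth, 0.5)
    assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)


def test_counts_follow_the_precision_recall_formulas():
    truth = np.array([[float(i), 0.0, 0.0] for i in range(7)])
    detected = np.vstack([truth[:5] + 0.05, [[50.0, 50.0, 50.0]]])  # 5 hits + 1 stray
    m = match_detections(as_puncta_set(detected), truth, 0.3)
    assert (m.tp, m.fp, m.fn) == (5, 1, 2)
    assert m.precision == pytest.approx(5 / 6)
    assert m.recall == pytest.approx(5 / 7)
    p, r = 5 / 6, 5 / 7
    assert m.f1 == pytest.approx(2 * p * r / (p + r))


def greedy_match_oracle(det_pts, det_int, truth, radius):
    """Plain-python reimplementation of the greedy matching contract."""
    order = sorted(range(len(det_pts)), key=lambda i: -det_int[i])
    claimed, tp = set(), 0
    for i in order:
        best_j, best_d = None, radius
        for j in range(len(truth)):
            if j in claimed:
                continue
            d = float(np.linalg.norm(np.subtract(det_pts[i], truth[j])))
            if d <= best_d:
                best_j, best_d = j, d
        if best_j is not None:
            claimed.add(best_j)
            tp += 1
    return tp, len(det_pts) - tp, len(truth) - tp


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 2**31 - 1))
def test_matching_agrees_with_bruteforce_and_count_identities(seed):
    r = np.random.default_rng(seed)
    nd, nt = int(r.integers(0, 12)), int(r.integers(0, 12))
    det = r.uniform(0, 5, (nd, 3))
    intensities = r.uniform(1, 100, nd)
    truth = r.uniform(0, 5, (nt, 3))
    m = match_detections(as_puncta_set(det, intensities), truth, 1.0)
    assert (m.tp, m.fp, m.fn) == greedy_match_oracle(det, intensities, truth, 1.0)
    assert m.tp + m.fp == nd and m.tp + m.fn == nt


def test_match_radius_must_be_positive():
    with pytest.raises(ConfigurationError):
        match_detections(PunctaSet(), np.zeros((0, 3)), 0.0)


# ------------------------------------------------------------------ optimization
def _training_rois(n=3, seed=0):
    rng = np.random.default_rng(seed)
    rois = []
    for _ in range(n):
        centers = [(rng.uniform(1, 7), rng.uniform(1, 7), rng.uniform(1, 3)) for _ in range(8)]
        g = render_spots(centers, rng.uniform(80, 120, 8), 0.25,
                         background=10.0, seed=int(rng.integers(1 << 30)), noise_sd=4.0)
        rois.append((g, np.array(centers)))
    return rois


def test_single_candidate_returned_with_its_evaluation():
    rois = _training_rois(1)
    params, result = optimize_params(rois, {"background_param": [20.0]})
    assert params.background_param == 20.0
    m = match_detections(detect_puncta(rois[0][0], params), rois[0][1], 0.5)
    assert (result.tp, result.fp, result.fn) == (m.tp, m.fp, m.fn)


def test_grid_search_beats_every_candidate_exhaustively():
    rois = _training_rois(3)
    space = {"background_param": [20.0, 500.0], "min_peak_height": [5.0, 250.0]}
    best, pooled = optimize_params(rois, space)
    # exhaustive re-evaluation oracle
    import itertools

    for bg, h in itertools.product(space["background_param"], space["min_peak_height"]):
        cand = DetectionParams(background_param=bg, min_peak_height=h)
        tp = fp = fn = 0
        for g, truth in rois:
            m = match_detections(detect_puncta(g, cand), truth, 0.5)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        from vncquant.puncta import MatchResult

        assert pooled.f1 >= MatchResult(tp, fp, fn).f1 - 1e-12
    assert best.background_param == 20.0  # the decoys destroy recall


def test_empty_search_space_is_an_error():
    with pytest.raises(ConfigurationError):
        optimize_params(_training_rois(1), {})
    with pytest.raises(ConfigurationError):
        optimize_params([], {"background_param": [1.0]})


# ------------------------------------------------------------------ ROI counting
def box(x0, x1, y0, y1, z0=0.0, z1=4.0):
    return {"x0": x0, "x1": x1, "y0": y0, "y1": y1, "z0": z0, "z1": z1}


def test_puncta_outside_all_rois_sum_to_zero():
    pts = as_puncta_set([[10.0, 10.0, 1.0]])
    _, total = count_in_rois(pts, [box(0, 1, 0, 1)])
    assert total == 0


def test_per_roi_counts_and_larva_sum():
    rois = [box(i, i + 1, 0, 1) for i in range(6)]
    want = [3, 1, 0, 2, 4, 0]
    pts = []
    for i, n in enumerate(want):
        pts += [[i + 0.5 + k * 1e-3, 0.5, 1.0] for k in range(n)]
    counts, total = count_in_rois(as_puncta_set(pts), rois)
    assert counts == want and total == 10


def test_boxes_are_half_open():
    pts = as_puncta_set([[1.0, 0.5, 1.0]])
    counts, _ = count_in_rois(pts, [box(0, 1, 0, 1), box(1, 2, 0, 1)])
    assert counts == [0, 1]


def test_density_arithmetic_and_guard():
    assert puncta_density(10, 5.0) == pytest.approx(2.0)
    assert puncta_density(0, 5.0) == 0.0
    assert puncta_density(20, 10.0) == puncta_density(10, 5.0)
    with pytest.raises(ConfigurationError, match="no axon volume"):
        puncta_density(1, 0.0)
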