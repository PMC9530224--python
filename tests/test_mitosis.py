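"""Mitosis detection: erosion/components, matching, PRF, density features."""

import itertools

import numpy as np
import pytest

from aigrading.containers import MitosisHeatmap, TumorMask
from aigrading.mitosis import (
    DetectionConfig,
    DetectionSet,
    ReferenceMitoses,
    detect_mitoses,
    detection_prf,
    match_detections,
    mitotic_density,
    se_size_px,
)

CFG = DetectionConfig()


# ---------------------------------------------------------------- oracles


def brute_force_erosion(binary: np.ndarray, k: int) -> np.ndarray:
    """Direct definition: pixel on iff every pixel under the kxk window is on."""
    padded = np.pad(binary, k // 2, constant_values=False)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k, k))
    return windows.all(axis=(2, 3))


def flood_components(binary: np.ndarray, connectivity: int = 8):
    """Independent BFS connected-components labelling; returns pixel lists."""
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    h, w = binary.shape
    for r0, c0 in zip(*np.nonzero(binary)):
        if seen[r0, c0]:
            continue
        stack = [(r0, c0)]
        seen[r0, c0] = True
        pixels = []
        while stack:
            r, c = stack.pop()
            pixels.append((r, c))
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        comps.append(pixels)
    return comps


def oracle_centroids(binary: np.ndarray, k: int, mpp: float, connectivity: int = 8):
    eroded = brute_force_erosion(binary, k)
    cents = []
    for pixels in flood_components(eroded, connectivity):
        arr = np.asarray(pixels, dtype=float)
        cents.append(((arr[:, 1].mean() + 0.5) * mpp, (arr[:, 0].mean() + 0.5) * mpp))
    return sorted(cents)


def brute_force_match(det_xy, ref_xy, radius):
    """Exhaustive best one-to-one matching: max cardinality, then min cost."""
    n_det, n_ref = len(det_xy), len(ref_xy)
    best = (0, 0.0, [])
    for r in range(min(n_det, n_ref), -1, -1):
        found = None
        for det_sub in itertools.combinations(range(n_det), r):
            for ref_perm in itertools.permutations(range(n_ref), r):
                dists = [
                    np.linalg.norm(np.subtract(det_xy[i], ref_xy[j]))
                    for i, j in zip(det_sub, ref_perm)
                ]
                if all(d <= radius for d in dists):
                    cost = sum(dists)
                    if found is None or cost < found[0]:
                        found = (cost, list(zip(det_sub, ref_perm)))
        if found:
            return r, found[1]
    return 0, []


# ------------------------------------------------------------- detection


def test_all_zero_heatmap_yields_no_detections():
    hm = MitosisHeatmap(np.zeros((64, 64)), 2.0)
    assert len(detect_mitoses(hm, CFG)) == 0


def test_single_cell_blob_erodes_to_its_center():
    """A blob exactly the SE footprint leaves one centroid at its center."""
    mpp = 2.0
    k = se_size_px(CFG.se_size_um, mpp)  # 9 px at 2 um/px
    grid = np.zeros((100, 100))
    r = c = 50 - k // 2
    grid[r : r + k, c : c + k] = 1.0
    det = detect_mitoses(MitosisHeatmap(grid, mpp), CFG)
    assert len(det) == 1
    center = (50 - k // 2 + k // 2 + 0.5) * mpp  # center pixel of the blob
    assert det.centroids[0] == pytest.approx((center, center), abs=mpp / 2)
    assert det.peak_likelihood[0] == 1.0


def test_two_overlapping_blobs_give_two_detections():
    """Two cell-sized blobs overlapping diagonally erode to two separate points."""
    mpp = 2.0
    k = se_size_px(CFG.se_size_um, mpp)
    grid = np.zeros((120, 120))
    grid[30 : 30 + k, 30 : 30 + k] = 1.0
    off = k // 2  # half-blob diagonal offset: regions genuinely overlap
    grid[30 + off : 30 + off + k, 30 + off : 30 + off + k] = 1.0
    det = detect_mitoses(MitosisHeatmap(grid, mpp), CFG)
    assert len(det) == 2


def test_axis_aligned_overlap_merges_to_one_component():
    """A purely horizontal overlap forms a rectangle: one eroded component."""
    mpp = 2.0
    k = se_size_px(CFG.se_size_um, mpp)
    grid = np.zeros((120, 120))
    grid[30 : 30 + k, 30 : 30 + k] = 1.0
    grid[30 : 30 + k, 30 + k // 2 : 30 + k // 2 + k] = 1.0
    det = detect_mitoses(MitosisHeatmap(grid, mpp), CFG)
    assert len(det) == 1


@pytest.mark.parametrize("connectivity", [4, 8])
def test_detector_matches_direct_definition_oracle(connectivity, rng):
    """Erosion + components on random binary maps equals the brute-force oracle."""
    cfg = DetectionConfig(connectivity=connectivity)
    for _ in range(20):
        base = rng.random((96, 96))
        binary = base > 0.25  # dense enough to survive erosion occasionally
        hm = MitosisHeatmap(binary.astype(float), 2.0)
        det = detect_mitoses(hm, cfg)
        k = se_size_px(cfg.se_size_um, 2.0)
        expected = oracle_centroids(binary, k, 2.0, connectivity)
        got = sorted(map(tuple, det.centroids))
        assert len(got) == len(expected)
        assert np.allclose(got, expected, atol=1e-9)


def test_threshold_monotonicity(rng):
    hm = MitosisHeatmap(rng.random((80, 80)) * 0.2 + 0.8, 2.0)
    counts = [
        len(detect_mitoses(hm, DetectionConfig(threshold=t)))
        for t in (0.82, 0.86, 0.9, 0.94, 0.98)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_translation_equivariance():
    mpp = 2.0
    k = se_size_px(16.0, mpp)
    grid = np.zeros((128, 128))
    grid[20 : 20 + k, 20 : 20 + k] = 1.0
    det0 = detect_mitoses(MitosisHeatmap(grid, mpp), CFG)
    shifted = np.roll(grid, (7, 11), axis=(0, 1))
    det1 = detect_mitoses(MitosisHeatmap(shifted, mpp), CFG)
    assert np.allclose(det1.centroids, det0.centroids + [11 * mpp, 7 * mpp])


def test_se_larger_than_grid_rejected():
    hm = MitosisHeatmap(np.ones((4, 4)), 2.0)
    with pytest.raises(ValueError, match="larger"):
        detect_mitoses(hm, CFG)


# -------------------------------------------------------------- matching


def test_perfect_match():
    pts = np.array([[10.0, 10.0], [50.0, 50.0]])
    det = DetectionSet(pts, np.ones(2))
    ref = ReferenceMitoses(pts, [3, 2])
    m = match_detections(det, ref, CFG)
    assert (m.tp, m.fp, m.fn) == (2, 0, 0)
    assert detection_prf(m)[:3] == (1.0, 1.0, 1.0)


def test_spec_distances_example_f1_04():
    """3 detections at 10/20/40 um from their nearest references: only the
    10-um pair is within the 16-um radius, so TP=1, FP=2, FN=1, F1=0.4."""
    refs = np.array([[0.0, 0.0], [100.0, 0.0]])
    dets = np.array([[10.0, 0.0], [20.0, 0.0], [140.0, 0.0]])
    m = match_detections(DetectionSet(dets, np.ones(3)), ReferenceMitoses(refs, [3, 3]), CFG)
    assert (m.tp, m.fp, m.fn) == (1, 2, 1)
    p, r, f1, flagged = detection_prf(m)
    assert (p, r) == (pytest.approx(1 / 3), pytest.approx(1 / 2))
    assert f1 == pytest.approx(0.4)
    assert not flagged


def test_duplicate_detections_yield_one_tp():
    refs = np.array([[0.0, 0.0]])
    dets = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
    m = match_detections(DetectionSet(dets, np.ones(3)), ReferenceMitoses(refs, [2]), CFG)
    assert (m.tp, m.fp, m.fn) == (1, 2, 0)


def test_sub_majority_boxes_are_not_references():
    refs = np.array([[0.0, 0.0], [50.0, 0.0]])
    ref = ReferenceMitoses(refs, [3, 1])  # second box only 1 rater-positive
    det = DetectionSet(np.array([[0.0, 0.0], [50.0, 0.0]]), np.ones(2))
    m = match_detections(det, ref, CFG)
    assert (m.tp, m.fp, m.fn) == (1, 1, 0)


def test_matching_equals_exhaustive_assignment_oracle(rng):
    for _ in range(30):
        n_det, n_ref = rng.integers(0, 6, size=2)
        det_xy = rng.random((n_det, 2)) * 60
        ref_xy = rng.random((n_ref, 2)) * 60
        m = match_detections(
            DetectionSet(det_xy, np.ones(n_det)),
            ReferenceMitoses(ref_xy, np.full(n_ref, 3)),
            CFG,
        )
        best_card, best_pairs = brute_force_match(det_xy, ref_xy, CFG.match_radius_um)
        assert m.tp == best_card
        if best_card:
            cost = sum(
                np.linalg.norm(det_xy[i] - ref_xy[j]) for i, j in m.tp_pairs
            )
            oracle_cost = sum(
                np.linalg.norm(det_xy[i] - ref_xy[j]) for i, j in best_pairs
            )
            assert cost == pytest.approx(oracle_cost, abs=1e-9)


def test_prf_zero_denominators_flagged():
    m = match_detections(
        DetectionSet(np.empty((0, 2)), np.empty(0)),
        ReferenceMitoses(np.array([[0.0, 0.0]]), [3]),
        CFG,
    )
    p, r, f1, flagged = detection_prf(m)
    assert (p, r, f1) == (0.0, 0.0, 0.0)
    assert flagged


# --------------------------------------------------------------- density


def _full_mask(n=10):
    # 10x10 patches of 256 um = 2.56 x 2.56 mm, fully invasive
    return TumorMask(np.ones((n, n), bool), 1024, 0.25)


def test_no_detections_zero_profile():
    profile = mitotic_density(DetectionSet(np.empty((0, 2)), np.empty(0)), _full_mask(), CFG)
    assert np.all(profile.tile_densities == 0)
    assert np.all(profile.percentile_features == 0)


def test_empty_mask_rejected():
    mask = TumorMask(np.zeros((10, 10), bool), 1024, 0.25)
    with pytest.raises(ValueError, match="invasive"):
        mitotic_density(DetectionSet(np.empty((0, 2)), np.empty(0)), mask, CFG)


def test_uniform_tile_counts_give_constant_features():
    """k detections in every tile -> all five features equal k / 3.24 mm^-2."""
    # 1.8 x 1.8 mm fully invasive slide: 4 tiles at origins {0, 900}^2; the
    # square [900, 1800)^2 lies inside every tile, so k detections placed
    # there give every tile the same count
    mask = TumorMask(np.ones((9, 9), bool), 800, 0.25)  # 9 * 200 um = 1.8 mm
    pts = np.array([(900.0 + 200.0 * i, 900.0 + 150.0 * i) for i in range(4)])
    det = DetectionSet(pts, np.ones(len(pts)))
    profile = mitotic_density(det, mask, CFG)
    assert len(profile.tile_densities) == 4
    assert np.allclose(profile.tile_densities, 4 / 3.24)
    assert np.allclose(profile.percentile_features, 4 / 3.24)


def test_single_detection_matches_exhaustive_tile_enumeration():
    mask = TumorMask(np.ones((18, 18), bool), 800, 0.25)  # 3.6 x 3.6 mm
    pt = np.array([[1000.0, 700.0]])
    det = DetectionSet(pt, np.ones(1))
    profile = mitotic_density(det, mask, CFG)
    # brute-force tile loop
    expected = []
    for y0 in np.arange(0.0, 3600.0, 900.0):
        for x0 in np.arange(0.0, 3600.0, 900.0):
            inside = (x0 <= pt[0, 0] < x0 + 1800) and (y0 <= pt[0, 1] < y0 + 1800)
            expected.append((1 if inside else 0) / 3.24)
    assert sorted(profile.tile_densities) == pytest.approx(sorted(expected))
    assert profile.percentile_features == pytest.approx(
        np.percentile(expected, [5, 25, 50, 75, 95])
    )


def test_percentile_vector_non_decreasing(rng):
    mask = _full_mask()
    pts = rng.random((40, 2)) * 2560.0
    profile = mitotic_density(DetectionSet(pts, np.ones(40)), mask, CFG)
    assert np.all(np.diff(profile.percentile_features) >= 0)


def test_detections_outside_mask_excluded():
    grid = np.zeros((10, 10), bool)
    grid[:, :5] = True  # left half invasive
    mask = TumorMask(grid, 1024, 0.25)
    inside = [[100.0, 100.0]]
    outside = [[2000.0, 100.0]]  # right half, outside the mask
    det = DetectionSet(np.array(inside + outside), np.ones(2))
    profile = mitotic_density(det, mask, CFG)
    assert profile.tile_densities.max() == pytest.approx(1 / 3.24)
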