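"""Mitotic-figure detection, matching, and density features.

The detector turns the fine-grid mitosis likelihood heatmap into point
detections: threshold at 0.915, morphologically erode with a square
structuring element of cell size (16 um x 16 um), label connected components,
and take each component's centroid as a mitosis location.  Erosion with a
cell-sized element is what separates two partially overlapping mitotic
figures into distinct points.

Detections are evaluated against reference annotations (cell-sized boxes
confirmed by at least two of three raters) by optimal one-to-one matching
within a 16 um radius, and summarised over the invasive mask as mitotic
densities on a sliding 1.8 x 1.8 mm tile lattice with 50% stride, reduced to
the 5th/25th/50th/75th/95th percentile feature vector consumed by the
slide-level mitotic-count classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.measure import label, regionprops
from skimage.morphology import erosion

from .containers import MitosisHeatmap, TumorMask

__all__ = [
    "DetectionConfig",
    "DetectionSet",
    "ReferenceMitoses",
    "MatchResult",
    "DensityProfile",
    "detect_mitoses",
    "match_detections",
    "detection_prf",
    "mitotic_density",
    "se_size_px",
]

DENSITY_PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the detection/matching/density pipeline.

    threshold
        Likelihood cut applied as ``>= threshold``.
    se_size_um
        Side of the square erosion structuring element, microns (about one
        cell).  Converted to pixels by ``ceil(se_size_um / mpp)`` and forced
        odd so the element has a centre pixel.
    match_radius_um
        A detection is a true positive if a reference figure lies within this
        distance.
    tile_um / stride_fraction
        Mitotic-density tile side and relative stride (0.5 = 50% overlap).
    connectivity
        4 or 8; pixel adjacency for connected components.
    density_denominator
        "tile": densities are per full tile area (constant 3.24 mm²);
        "invasive": per invasive area inside the tile.
    tile_inclusion
        "intersect": a tile enters the profile if it touches >=1 mask cell;
        "center": only if its centre falls in a mask cell.
    """

    threshold: float = 0.915
    se_size_um: float = 16.0
    match_radius_um: float = 16.0
    tile_um: float = 1800.0
    stride_fraction: float = 0.5
    connectivity: int = 8
    density_denominator: str = "tile"
    tile_inclusion: str = "intersect"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if min(self.se_size_um, self.match_radius_um, self.tile_um) <= 0:
            raise ValueError("physical sizes must be positive")
        if not 0 < self.stride_fraction <= 1:
            raise ValueError("stride_fraction must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.density_denominator not in ("tile", "invasive"):
            raise ValueError("density_denominator must be 'tile' or 'invasive'")
        if self.tile_inclusion not in ("intersect", "center"):
            raise ValueError("tile_inclusion must be 'intersect' or 'center'")


@dataclass
class DetectionSet:
    """Detected mitotic figures in slide micron coordinates."""

    centroids: np.ndarray  # (n, 2) of (x_um, y_um)
    peak_likelihood: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.peak_likelihood = np.asarray(self.peak_likelihood, dtype=float).reshape(-1)
        if len(self.centroids) != len(self.peak_likelihood):
            raise ValueError("one peak likelihood per centroid")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class ReferenceMitoses:
    """Reference-standard mitoses: cell-sized boxes with rater-positive counts.

    A box is a positive reference iff at least 2 of the 3 raters marked it.
    """

    centers: np.ndarray  # (n, 2) box centres (x_um, y_um)
    rater_counts: np.ndarray  # (n,) ints 0..3
    box_um: float = 16.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.rater_counts = np.asarray(self.rater_counts, dtype=int).reshape(-1)
        if len(self.centers) != len(self.rater_counts):
            raise ValueError("one rater count per box")

    @property
    def positive_centers(self) -> np.ndarray:
        return self.centers[self.rater_counts >= 2]


@dataclass
class MatchResult:
    tp_pairs: list[tuple[int, int]]  # (detection idx, reference idx)
    fp_detections: list[int]
    fn_references: list[int]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_detections)

    @property
    def fn(self) -> int:
        return len(self.fn_references)


@dataclass
class DensityProfile:
    """Per-tile mitotic densities and their percentile summary."""

    tile_densities: np.ndarray
    percentile_features: np.ndarray  # 5-vector, non-decreasing
    tile_origins_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def se_size_px(se_size_um: float, mpp: float) -> int:
    """Structuring-element side in pixels: ceil of the physical size, forced odd."""
    k = math.ceil(se_size_um / mpp)
    return k + 1 if k % 2 == 0 else k


def detect_mitoses(heatmap: MitosisHeatmap, cfg: DetectionConfig = DetectionConfig()) -> DetectionSet:
    """Threshold -> erode -> connected components -> centroids (microns)."""
    if heatmap.grid.size == 0:
        raise ValueError("empty heatmap")
    k = se_size_px(cfg.se_size_um, heatmap.mpp)
    if k > min(heatmap.grid.shape):
        raise ValueError("structuring element larger than heatmap grid")

    binary = heatmap.grid >= cfg.threshold
    # binary erosion: pixel stays on iff every pixel under the (odd) square
    # footprint is on; out-of-grid neighbourhoods count as off
    eroded = erosion(np.pad(binary, k // 2), footprint=np.ones((k, k), dtype=bool))
    eroded = eroded[k // 2 : k // 2 + binary.shape[0], k // 2 : k // 2 + binary.shape[1]]
    labelled = label(eroded, connectivity=2 if cfg.connectivity == 8 else 1)

    centroids = []
    peaks = []
    for region in regionprops(labelled):
        r, c = region.centroid  # mean of member pixel indices
        centroids.append(((c + 0.5) * heatmap.mpp, (r + 0.5) * heatmap.mpp))
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        peaks.append(heatmap.grid[rr, cc].max())
    if not centroids:
        return DetectionSet(np.empty((0, 2)), np.empty(0))
    return DetectionSet(np.array(centroids), np.array(peaks))


def match_detections(
    det: DetectionSet, ref: ReferenceMitoses, cfg: DetectionConfig = DetectionConfig()
) -> MatchResult:
    """Optimal one-to-one assignment of detections to positive references.

    Min-cost maximum-cardinality matching over pairs within
    ``cfg.match_radius_um``; deterministic and independent of input order.
    """
    refs = ref.positive_centers
    n_det, n_ref = len(det), len(refs)
    if n_det == 0 or n_ref == 0:
        return MatchResult([], list(range(n_det)), list(range(n_ref)))

    dist = np.linalg.norm(det.centroids[:, None, :] - refs[None, :, :], axis=2)
    feasible = dist <= cfg.match_radius_um
    # large constant >> any feasible cost: assignment prefers any feasible pair
    big = cfg.match_radius_um * (n_det + n_ref + 1) + dist.max() + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)

    tp_pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    matched_d = {i for i, _ in tp_pairs}
    matched_r = {j for _, j in tp_pairs}
    fp = [i for i in range(n_det) if i not in matched_d]
    fn = [j for j in range(n_ref) if j not in matched_r]
    return MatchResult(tp_pairs, fp, fn)


def detection_prf(match: MatchResult) -> tuple[float, float, float, bool]:
    """Precision, recall, F1; flag is True when a zero denominator forced a 0."""
    tp, fp, fn = match.tp, match.fp, match.fn
    flagged = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1, flagged


def mitotic_density(
    det: DetectionSet, mask: TumorMask, cfg: DetectionConfig = DetectionConfig()
) -> DensityProfile:
    """Mitotic density over a sliding tile lattice covering the invasive mask.

    Tiles of side ``cfg.tile_um`` are laid on a lattice with stride
    ``stride_fraction * tile_um`` starting at the slide origin.  A tile is
    included iff it intersects the invasive mask (or contains a mask cell at
    its centre, per ``tile_inclusion``).  Density is the count of detections
    falling inside both the tile and the mask, divided by the tile area in mm²
    (or the invasive area within the tile).
    """
    if not mask.grid.any():
        raise ValueError("no invasive carcinoma")
    patch_um = mask.patch_um
    h, w = mask.grid.shape
    slide_w, slide_h = w * patch_um, h * patch_um
    tile = cfg.tile_um
    stride = cfg.stride_fraction * tile

    # keep only detections inside the invasive mask
    if len(det):
        cols = np.clip((det.centroids[:, 0] // patch_um).astype(int), 0, w - 1)
        rows = np.clip((det.centroids[:, 1] // patch_um).astype(int), 0, h - 1)
        in_mask = mask.grid[rows, cols]
        pts = det.centroids[in_mask]
    else:
        pts = np.empty((0, 2))

    densities = []
    origins = []
    y0 = 0.0
    while y0 < slide_h:
        x0 = 0.0
        while x0 < slide_w:
            if _tile_included(mask, x0, y0, tile, cfg.tile_inclusion):
                n = int(
                    np.sum(
                        (pts[:, 0] >= x0) & (pts[:, 0] < x0 + tile)
                        & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + tile)
                    )
                )
                if cfg.density_denominator == "tile":
                    area = (tile / 1000.0) ** 2
                else:
                    area = _invasive_area_in_tile_mm2(mask, x0, y0, tile)
                densities.append(n / area if area > 0 else 0.0)
                origins.append((x0, y0))
            x0 += stride
        y0 += stride

    densities_arr = np.asarray(densities, dtype=float)
    features = np.percentile(densities_arr, DENSITY_PERCENTILES, method="linear")
    return DensityProfile(densities_arr, features, np.asarray(origins, dtype=float).reshape(-1, 2))


def _mask_cell_range(mask: TumorMask, x0: float, y0: float, tile: float):
    patch_um = mask.patch_um
    h, w = mask.grid.shape
    c0 = max(0, int(math.floor(x0 / patch_um)))
    c1 = min(w, int(math.ceil((x0 + tile) / patch_um)))
    r0 = max(0, int(math.floor(y0 / patch_um)))
    r1 = min(h, int(math.ceil((y0 + tile) / patch_um)))
    return r0, r1, c0, c1


def _tile_included(mask: TumorMask, x0: float, y0: float, tile: float, rule: str) -> bool:
    if rule == "center":
        cx, cy = x0 + tile / 2, y0 + tile / 2
        c = int(cx // mask.patch_um)
        r = int(cy // mask.patch_um)
        h, w = mask.grid.shape
        return 0 <= r < h and 0 <= c < w and bool(mask.grid[r, c])
    r0, r1, c0, c1 = _mask_cell_range(mask, x0, y0, tile)
    if r0 >= r1 or c0 >= c1:
        return False
    return bool(mask.grid[r0:r1, c0:c1].any())


def _invasive_area_in_tile_mm2(mask: TumorMask, x0: float, y0: float, tile: float) -> float:
    """Exact overlap area between the tile and the True mask cells, mm²."""
    r0, r1, c0, c1 = _mask_cell_range(mask, x0, y0, tile)
    patch_um = mask.patch_um
    total = 0.0
    for r in range(r0, r1):
        oy = min((r + 1) * patch_um, y0 + tile) - max(r * patch_um, y0)
        if oy <= 0:
            continue
        for c in range(c0, c1):
            if not mask.grid[r, c]:
                continue
            ox = min((c + 1) * patch_um, x0 + tile) - max(c * patch_um, x0)
            if ox > 0:
                total += ox * oy
    return total / 1e6
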