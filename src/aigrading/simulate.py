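"""Synthetic cohort generator emulating patch-level grading model outputs.

Real slide-level grading consumes the outputs of patch-level convolutional
models: an invasive-carcinoma likelihood map, a fine mitosis likelihood
heatmap, and per-patch 3-class softmax maps for nuclear pleomorphism and
tubule formation — together with triplicate pathologist panels and
progression-free-interval outcomes.  This module generates all of those with
the statistical structure the downstream analysis assumes, so every stage of
the pipeline is testable without clinical data:

* each case draws a latent component-score triple (MC, NP, TF) from a prior;
* the slide's invasive region is a patch-aligned rectangle of configurable
  area fraction, observed through a noisy 3-class likelihood map whose argmax
  recovers the truth on >99% of patches at default noise;
* mitoses are planted in the invasive region as a hard-core point process at
  a score-dependent rate (defaults 1 / 5 / 15 per mm² for scores 1/2/3) and
  rendered into the heatmap as cell-sized high-likelihood blobs over a
  low-likelihood Beta background plus Gaussian noise;
* NP/TF softmax maps concentrate mass on the true class with logit noise;
* each slide is read by 3 raters drawn from a pool of 10, with labels drawn
  from per-component confusion matrices calibrated so that the expected
  pairwise quadratic kappa matches the moderate inter-pathologist agreement
  observed for slide-level grading (about 0.56 / 0.36 / 0.55 for MC/NP/TF);
* PFI outcomes follow a proportional-hazards model with exponential baseline
  and censoring, grade- and covariate-dependent hazard, and a configurable
  fraction of events relabelled as new primary tumors carrying an earlier
  disease-free-interval time.

A single master seed drives named substreams (scores, slides, raters,
survival, covariates), so enlarging one part of the cohort never perturbs the
draws of another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import RaterPanel
from .containers import INVASIVE_CLASSES, SCORE_CLASSES, LikelihoodMap, MitosisHeatmap
from .mitosis import ReferenceMitoses, se_size_px
from .survival import SurvivalRecord, encode_covariates, records_to_frame

__all__ = [
    "SimulationConfig",
    "GroundTruthSlide",
    "SyntheticCohort",
    "simulate_slide",
    "simulate_rater_panel",
    "simulate_survival",
    "simulate_covariates",
    "simulate_cohort",
    "expected_pairwise_kappa",
    "select_regions",
    "DEFAULT_RATER_CONFUSION",
]

COMPONENTS = ("MC", "NP", "TF")

#: Score priors per component, shaped like the held-out test cohort's
#: slide-level score distributions (MC skewed low, NP mid/high, TF high).
DEFAULT_SCORE_PRIORS = {
    "MC": (0.42, 0.26, 0.32),
    "NP": (0.06, 0.47, 0.47),
    "TF": (0.10, 0.18, 0.72),
}

def _confusion_from_accuracy(a: float) -> np.ndarray:
    """Ordinal confusion row family: keep truth w.p. ``a``, spill mostly to
    the adjacent score (85/15 split from the extremes, symmetric from the
    middle)."""
    m = np.array(
        [
            [a, (1 - a) * 0.85, (1 - a) * 0.15],
            [(1 - a) / 2, a, (1 - a) / 2],
            [(1 - a) * 0.15, (1 - a) * 0.85, a],
        ]
    )
    return m / m.sum(axis=1, keepdims=True)


# Accuracies solved (brentq on expected_pairwise_kappa under
# DEFAULT_SCORE_PRIORS) so the expected pairwise quadratic kappa equals the
# moderate inter-pathologist agreement levels 0.56 / 0.36 / 0.55 for MC/NP/TF.
DEFAULT_RATER_CONFUSION: dict[str, np.ndarray] = {
    "MC": _confusion_from_accuracy(0.739181),
    "NP": _confusion_from_accuracy(0.717875),
    "TF": _confusion_from_accuracy(0.812057),
}


@dataclass
class SimulationConfig:
    """All data-generating knobs of the synthetic cohort.

    Geometry defaults give a 2.56 x 2.56 mm slide of 10 x 10 patches
    (1024 px at 0.25 um/px), with the mitosis heatmap on a 2 um/px fine grid
    — large enough for at least one 1.8 mm density tile while keeping arrays
    small.  Hazard-model defaults emulate a follow-up-rich cohort with the
    mitotic-count effect at hazard ratio 1.30 per score unit.
    """

    seed: int = 0
    n_cases: int = 100
    mpp: float = 0.25
    patch_size_px: int = 1024
    slide_size_um: tuple[float, float] = (2560.0, 2560.0)
    heatmap_mpp: float = 2.0
    true_score_priors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_PRIORS)
    )
    mitoses_per_mm2_by_score: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 5.0, 3: 15.0}
    )
    deterministic_counts: bool = False
    heatmap_noise_sd: float = 0.02
    blob_likelihood: float = 0.99
    background_beta: tuple[float, float] = (1.0, 20.0)
    min_mitosis_separation_um: float = 24.0
    invasive_fraction: float = 0.5
    invasive_logit_gap: float = 2.5
    invasive_logit_sd: float = 0.45
    softmax_logit_gap: float = 2.0
    softmax_logit_sd: float = 1.0
    rater_confusion: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_RATER_CONFUSION.items()}
    )
    rater_pool_size: int = 10
    cox_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "mc_disc": math.log(1.30),
            "er": math.log(0.60),
            "t2": math.log(0.90),
            "t3plus": math.log(2.39),
            "n1plus": math.log(2.10),
            "m1": math.log(14.09),
            "age": math.log(1.01),
        }
    )
    baseline_hazard: float = 1.2e-4  # per day, reference case (score 2, age 58)
    censor_rate: float = 1.5e-4  # per day
    frac_new_primary: float = 0.1

    def __post_init__(self) -> None:
        for comp, prior in self.true_score_priors.items():
            if abs(sum(prior) - 1.0) > 1e-12:
                raise ValueError(f"{comp} score prior must sum to 1")
            if min(prior) < 0:
                raise ValueError("prior probabilities must be non-negative")
        for comp, mat in self.rater_confusion.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (3, 3) or np.any(mat < 0):
                raise ValueError(f"{comp} confusion must be a non-negative 3x3 matrix")
            if np.max(np.abs(mat.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"{comp} confusion rows must sum to 1")
            self.rater_confusion[comp] = mat
        if any(r < 0 for r in self.mitoses_per_mm2_by_score.values()):
            raise ValueError("mitosis rates must be non-negative")
        if min(self.baseline_hazard, self.censor_rate) < 0:
            raise ValueError("hazard rates must be non-negative")
        patch_um = self.patch_size_px * self.mpp
        for dim in self.slide_size_um:
            if dim <= 0 or abs(dim / patch_um - round(dim / patch_um)) > 1e-9:
                raise ValueError("slide dimensions must be positive multiples of the patch size")

    @property
    def patch_um(self) -> float:
        return self.patch_size_px * self.mpp

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            int(round(self.slide_size_um[1] / self.patch_um)),
            int(round(self.slide_size_um[0] / self.patch_um)),
        )


@dataclass
class GroundTruthSlide:
    """One synthetic slide: latent truth plus emulated patch-level outputs."""

    slide_id: str
    true_component_scores: dict[str, int]
    invasive_mask_truth: np.ndarray  # bool, patch grid
    planted_mitoses: np.ndarray  # (n, 2) microns
    invasive_map: LikelihoodMap
    mitosis_heatmap: MitosisHeatmap
    np_softmax: LikelihoodMap
    tf_softmax: LikelihoodMap


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    slides: list[GroundTruthSlide]
    slide_panels: dict[str, dict[str, RaterPanel]]  # component -> slide_id -> panel
    region_panels: dict[str, dict[str, RaterPanel]]  # component -> region_id -> panel
    regions: dict[str, list[tuple[float, float]]]  # slide_id -> 1x1 mm window origins
    reference_mitoses: dict[str, ReferenceMitoses]
    survival: list[SurvivalRecord]
    covariates: pd.DataFrame  # per case, indexed by case_id
    truth: pd.DataFrame  # per case true component scores

    def true_scores_frame(self) -> pd.DataFrame:
        return self.truth.copy()


# --------------------------------------------------------------------------
# analytic agreement helper (used to calibrate confusion defaults and as the
# closed-form oracle for panel-noise tests)


def expected_pairwise_kappa(
    prior, confusion, weighting: str = "quadratic"
) -> float:
    """Expected weighted kappa between two raters sharing a latent truth.

    Both raters draw labels independently from ``confusion[truth]`` with
    truth ~ ``prior``; the population contingency table is
    ``sum_t prior_t outer(C_t, C_t)`` and kappa follows from the weighted
    observed/expected disagreement of that table.
    """
    prior = np.asarray(prior, dtype=float)
    conf = np.asarray(confusion, dtype=float)
    k = len(prior)
    joint = np.einsum("t,ti,tj->ij", prior, conf, conf)
    marg = prior @ conf
    expected = np.outer(marg, marg)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weighting == "quadratic":
        w = ((i - j) / (k - 1)) ** 2
    elif weighting == "linear":
        w = np.abs(i - j) / (k - 1)
    else:
        w = (i != j).astype(float)
    return 1.0 - float((w * joint).sum()) / float((w * expected).sum())


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


_SCORES, _SLIDES, _RATERS, _SURVIVAL, _COVARIATES = range(5)


# --------------------------------------------------------------------------
# slide generation


def simulate_slide(
    config: SimulationConfig, true_scores: dict[str, int], seed: int
) -> GroundTruthSlide:
    """Generate one slide's ground truth and emulated patch-level outputs.

    The mitosis heatmap renders each planted mitosis as a filled square blob
    of high likelihood whose pixel footprint equals the detector's
    (forced-odd) structuring element, over a Beta(1, 20) background, with
    additive Gaussian noise of ``heatmap_noise_sd`` everywhere — separable at
    the 0.915 threshold yet exercising it.
    """
    for comp in COMPONENTS:
        if true_scores[comp] not in (1, 2, 3):
            raise ValueError("component scores must be in {1, 2, 3}")
    if min(config.slide_size_um) < 1800.0:
        raise ValueError("slide too small for a 1.8 mm density tile")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed

    mask = _invasive_rectangle(config, rng)
    area_mm2 = mask.sum() * (config.patch_um / 1000.0) ** 2
    rate = config.mitoses_per_mm2_by_score[true_scores["MC"]]
    if area_mm2 == 0 and rate > 0:
        raise ValueError("no tumor to plant in")

    n_mitoses = (
        int(round(rate * area_mm2))
        if config.deterministic_counts
        else int(rng.poisson(rate * area_mm2))
    )
    points = _plant_points(config, mask, n_mitoses, rng)

    heatmap = _render_heatmap(config, points, rng)
    invasive_map = _invasive_likelihood(config, mask, rng)
    np_map = _score_softmax_map(config, mask, true_scores["NP"], rng)
    tf_map = _score_softmax_map(config, mask, true_scores["TF"], rng)

    return GroundTruthSlide(
        slide_id="",
        true_component_scores=dict(true_scores),
        invasive_mask_truth=mask,
        planted_mitoses=points,
        invasive_map=invasive_map,
        mitosis_heatmap=heatmap,
        np_softmax=np_map,
        tf_softmax=tf_map,
    )


def _invasive_rectangle(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Patch-aligned invasive region of exactly round(fraction * cells) cells."""
    h, w = config.grid_shape
    k = int(round(config.invasive_fraction * h * w))
    mask = np.zeros((h, w), dtype=bool)
    if k == 0:
        return mask
    bh = min(h, max(1, int(round(math.sqrt(k)))))
    bw = min(w, math.ceil(k / bh))
    while bh * bw < k:  # grow if clipped by the grid
        bh = min(h, bh + 1)
        if bh * bw >= k:
            break
        bw = min(w, bw + 1)
        if bh == h and bw == w:
            break
    r0 = int(rng.integers(0, h - bh + 1))
    c0 = int(rng.integers(0, w - bw + 1))
    block = np.zeros(bh * bw, dtype=bool)
    block[:k] = True  # trim the excess from the raster tail
    mask[r0 : r0 + bh, c0 : c0 + bw] = block.reshape(bh, bw)
    return mask


def _plant_points(
    config: SimulationConfig, mask: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Hard-core uniform points inside invasive cells, blob-safe at the edges."""
    if n == 0:
        return np.empty((0, 2))
    rows, cols = np.nonzero(mask)
    patch_um = config.patch_um
    half_blob = (se_size_px(16.0, config.heatmap_mpp) // 2 + 1) * config.heatmap_mpp
    width, height = config.slide_size_um
    sep2 = config.min_mitosis_separation_um**2
    points: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(points) < n and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(0, len(rows)))
        x = (cols[i] + rng.random()) * patch_um
        y = (rows[i] + rng.random()) * patch_um
        x = float(np.clip(x, half_blob, width - half_blob))
        y = float(np.clip(y, half_blob, height - half_blob))
        if all((x - px) ** 2 + (y - py) ** 2 >= sep2 for px, py in points):
            points.append((x, y))
    if len(points) < n:
        raise RuntimeError("could not place mitoses with the requested separation")
    return np.asarray(points)


def _render_heatmap(
    config: SimulationConfig, points: np.ndarray, rng: np.random.Generator
) -> MitosisHeatmap:
    mpp = config.heatmap_mpp
    shape = (
        int(round(config.slide_size_um[1] / mpp)),
        int(round(config.slide_size_um[0] / mpp)),
    )
    a, b = config.background_beta
    grid = rng.beta(a, b, size=shape)
    k = se_size_px(16.0, mpp)
    half = k // 2
    for x, y in points:
        r = int(y // mpp)
        c = int(x // mpp)
        grid[r - half : r + half + 1, c - half : c + half + 1] = config.blob_likelihood
    if config.heatmap_noise_sd > 0:
        grid = grid + rng.normal(0.0, config.heatmap_noise_sd, size=shape)
    return MitosisHeatmap(np.clip(grid, 0.0, 1.0), mpp)


def _noisy_softmax(
    rng: np.random.Generator, shape: tuple[int, int], true_class: np.ndarray,
    gap: float, sd: float,
) -> np.ndarray:
    """Per-cell softmax of (gap * onehot(true) + Gaussian logit noise)."""
    logits = rng.normal(0.0, sd, size=shape + (3,))
    onehot = np.eye(3)[true_class]
    logits = logits + gap * onehot
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=2, keepdims=True)


def _invasive_likelihood(
    config: SimulationConfig, mask: np.ndarray, rng: np.random.Generator
) -> LikelihoodMap:
    true_class = np.where(mask, 2, 0)  # invasive vs non_tumor truth
    grid = _noisy_softmax(rng, mask.shape, true_class,
                          config.invasive_logit_gap, config.invasive_logit_sd)
    return LikelihoodMap(grid, INVASIVE_CLASSES, config.patch_size_px, config.mpp)


def _score_softmax_map(
    config: SimulationConfig, mask: np.ndarray, score: int, rng: np.random.Generator
) -> LikelihoodMap:
    true_class = np.full(mask.shape, score - 1)
    grid = _noisy_softmax(rng, mask.shape, true_class,
                          config.softmax_logit_gap, config.softmax_logit_sd)
    # outside the invasive region the signal is absent (pure noise)
    noise = _noisy_softmax(rng, mask.shape, true_class, 0.0, config.softmax_logit_sd)
    grid = np.where(mask[:, :, None], grid, noise)
    return LikelihoodMap(grid, SCORE_CLASSES, config.patch_size_px, config.mpp)


# --------------------------------------------------------------------------
# raters


def simulate_rater_panel(
    truth: dict[str, int],
    confusion: dict[str, np.ndarray],
    rng: np.random.Generator,
    unit_id: str,
    rater_pool_size: int = 10,
) -> dict[str, RaterPanel]:
    """Triplicate panels for one unit: 3 raters from the pool score each component.

    The same three raters score all components of the unit; each label is
    drawn independently from the component's confusion row for the true score.
    """
    raters = rng.choice(rater_pool_size, size=3, replace=False)
    panels = {}
    for comp in COMPONENTS:
        row = np.asarray(confusion[comp])[truth[comp] - 1]
        labels = [
            (f"rater{int(r):02d}", int(rng.choice(3, p=row) + 1)) for r in raters
        ]
        panels[comp] = RaterPanel(unit_id, comp, labels)
    return panels


def select_regions(
    slide: GroundTruthSlide, region_um: float = 1000.0, n_regions: int = 3
) -> list[tuple[float, float]]:
    """The three non-overlapping 1 x 1 mm windows richest in planted mitoses.

    Candidate windows sit on a half-region lattice; windows are picked
    greedily by planted count with ties broken in raster order, rejecting
    overlap with already-picked windows.
    """
    width, height = (
        slide.invasive_mask_truth.shape[1] * slide.invasive_map.patch_um,
        slide.invasive_mask_truth.shape[0] * slide.invasive_map.patch_um,
    )
    step = region_um / 2.0
    candidates = []
    y0 = 0.0
    while y0 + region_um <= height + 1e-9:
        x0 = 0.0
        while x0 + region_um <= width + 1e-9:
            pts = slide.planted_mitoses
            count = 0
            if len(pts):
                count = int(
                    np.sum(
                        (pts[:, 0] >= x0) & (pts[:, 0] < x0 + region_um)
                        & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + region_um)
                    )
                )
            candidates.append((count, y0, x0))
            x0 += step
        y0 += step
    # sort by count descending, then raster order (y, x ascending)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen: list[tuple[float, float]] = []
    for _, y0, x0 in candidates:
        if len(chosen) == n_regions:
            break
        if all(
            abs(x0 - cx) >= region_um or abs(y0 - cy) >= region_um for cx, cy in chosen
        ):
            chosen.append((x0, y0))
    return chosen


def _reference_mitoses(
    slide: GroundTruthSlide, rng: np.random.Generator, n_decoys: int = 5
) -> ReferenceMitoses:
    """Reference boxes: planted mitoses (2-3 rater-positive) plus sub-majority decoys."""
    pts = slide.planted_mitoses
    counts = rng.choice([2, 3], size=len(pts), p=[0.2, 0.8])
    width, height = (
        slide.invasive_mask_truth.shape[1] * slide.invasive_map.patch_um,
        slide.invasive_mask_truth.shape[0] * slide.invasive_map.patch_um,
    )
    decoys = rng.random((n_decoys, 2)) * [width, height]
    centers = np.vstack([pts.reshape(-1, 2), decoys])
    counts = np.concatenate([counts, rng.choice([0, 1], size=n_decoys)])
    return ReferenceMitoses(centers, counts)


# --------------------------------------------------------------------------
# survival


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariates with registry-like marginals.

    Age ~ Normal(58, 13) truncated to [25, 90]; ER positive 77%;
    T1/T2/T3+ at 27/57/16%; N0/N1/N2+ at 50/32/18%; M1 1.6%.
    """
    age = rng.normal(58.0, 13.0, size=4 * n)
    age = age[(age >= 25) & (age <= 90)][:n]
    while len(age) < n:  # pragma: no cover - pathological truncation
        extra = rng.normal(58.0, 13.0, size=n)
        age = np.concatenate([age, extra[(extra >= 25) & (extra <= 90)]])[:n]
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "er": rng.choice([0, 1], size=n, p=[0.23, 0.77]),
            "t_cat": rng.choice(["T1", "T2", "T3plus"], size=n, p=[0.27, 0.57, 0.16]),
            "n_cat": rng.choice(["N0", "N1", "N2plus"], size=n, p=[0.50, 0.32, 0.18]),
            "m_cat": rng.choice([0, 1], size=n, p=[0.984, 0.016]),
        }
    )


def simulate_survival(
    table: pd.DataFrame, config: SimulationConfig, seed: int | np.random.Generator
) -> list[SurvivalRecord]:
    """PFI outcomes from a proportional-hazards model on scores + covariates.

    The hazard is ``baseline_hazard * exp(lp)`` with the linear predictor
    summing ``cox_log_hr`` over centred features (component scores centred at
    2, age at 58, indicator covariates as-is); censoring is independent
    exponential at ``censor_rate``.  Exactly
    ``round(frac_new_primary * n_events)`` events are relabelled as new
    primaries with a DFI time drawn uniformly below the PFI time.

    ``table`` needs columns mc_disc/np_disc/tf_disc plus the baseline
    covariate columns (age, er, t_cat, n_cat, m_cat) and case_id.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if table[["age", "er", "t_cat", "n_cat", "m_cat"]].isna().any().any():
        raise ValueError("every case needs complete covariates")
    encoded = encode_covariates(table)
    centred = {
        "age": encoded["age"] - 58.0,
        "er": encoded["er"],
        "t2": encoded["t2"],
        "t3plus": encoded["t3plus"],
        "n1plus": encoded["n1plus"],
        "m1": encoded["m1"],
    }
    for comp in ("mc", "np", "tf"):
        col = f"{comp}_disc"
        if col in table.columns:
            centred[col] = table[col].astype(float) - 2.0
    lp = np.zeros(len(table))
    for feat, loghr in config.cox_log_hr.items():
        if feat not in centred:
            raise ValueError(f"cox_log_hr names unknown feature {feat}")
        lp += loghr * np.asarray(centred[feat], dtype=float)

    hazard = config.baseline_hazard * np.exp(lp)
    if np.any(hazard < 0):
        raise ValueError("negative hazard rate")
    t_event = rng.exponential(1.0 / np.maximum(hazard, 1e-300))
    t_cens = (
        rng.exponential(1.0 / config.censor_rate, size=len(table))
        if config.censor_rate > 0
        else np.full(len(table), np.inf)
    )
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1.0)  # follow-up recorded in whole positive days

    event_idx = np.flatnonzero(event == 1)
    n_new = int(round(config.frac_new_primary * len(event_idx)))
    new_primary_idx = set(
        rng.choice(event_idx, size=n_new, replace=False).tolist() if n_new else []
    )

    records = []
    for i, row in enumerate(table.itertuples(index=False)):
        if event[i] and i in new_primary_idx:
            etype = "new_primary"
            dfi = float(time[i] * rng.uniform(0.4, 0.95))
        else:
            etype = "progression" if event[i] else "censored"
            dfi = None
        records.append(
            SurvivalRecord(
                case_id=str(row.case_id),
                time_days=float(time[i]),
                event=int(event[i]),
                event_type=etype,
                dfi_days=dfi,
                age=float(row.age),
                er=int(row.er),
                t_cat=str(row.t_cat),
                n_cat=str(row.n_cat),
                m_cat=int(row.m_cat),
            )
        )
    return records


# --------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full synthetic cohort: slides, panels, reference mitoses, outcomes.

    Identical configs (including the seed) produce byte-identical cohorts.
    """
    score_rng = _substream(config.seed, _SCORES)
    rater_rng = _substream(config.seed, _RATERS)
    cov_rng = _substream(config.seed, _COVARIATES)
    surv_rng = _substream(config.seed, _SURVIVAL)

    n = config.n_cases
    truth_rows = {}
    for comp in COMPONENTS:
        prior = config.true_score_priors[comp]
        truth_rows[comp] = score_rng.choice([1, 2, 3], size=n, p=prior)

    case_ids = [f"case{i:04d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "case_id": case_ids,
            "mc_true": truth_rows["MC"],
            "np_true": truth_rows["NP"],
            "tf_true": truth_rows["TF"],
        }
    ).set_index("case_id")

    slides = []
    slide_panels: dict[str, dict[str, RaterPanel]] = {c: {} for c in COMPONENTS}
    region_panels: dict[str, dict[str, RaterPanel]] = {c: {} for c in COMPONENTS}
    regions: dict[str, list[tuple[float, float]]] = {}
    reference: dict[str, ReferenceMitoses] = {}

    for i, case_id in enumerate(case_ids):
        true_scores = {
            "MC": int(truth_rows["MC"][i]),
            "NP": int(truth_rows["NP"][i]),
            "TF": int(truth_rows["TF"][i]),
        }
        slide_rng = _substream(config.seed, _SLIDES, i)
        slide = simulate_slide(config, true_scores, slide_rng)
        slide = replace(slide, slide_id=f"slide{i:04d}")
        slides.append(slide)

        panels = simulate_rater_panel(
            true_scores, config.rater_confusion, rater_rng, slide.slide_id,
            config.rater_pool_size,
        )
        for comp in COMPONENTS:
            slide_panels[comp][slide.slide_id] = panels[comp]

        regions[slide.slide_id] = select_regions(slide)
        for j in range(len(regions[slide.slide_id])):
            region_id = f"{slide.slide_id}:roi{j}"
            rpanels = simulate_rater_panel(
                true_scores, config.rater_confusion, rater_rng, region_id,
                config.rater_pool_size,
            )
            for comp in COMPONENTS:
                region_panels[comp][region_id] = rpanels[comp]

        reference[slide.slide_id] = _reference_mitoses(slide, rater_rng)

    covariates = simulate_covariates(n, cov_rng)
    covariates.insert(0, "case_id", case_ids)
    surv_table = covariates.copy()
    surv_table["mc_disc"] = truth_rows["MC"]
    surv_table["np_disc"] = truth_rows["NP"]
    surv_table["tf_disc"] = truth_rows["TF"]
    survival = simulate_survival(surv_table, config, surv_rng)

    return SyntheticCohort(
        config=config,
        slides=slides,
        slide_panels=slide_panels,
        region_panels=region_panels,
        regions=regions,
        reference_mitoses=reference,
        survival=survival,
        covariates=covariates.set_index("case_id"),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the cohort in the on-disk layout the CLI consumes.

    Per slide: PNG16+JSON likelihood containers; plus ``annotations.json``
    (planted mitoses in microns, rater panels, regions) and ``cohort.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for slide in cohort.slides:
        base = out / slide.slide_id
        slide.invasive_map.save(base / "invasive")
        slide.mitosis_heatmap.save(base / "mitosis")
        slide.np_softmax.save(base / "np")
        slide.tf_softmax.save(base / "tf")

    annotations = {
        "mitoses_um": {
            s.slide_id: np.asarray(s.planted_mitoses).tolist() for s in cohort.slides
        },
        "reference_boxes": {
            sid: {
                "centers_um": ref.centers.tolist(),
                "rater_counts": ref.rater_counts.tolist(),
            }
            for sid, ref in cohort.reference_mitoses.items()
        },
        "regions_um": {sid: r for sid, r in cohort.regions.items()},
        "slide_panels": {
            comp: {
                sid: panel.labels for sid, panel in cohort.slide_panels[comp].items()
            }
            for comp in COMPONENTS
        },
        "region_panels": {
            comp: {
                rid: panel.labels for rid, panel in cohort.region_panels[comp].items()
            }
            for comp in COMPONENTS
        },
    }
    (out / "annotations.json").write_text(json.dumps(annotations))

    frame = records_to_frame(cohort.survival)
    frame = frame.merge(cohort.truth.reset_index(), on="case_id")
    frame = frame.merge(cohort.covariates.reset_index(), on="case_id", suffixes=("", "_cov"))
    frame.to_csv(out / "cohort.csv", index=False)
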