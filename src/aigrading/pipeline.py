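"""End-to-end orchestration: stage-1 maps -> slide scores -> grade summary.

Glue used by the CLI, the test suite and reproduction scripts: run the
detection and feature-extraction path over a synthetic cohort, fit the
stage-2 classifiers on one subset of slides against majority-vote labels,
and score another subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import NO_MAJORITY, majority_vote
from .containers import TumorMask
from .grading import (
    ComponentScore,
    SlideFeatures,
    Stage2Model,
    combine_scores,
    extract_features,
    fit_stage2,
    predict_component,
)
from .masking import compute_tumor_mask
from .mitosis import DetectionConfig, detect_mitoses, mitotic_density
from .simulate import COMPONENTS, SyntheticCohort

__all__ = ["slide_features", "fit_cohort_models", "score_cohort", "CohortScores"]


def slide_features(slide, cfg: DetectionConfig = DetectionConfig()) -> tuple[SlideFeatures, TumorMask]:
    """Stage-1 outputs of one slide to stage-2 features (mask-restricted)."""
    mask = compute_tumor_mask(slide.invasive_map)
    det = detect_mitoses(slide.mitosis_heatmap, cfg)
    density = mitotic_density(det, mask, cfg)
    return extract_features(density, slide.np_softmax, slide.tf_softmax, mask), mask


@dataclass
class CohortScores:
    """Per-slide component scores and grade summaries."""

    table: pd.DataFrame  # indexed by slide_id
    class_probs: dict[str, dict[str, np.ndarray]]  # component -> slide_id -> probs


def _feature_matrix(features: list[SlideFeatures], component: str) -> np.ndarray:
    if component == "MC":
        return np.stack([f.mc for f in features])
    if component == "NP":
        return np.stack([f.np_mean_softmax for f in features])
    return np.stack([f.tf_mean_softmax for f in features])


def fit_cohort_models(
    cohort: SyntheticCohort,
    slide_ids: list[str],
    cfg: DetectionConfig = DetectionConfig(),
    cv_seed: int = 0,
) -> dict[str, Stage2Model]:
    """Fit the three stage-2 models on majority-vote labels of the given slides.

    Slides without a rater majority for a component are excluded from that
    component's training set (mirroring reference-standard construction).
    """
    by_id = {s.slide_id: s for s in cohort.slides}
    feats = {sid: slide_features(by_id[sid], cfg)[0] for sid in slide_ids}
    models = {}
    for comp, kind in (("MC", "logistic"), ("NP", "ridge"), ("TF", "ridge")):
        rows, labels = [], []
        for sid in slide_ids:
            vote = majority_vote(cohort.slide_panels[comp][sid])
            if vote is NO_MAJORITY:
                continue
            rows.append(feats[sid])
            labels.append(int(vote))
        X = _feature_matrix(rows, comp)
        models[comp] = fit_stage2(X, np.asarray(labels), kind, cv_seed, component=comp)
    return models


def score_cohort(
    cohort: SyntheticCohort,
    models: dict[str, Stage2Model],
    slide_ids: list[str] | None = None,
    cfg: DetectionConfig = DetectionConfig(),
) -> CohortScores:
    """Apply fitted stage-2 models to slides, returning the score table."""
    by_id = {s.slide_id: s for s in cohort.slides}
    ids = slide_ids if slide_ids is not None else [s.slide_id for s in cohort.slides]
    rows = []
    probs: dict[str, dict[str, np.ndarray]] = {c: {} for c in COMPONENTS}
    for sid in ids:
        features, _ = slide_features(by_id[sid], cfg)
        scores: dict[str, ComponentScore] = {}
        for comp in COMPONENTS:
            x = _feature_matrix([features], comp)[0]
            scores[comp] = predict_component(models[comp], x, component=comp)
            if scores[comp].class_probs.size:
                probs[comp][sid] = scores[comp].class_probs
        summary = combine_scores(scores["MC"], scores["NP"], scores["TF"])
        rows.append(
            {
                "slide_id": sid,
                "mc_disc": scores["MC"].discrete,
                "mc_cont": scores["MC"].continuous,
                "np_disc": scores["NP"].discrete,
                "np_cont": scores["NP"].continuous,
                "tf_disc": scores["TF"].discrete,
                "tf_cont": scores["TF"].continuous,
                "sum_disc": summary.summed_discrete,
                "sum_cont": summary.summed_continuous,
                "combined_grade": summary.combined_grade,
            }
        )
    return CohortScores(pd.DataFrame(rows).set_index("slide_id"), probs)
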