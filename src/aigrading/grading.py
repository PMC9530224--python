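"""Stage-2 slide-level scoring of the three Nottingham components.

Patch-level outputs are aggregated into compact slide features — the five
mitotic-density percentiles for mitotic count (MC), and the mean softmax
vector over invasive patches for nuclear pleomorphism (NP) and tubule
formation (TF).  A lightweight regularized classifier per component maps
features to a component score: multinomial logistic regression for MC, ridge
regression on the numeric labels 1/2/3 for NP and TF, each with its L2
strength chosen by five-fold cross-validation on the training slides.

Each component yields both a discrete score in {1,2,3} and a continuous score
in [1,3] (expected class value for logistic; the clipped prediction for
ridge).  The three scores combine into the summed score (3-9) and combined
histologic grade (3-5 -> grade 1, 6-7 -> grade 2, 8-9 -> grade 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import log_loss, mean_squared_error
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import LikelihoodMap, TumorMask
from .mitosis import DensityProfile

__all__ = [
    "SlideFeatures",
    "ComponentScore",
    "GradeSummary",
    "Stage2Model",
    "extract_features",
    "fit_stage2",
    "predict_component",
    "combine_scores",
    "patch_level_prediction",
    "REGULARIZATION_GRID",
]

#: 13 logarithmically spaced L2 strengths searched by 5-fold CV
REGULARIZATION_GRID = tuple(float(a) for a in np.logspace(-3, 3, 13))


@dataclass
class SlideFeatures:
    """Per-slide stage-2 inputs for the three components."""

    mc: np.ndarray  # 5 density percentiles
    np_mean_softmax: np.ndarray  # mean 3-vector over invasive patches
    tf_mean_softmax: np.ndarray

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc, dtype=float).reshape(-1)
        self.np_mean_softmax = np.asarray(self.np_mean_softmax, dtype=float).reshape(-1)
        self.tf_mean_softmax = np.asarray(self.tf_mean_softmax, dtype=float).reshape(-1)
        if self.mc.shape != (5,):
            raise ValueError("mc feature must be the 5 density percentiles")
        for v in (self.np_mean_softmax, self.tf_mean_softmax):
            if v.shape != (3,):
                raise ValueError("softmax means must be 3-vectors")


@dataclass
class ComponentScore:
    component: str  # "MC" | "NP" | "TF"
    discrete: int
    continuous: float
    class_probs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.component not in ("MC", "NP", "TF"):
            raise ValueError("component must be MC, NP or TF")
        if self.discrete not in (1, 2, 3):
            raise ValueError("discrete score must be 1, 2 or 3")
        if not 1.0 <= self.continuous <= 3.0:
            raise ValueError("continuous score must lie in [1, 3]")
        self.class_probs = np.asarray(self.class_probs, dtype=float).reshape(-1)


@dataclass
class GradeSummary:
    summed_discrete: int  # 3..9
    summed_continuous: float  # [3, 9]
    combined_grade: int  # 1..3


@dataclass
class Stage2Model:
    """Fitted slide-level classifier for one component.

    Stores the standardization parameters and coefficients so the model can be
    serialized to JSON and re-applied without scikit-learn estimator state.
    """

    component: str
    kind: str  # "logistic" | "ridge"
    coef: np.ndarray  # logistic: (3, d); ridge: (d,)
    intercept: np.ndarray  # logistic: (3,); ridge: (1,)
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    alpha: float  # selected L2 strength (ridge alpha; logistic C = 1/alpha)
    cv_seed: int
    degenerate: bool = False  # ridge fitted on constant labels

    def to_json(self) -> str:
        return json.dumps(
            {
                "component": self.component,
                "kind": self.kind,
                "coef": np.asarray(self.coef).tolist(),
                "intercept": np.asarray(self.intercept).tolist(),
                "feature_mean": self.feature_mean.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "alpha": self.alpha,
                "cv_seed": self.cv_seed,
                "degenerate": self.degenerate,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Stage2Model":
        d = json.loads(text)
        return cls(
            component=d["component"],
            kind=d["kind"],
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_scale=np.asarray(d["feature_scale"], dtype=float),
            alpha=float(d["alpha"]),
            cv_seed=int(d["cv_seed"]),
            degenerate=bool(d["degenerate"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Stage2Model":
        return cls.from_json(Path(path).read_text())


def extract_features(
    density: DensityProfile,
    np_softmax_map: LikelihoodMap,
    tf_softmax_map: LikelihoodMap,
    mask: TumorMask,
) -> SlideFeatures:
    """Slide features from stage-1 outputs, pooled over the invasive mask only."""
    if not mask.grid.any():
        raise ValueError("no invasive carcinoma")
    np_mean = _masked_mean_softmax(np_softmax_map, mask)
    tf_mean = _masked_mean_softmax(tf_softmax_map, mask)
    return SlideFeatures(density.percentile_features, np_mean, tf_mean)


def _masked_mean_softmax(softmax_map: LikelihoodMap, mask: TumorMask) -> np.ndarray:
    if softmax_map.shape != mask.shape:
        raise ValueError("softmax map and mask grids must align")
    return softmax_map.grid[mask.grid].mean(axis=0)


def fit_stage2(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str,
    cv_seed: int = 0,
    component: str | None = None,
) -> Stage2Model:
    """Fit a component classifier with CV-selected L2 regularization.

    Features are standardized to zero mean / unit variance on the training
    set.  The L2 strength minimizing mean 5-fold CV loss (log-loss for
    logistic, MSE for ridge on the numeric labels) over
    ``REGULARIZATION_GRID`` is refitted on all slides.  Folds are stratified
    by label and shuffled with ``cv_seed``, so refits are deterministic.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) aligned with labels")
    if not np.isin(y, (1, 2, 3)).all():
        raise ValueError("labels must be component scores in {1, 2, 3}")
    if kind not in ("logistic", "ridge"):
        raise ValueError("kind must be 'logistic' or 'ridge'")

    degenerate = len(np.unique(y)) < 2
    if degenerate and kind == "logistic":
        raise ValueError("logistic stage-2 requires at least 2 distinct labels")
    comp = component or ("MC" if kind == "logistic" else "NP")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    if degenerate:  # ridge on constant labels: constant prediction, flagged
        est = Ridge(alpha=1.0).fit(Z, y.astype(float))
        return Stage2Model(comp, kind, est.coef_, np.atleast_1d(est.intercept_),
                           mean, scale, 1.0, cv_seed, degenerate=True)

    best_alpha, best_loss = None, np.inf
    for alpha in REGULARIZATION_GRID:
        losses = []
        for train, test in _cv_splits(y, kind, cv_seed):
            if kind == "logistic":
                est = LogisticRegression(C=1.0 / alpha, max_iter=2000)
                est.fit(Z[train], y[train])
                p = est.predict_proba(Z[test])
                losses.append(log_loss(y[test], p, labels=est.classes_))
            else:
                est = Ridge(alpha=alpha).fit(Z[train], y[train].astype(float))
                losses.append(mean_squared_error(y[test], est.predict(Z[test])))
        cv = float(np.mean(losses))
        if cv < best_loss - 1e-12:
            best_loss, best_alpha = cv, alpha

    if kind == "logistic":
        est = LogisticRegression(C=1.0 / best_alpha, max_iter=5000).fit(Z, y)
        coef = _expand_logistic_coef(est.coef_, est.intercept_, est.classes_)[0]
        intercept = _expand_logistic_coef(est.coef_, est.intercept_, est.classes_)[1]
    else:
        est = Ridge(alpha=best_alpha).fit(Z, y.astype(float))
        coef, intercept = est.coef_, np.atleast_1d(est.intercept_)

    return Stage2Model(comp, kind, np.asarray(coef), np.asarray(intercept),
                       mean, scale, float(best_alpha), cv_seed)


def _cv_splits(y: np.ndarray, kind: str, cv_seed: int):
    """5-fold splits, stratified by label where every class allows it."""
    counts = np.bincount(y)[1:]
    if counts[counts > 0].min() >= 5:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=cv_seed)
        return cv.split(np.zeros(len(y)), y)
    cv = KFold(n_splits=5, shuffle=True, random_state=cv_seed)
    return cv.split(np.zeros(len(y)))


def _expand_logistic_coef(coef, intercept, classes):
    """Rows for all three scores; classes absent in training get -inf logits.

    With two classes scikit-learn uses the binary parameterization (one row:
    the logit of the second class against the first), which expands to rows
    (0, coef) for the observed classes.
    """
    full_coef = np.zeros((3, coef.shape[1]))
    full_int = np.full(3, -np.inf)
    if len(classes) == 2:
        lo, hi = (int(c) for c in classes)
        full_coef[lo - 1] = 0.0
        full_int[lo - 1] = 0.0
        full_coef[hi - 1] = coef[0]
        full_int[hi - 1] = intercept[0]
        return full_coef, full_int
    for row, c in enumerate(classes):
        full_coef[int(c) - 1] = coef[row]
        full_int[int(c) - 1] = intercept[row]
    return full_coef, full_int


def predict_component(model: Stage2Model, features: np.ndarray, component: str | None = None) -> ComponentScore:
    """Score one slide: continuous in [1,3], discrete in {1,2,3}.

    Logistic: class probabilities p give continuous = 1 p1 + 2 p2 + 3 p3 and
    discrete = argmax class with ties resolved toward the higher score.
    Ridge: continuous = prediction clipped to [1,3]; discrete by the 1.5/2.5
    thresholds with half-open intervals [1,1.5) -> 1, [1.5,2.5) -> 2,
    [2.5,3] -> 3; class probabilities are not defined.
    """
    x = np.asarray(features, dtype=float).reshape(-1)
    if x.shape[0] != model.feature_mean.shape[0]:
        raise ValueError("feature dimension mismatch")
    z = (x - model.feature_mean) / model.feature_scale
    comp = component or model.component

    if model.kind == "logistic":
        logits = model.coef @ z + model.intercept
        logits = logits - logits.max()
        p = np.exp(logits)
        p /= p.sum()
        continuous = float(np.dot(p, (1.0, 2.0, 3.0)))
        # argmax with ties toward the higher score
        discrete = int(3 - np.argmax(p[::-1]))
        return ComponentScore(comp, discrete, continuous, p)

    raw = float(np.dot(model.coef, z) + model.intercept[0])
    continuous = float(np.clip(raw, 1.0, 3.0))
    discrete = 1 if continuous < 1.5 else (2 if continuous < 2.5 else 3)
    return ComponentScore(comp, discrete, continuous)


def combine_scores(mc: ComponentScore, np_score: ComponentScore, tf: ComponentScore) -> GradeSummary:
    """Summed scores and combined histologic grade (3-5 / 6-7 / 8-9)."""
    summed_discrete = mc.discrete + np_score.discrete + tf.discrete
    summed_continuous = mc.continuous + np_score.continuous + tf.continuous
    return GradeSummary(summed_discrete, summed_continuous, grade_from_sum(summed_discrete))


def grade_from_sum(summed: int) -> int:
    """Combined histologic grade from the discrete summed score."""
    if not 3 <= summed <= 9:
        raise ValueError("summed score must be 3..9")
    if summed <= 5:
        return 1
    if summed <= 7:
        return 2
    return 3


def patch_level_prediction(softmax_map: LikelihoodMap) -> np.ndarray:
    """Per-patch predicted score: argmax class, ties toward the higher score."""
    g = softmax_map.grid
    rev = g[:, :, ::-1]  # reversed so first maximum is the higher score
    return (g.shape[2] - rev.argmax(axis=2)).astype(int)
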