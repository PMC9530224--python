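"""Reference-standard construction and inter-rater agreement analyses.

Each slide (or region of interest) carries three ordinal scores from a
rotating panel of raters.  The majority vote defines the reference standard;
panels split 1/2/3 have no majority and are excluded.  Agreement is measured
by weighted Cohen's kappa — quadratic by default, since confusing score 1
with 3 is a graver error than confusing adjacent scores — both between raters
(one-vs-rest pooling over the panels each rater sat on) and between the
automated grader and the pooled rater labels.  Confidence intervals come from
percentile bootstrap over slides.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NO_MAJORITY",
    "RaterPanel",
    "KappaResult",
    "majority_vote",
    "weighted_kappa",
    "one_vs_rest_agreement",
    "score_combination_profile",
    "bootstrap_ci",
    "patch_level_eval",
]


class _NoMajority:
    """Sentinel for 1/2/3 split panels (excluded from reference standards)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_MAJORITY"

    def __bool__(self) -> bool:
        return False


NO_MAJORITY = _NoMajority()


@dataclass
class RaterPanel:
    """Triplicate ordinal scores for one unit (slide or region)."""

    unit_id: str
    component: str
    labels: list[tuple[str, int]]  # (rater_id, score in {1,2,3})

    def __post_init__(self) -> None:
        raters = [r for r, _ in self.labels]
        if len(set(raters)) != len(raters):
            raise ValueError("rater ids must be distinct within a unit")
        for _, s in self.labels:
            if s not in (1, 2, 3):
                raise ValueError("scores must be in {1, 2, 3}")

    @property
    def scores(self) -> list[int]:
        return [s for _, s in self.labels]


@dataclass
class KappaResult:
    kappa: float
    weighting: str  # "quadratic" | "linear" | "unweighted"
    n_units: int
    ci: tuple[float, float] | None = None
    flagged: bool = False  # zero expected disagreement -> kappa defined as 1


def majority_vote(panel: RaterPanel):
    """Score given by >=2 of the 3 raters, or NO_MAJORITY for a 1/2/3 split."""
    if len(panel.labels) != 3:
        raise ValueError("majority vote requires exactly 3 labels")
    counts = Counter(panel.scores)
    score, n = counts.most_common(1)[0]
    return score if n >= 2 else NO_MAJORITY


def _disagreement_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weighting == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    if weighting == "linear":
        return np.abs(i - j) / (k - 1)
    if weighting == "unweighted":
        return (i != j).astype(float)
    raise ValueError("weighting must be quadratic, linear or unweighted")


def weighted_kappa(a, b, weighting: str = "quadratic", n_classes: int = 3,
                   ci_boot: int = 0, seed: int = 0) -> KappaResult:
    """Weighted Cohen's kappa between two label vectors on classes 1..k.

    kappa = 1 - sum(w O) / sum(w E) with disagreement weights
    w_ij = ((i-j)/(k-1))^2 (quadratic), |i-j|/(k-1) (linear) or 1{i != j}
    (unweighted); O is the observed contingency table and E the product of its
    marginals.  When both raters are constant and identical the expected
    disagreement is zero and kappa is defined as 1 with ``flagged=True``.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("label vectors must be equal-length 1-D with n >= 2")
    k = n_classes
    if not (np.isin(a, np.arange(1, k + 1)).all() and np.isin(b, np.arange(1, k + 1)).all()):
        raise ValueError(f"labels must be in 1..{k}")

    kappa, flagged = _kappa_value(a, b, weighting, k)
    ci = None
    if ci_boot:
        lo, hi = bootstrap_ci(
            lambda idx: _kappa_value(a[idx], b[idx], weighting, k)[0],
            np.arange(len(a)), n_boot=ci_boot, seed=seed, index_statistic=True,
        )
        ci = (lo, hi)
    return KappaResult(float(kappa), weighting, len(a), ci, flagged)


def _kappa_value(a, b, weighting, k):
    n = len(a)
    observed = np.zeros((k, k))
    np.add.at(observed, (a - 1, b - 1), 1.0)
    observed /= n
    expected = observed.sum(axis=1)[:, None] * observed.sum(axis=0)[None, :]
    w = _disagreement_weights(k, weighting)
    denom = float((w * expected).sum())
    if denom == 0.0:
        return 1.0, True
    return 1.0 - float((w * observed).sum()) / denom, False


def one_vs_rest_agreement(
    panels: list[RaterPanel],
    dls_scores: dict[str, int] | None = None,
    weighting: str = "quadratic",
    min_slides: int = 10,
    pooling: str = "pairs",
) -> dict:
    """Per-rater one-vs-rest kappas, plus the automated grader's row.

    For each rater r, pairs (r's label, other rater's label) are pooled over
    every unit r graded (two pairs per unit, ``pooling="pairs"``) and scored by
    weighted kappa; ``pooling="majority"`` instead pairs r's label with the
    majority vote of the other two raters (ties broken toward r's label are
    impossible with two raters, so split pairs contribute both labels).
    The grader row pools (automated score, each rater label) over all units.
    Raters who graded fewer than ``min_slides`` units are excluded with a
    warning.

    Returns a dict with per-rater kappas, their average, and (when
    ``dls_scores`` is given) the grader-vs-raters kappa.
    """
    by_rater: dict[str, list[tuple[int, int]]] = defaultdict(list)
    n_units: Counter = Counter()
    for panel in panels:
        for idx, (rater, score) in enumerate(panel.labels):
            others = [s for j, (_, s) in enumerate(panel.labels) if j != idx]
            n_units[rater] += 1
            if pooling == "pairs":
                by_rater[rater].extend((score, o) for o in others)
            else:  # vs the other two: both pairs if they disagree, one if equal
                if others[0] == others[1]:
                    by_rater[rater].append((score, others[0]))
                else:
                    by_rater[rater].extend((score, o) for o in others)

    rater_kappas: dict[str, KappaResult] = {}
    for rater, pairs in sorted(by_rater.items()):
        if n_units[rater] < min_slides:
            warnings.warn(f"rater {rater} graded {n_units[rater]} units (<{min_slides}); excluded")
            continue
        arr = np.asarray(pairs)
        rater_kappas[rater] = weighted_kappa(arr[:, 0], arr[:, 1], weighting)

    out = {
        "per_rater": rater_kappas,
        "average_inter_rater": float(np.mean([r.kappa for r in rater_kappas.values()]))
        if rater_kappas else np.nan,
    }
    if dls_scores is not None:
        pairs = [
            (dls_scores[p.unit_id], s)
            for p in panels if p.unit_id in dls_scores
            for s in p.scores
        ]
        arr = np.asarray(pairs)
        out["dls_vs_raters"] = weighted_kappa(arr[:, 0], arr[:, 1], weighting)
    return out


def score_combination_profile(
    panels: list[RaterPanel],
    class_probs: dict[str, np.ndarray],
    n_boot: int = 0,
    seed: int = 0,
) -> dict[tuple[int, ...], dict]:
    """Mean model class probabilities per rater-score combination.

    Units are grouped by the unordered multiset of their three rater scores
    (e.g. ``(1, 1, 2)``); per group the mean of each model class probability
    is reported, optionally with a percentile-bootstrap CI over units.  Groups
    with no units are simply absent.
    """
    groups: dict[tuple[int, ...], list[np.ndarray]] = defaultdict(list)
    for panel in panels:
        if panel.unit_id not in class_probs:
            continue
        key = tuple(sorted(panel.scores))
        groups[key].append(np.asarray(class_probs[panel.unit_id], dtype=float))

    out = {}
    for key in sorted(groups):
        probs = np.stack(groups[key])
        entry = {"mean_probs": probs.mean(axis=0), "n": len(probs)}
        if n_boot and len(probs) >= 2:
            cis = [
                bootstrap_ci(lambda idx, c=c: probs[idx, c].mean(),
                             np.arange(len(probs)), n_boot=n_boot, seed=seed,
                             index_statistic=True)
                for c in range(probs.shape[1])
            ]
            entry["ci"] = np.asarray(cis)
        out[key] = entry
    return out


def bootstrap_ci(statistic_fn, units, n_boot: int = 1000, seed: int = 0,
                 index_statistic: bool = False, max_retries: int = 10) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap CI of a statistic over resampled units.

    ``statistic_fn`` receives a resampled array of units (or, with
    ``index_statistic=True``, an integer index array into the original
    units).  A resample on which the statistic raises or returns NaN is
    redrawn up to ``max_retries`` times, after which an error propagates.
    """
    units = np.asarray(units)
    if len(units) < 2:
        raise ValueError("bootstrap needs at least 2 units")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, len(units), size=len(units))
            try:
                val = statistic_fn(idx) if index_statistic else statistic_fn(units[idx])
            except Exception:
                if attempt == max_retries:
                    raise
                continue
            if np.isnan(val):
                if attempt == max_retries:
                    raise ValueError("statistic undefined on resample")
                continue
            stats[b] = val
            break
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def patch_level_eval(
    patch_predictions: np.ndarray,
    region_panels: list[RaterPanel],
    region_slices: dict[str, tuple[slice, slice]],
    weighting: str = "quadratic",
) -> KappaResult:
    """Patch-level kappa against region majority labels broadcast to patches.

    Each annotated region of interest carries a triplicate panel; its majority
    vote is assigned to every patch inside the region (``region_slices`` maps
    unit_id to the (row, col) slices of the prediction grid).  Regions without
    a majority are excluded.
    """
    preds, refs = [], []
    for panel in region_panels:
        vote = majority_vote(panel)
        if vote is NO_MAJORITY:
            continue
        rs, cs = region_slices[panel.unit_id]
        block = np.asarray(patch_predictions)[rs, cs].ravel()
        preds.extend(int(v) for v in block)
        refs.extend([int(vote)] * block.size)
    if not refs:
        raise ValueError("no labelled regions with a majority vote")
    return weighted_kappa(np.asarray(preds), np.asarray(refs), weighting)
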