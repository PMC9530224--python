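"""Prognostic evaluation of grading scores against progression-free interval.

Grading scores (automated or pathologist) are evaluated as risk scores for
the progression-free interval (PFI) endpoint.  Records whose first event is a
new primary tumor are censored at the disease-free-interval (DFI) time.  Cox
proportional-hazards models (Efron tie handling, via lifelines) provide
hazard ratios and likelihood-ratio tests of nested feature sets; Harrell's
c-index measures discrimination, with leave-one-out cross-validation and
per-fold percentile normalization of risk scores for multivariable models.
Non-inferiority of one risk score against another is assessed by paired
bootstrap of the c-index difference with a one-sided 95% lower bound
compared to a pre-specified margin (default 0.075), and the association of
mitotic-count scores with Ki-67 (MKI67) expression is compared by a
case-swap permutation test on the correlation difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "NonInferiorityResult",
    "records_to_frame",
    "frame_to_records",
    "censor_new_primaries",
    "cindex",
    "fit_cox",
    "loo_cv_cindex",
    "likelihood_ratio_test",
    "noninferiority_cindex",
    "correlation_permutation_test",
    "score_configurations",
    "encode_covariates",
    "BASELINE_FEATURES",
]

#: baseline clinicopathologic adjustment set (age continuous, TNM, ER)
BASELINE_FEATURES = ("age", "er", "t2", "t3plus", "n1plus", "m1")


@dataclass
class SurvivalRecord:
    """One case's follow-up, endpoint, and baseline covariates.

    ``event_type`` is "progression", "new_primary" or "censored"; a new
    primary carries the DFI time at which it is censored for PFI analysis.
    Categorical covariates use the reference levels T1 / N0 / M0 / ER-.
    """

    case_id: str
    time_days: float
    event: int
    event_type: str
    dfi_days: float | None = None
    age: float = np.nan
    er: int = 0
    t_cat: str = "T1"
    n_cat: str = "N0"
    m_cat: int = 0

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("time_days must be positive")
        if self.event_type not in ("progression", "new_primary", "censored"):
            raise ValueError("unknown event_type")
        if self.event_type == "new_primary" and self.dfi_days is not None:
            if self.dfi_days > self.time_days:
                raise ValueError("DFI time must not exceed PFI time")


@dataclass
class CoxFit:
    features: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    fitter: CoxPHFitter

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)


@dataclass
class NonInferiorityResult:
    delta: float
    one_sided_lo: float
    margin: float
    conclusion: bool
    n_boot: int


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "time_days": [r.time_days for r in records],
            "event": [r.event for r in records],
            "event_type": [r.event_type for r in records],
            "dfi_days": [r.dfi_days for r in records],
            "age": [r.age for r in records],
            "er": [r.er for r in records],
            "t_cat": [r.t_cat for r in records],
            "n_cat": [r.n_cat for r in records],
            "m_cat": [r.m_cat for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[SurvivalRecord]:
    records = []
    for row in frame.itertuples(index=False):
        dfi = getattr(row, "dfi_days", None)
        records.append(
            SurvivalRecord(
                case_id=str(row.case_id),
                time_days=float(row.time_days),
                event=int(row.event),
                event_type=str(row.event_type),
                dfi_days=None if dfi is None or pd.isna(dfi) else float(dfi),
                age=float(row.age),
                er=int(row.er),
                t_cat=str(row.t_cat),
                n_cat=str(row.n_cat),
                m_cat=int(row.m_cat),
            )
        )
    return records


def censor_new_primaries(records: list[SurvivalRecord]) -> list[SurvivalRecord]:
    """Censor new-primary events at their disease-free-interval time.

    A record whose first event is a new primary tumor does not count as PFI
    progression: it becomes censored (event=0) at ``dfi_days``.  Other records
    pass through unchanged; the operation is idempotent.
    """
    out = []
    for r in records:
        if r.event_type == "new_primary" and r.event == 1:
            if r.dfi_days is None:
                raise ValueError(f"case {r.case_id}: new primary without DFI time")
            out.append(replace(r, event=0, time_days=r.dfi_days))
        else:
            out.append(replace(r))
    return out


def cindex(risk: np.ndarray, records: list[SurvivalRecord]) -> float:
    """Harrell's concordance of a per-case risk score against PFI.

    Comparable pairs order the case with the higher risk before the case with
    the longer event time; risk ties count one half.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.array([r.time_days for r in records])
    events = np.array([r.event for r in records])
    if len(risk) != len(records):
        raise ValueError("one risk value per record")
    if events.sum() == 0:
        raise ValueError("no comparable pairs (no events)")
    # lifelines scores *predicted time* concordance; negate risk so that
    # higher risk ~ shorter predicted survival
    return float(concordance_index(times, -risk, events))


def encode_covariates(frame: pd.DataFrame) -> pd.DataFrame:
    """Design columns for the baseline covariates with T1/N0/M0/ER- reference.

    T3 and T4 merge into ``t3plus``; N1 and higher merge into ``n1plus``
    (``n2plus`` is additionally emitted for finer analyses); metastasis and ER
    are binary indicators.
    """
    out = pd.DataFrame(index=frame.index)
    out["age"] = frame["age"].astype(float)
    out["er"] = frame["er"].astype(int)
    out["t2"] = (frame["t_cat"] == "T2").astype(int)
    out["t3plus"] = frame["t_cat"].isin(["T3", "T4", "T3plus"]).astype(int)
    out["n1plus"] = (frame["n_cat"] != "N0").astype(int)
    out["n2plus"] = frame["n_cat"].isin(["N2", "N3", "N2plus"]).astype(int)
    out["m1"] = frame["m_cat"].astype(int)
    return out


def _design_matrix(records: list[SurvivalRecord], feature_spec: list[str],
                   extra: pd.DataFrame | None) -> pd.DataFrame:
    frame = records_to_frame(records)
    encoded = encode_covariates(frame)
    if extra is not None:
        extra = extra.reset_index(drop=True)
        encoded = pd.concat([encoded, extra], axis=1)
    missing = [f for f in feature_spec if f not in encoded.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    X = encoded[list(feature_spec)].astype(float)
    X["time_days"] = frame["time_days"].values
    X["event"] = frame["event"].values
    return X


def fit_cox(records: list[SurvivalRecord], feature_spec: list[str],
            extra_features: pd.DataFrame | None = None) -> CoxFit:
    """Maximum-partial-likelihood Cox fit (Efron ties) for the feature set.

    ``feature_spec`` names columns of the encoded baseline design (see
    ``encode_covariates``) or of ``extra_features`` (per-case score columns
    aligned with ``records``).  Cases with missing values in the requested
    features are dropped.  Fewer than 5 events per feature triggers a
    warning; separation or non-convergence raises with diagnostics.
    """
    X = _design_matrix(records, list(feature_spec), extra_features)
    X = X.dropna()
    n_events = int(X["event"].sum())
    if n_events < 1:
        raise ValueError("no events")
    for f in feature_spec:
        if X[f].nunique() < 2:
            raise ValueError(f"zero-variance covariate: {f}")
    if n_events < 5 * len(feature_spec):
        warnings.warn(f"only {n_events} events for {len(feature_spec)} features")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="time_days", event_col="event")
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Cox fit failed for {feature_spec}: {exc}") from exc
    return CoxFit(
        features=tuple(feature_spec),
        coef=cph.params_,
        se=cph.standard_errors_,
        log_likelihood=float(cph.log_likelihood_),
        n=len(X),
        n_events=n_events,
        fitter=cph,
    )


def loo_cv_cindex(records: list[SurvivalRecord], feature_spec: list[str],
                  extra_features: pd.DataFrame | None = None,
                  max_skip_fraction: float = 0.05) -> float:
    """Leave-one-out cross-validated c-index with percentile normalization.

    For each case, a Cox model is fitted on the remaining cases and the
    held-out case's linear-predictor risk is converted to its percentile
    (fraction of training risks at or below it).  Because absolute risk
    scales vary across folds, the percentile makes scores comparable; the
    pooled percentiles are then scored by Harrell's c-index.  Non-convergent
    folds are skipped with a warning; more than ``max_skip_fraction`` skipped
    folds is an error.
    """
    X = _design_matrix(records, list(feature_spec), extra_features).dropna()
    if len(X) < 20:
        raise ValueError("leave-one-out CV requires n >= 20")
    feats = list(feature_spec)
    percentiles = np.full(len(X), np.nan)
    Xr = X.reset_index(drop=True)
    skipped = 0
    for i in range(len(Xr)):
        train = Xr.drop(index=i)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(train, duration_col="time_days", event_col="event")
        except Exception:
            skipped += 1
            warnings.warn(f"fold {i} non-convergent; skipped")
            continue
        beta = cph.params_[feats].values
        train_risk = train[feats].values @ beta
        held_risk = Xr.loc[i, feats].values @ beta
        percentiles[i] = np.mean(train_risk <= held_risk)
    if skipped > max_skip_fraction * len(Xr):
        raise RuntimeError(f"{skipped} of {len(Xr)} folds non-convergent")
    ok = np.flatnonzero(~np.isnan(percentiles))
    recs = [
        SurvivalRecord(
            str(i),
            float(Xr.loc[i, "time_days"]),
            int(Xr.loc[i, "event"]),
            "progression" if Xr.loc[i, "event"] else "censored",
        )
        for i in ok
    ]
    return cindex(percentiles[ok], recs)


def likelihood_ratio_test(nested: CoxFit, full: CoxFit) -> tuple[float, float]:
    """Chi-square LRT of a nested Cox model against the full model.

    Returns (statistic, p).  The nested feature set must be a strict subset of
    the full set, fitted on the same cases.
    """
    if not set(nested.features) < set(full.features):
        raise ValueError("models are not strictly nested")
    if nested.n != full.n:
        raise ValueError("models must be fitted on the same records")
    df = len(full.features) - len(nested.features)
    stat = 2.0 * (full.log_likelihood - nested.log_likelihood)
    stat = max(stat, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df))


def noninferiority_cindex(
    risk_a: np.ndarray,
    risk_b: np.ndarray,
    records: list[SurvivalRecord],
    margin: float = 0.075,
    n_boot: int = 1000,
    seed: int = 0,
    max_retries: int = 10,
) -> NonInferiorityResult:
    """One-sided non-inferiority of risk score *a* against risk score *b*.

    delta = C(a) - C(b) on the full cohort; paired bootstrap over cases gives
    the distribution of delta, whose 5th percentile is the lower bound of a
    one-sided 95% CI.  Non-inferiority is concluded when that bound exceeds
    ``-margin``.
    """
    risk_a = np.asarray(risk_a, dtype=float)
    risk_b = np.asarray(risk_b, dtype=float)
    if not (len(risk_a) == len(risk_b) == len(records)):
        raise ValueError("risk scores and records must align")
    delta = cindex(risk_a, records) - cindex(risk_b, records)

    rng = np.random.default_rng(seed)
    n = len(records)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            sub = [records[i] for i in idx]
            try:
                deltas[b] = cindex(risk_a[idx], sub) - cindex(risk_b[idx], sub)
                break
            except (ValueError, ZeroDivisionError):
                if attempt == max_retries:
                    raise
    lo = float(np.percentile(deltas, 5))
    return NonInferiorityResult(float(delta), lo, margin, lo > -margin, n_boot)


def correlation_permutation_test(
    score_a: np.ndarray,
    score_b: np.ndarray,
    target: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """Paired permutation test for a difference in correlation with a target.

    Observed statistic: r(a, target) - r(b, target) (Spearman by default,
    Pearson optional).  The null swaps a and b within each case with
    probability 1/2; two-sided p uses the add-one rule, so p >= 1/(n_perm+1).
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    t = np.asarray(target, dtype=float)
    if not (len(a) == len(b) == len(t)) or len(a) < 10:
        raise ValueError("aligned vectors of length >= 10 required")
    for v in (a, b, t):
        if np.std(v) == 0:
            raise ValueError("zero-variance input")

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        if method == "pearson":
            return stats.pearsonr(x, y).statistic
        raise ValueError("method must be 'spearman' or 'pearson'")

    observed = corr(a, t) - corr(b, t)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        ap = np.where(swap, b, a)
        bp = np.where(swap, a, b)
        if abs(corr(ap, t) - corr(bp, t)) >= abs(observed):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return float(observed), float(p)


def score_configurations(
    dls_components: pd.DataFrame,
    panels_by_component: dict[str, dict[str, list[int]]] | None = None,
    historic: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case scalar risk scores for each grading configuration.

    ``dls_components`` must carry columns ``mc_disc``/``np_disc``/``tf_disc``
    and ``mc_cont``/``np_cont``/``tf_cont`` indexed by case.  Emitted columns:
    the automated continuous sum, discrete sum and combined grade; when rater
    panels are supplied, the single-rater (first rater) and majority-vote
    sums and grades; when historic report scores are supplied, their sum and
    grade.  Configurations with missing inputs are skipped with a warning.
    """
    from .agreement import NO_MAJORITY, RaterPanel, majority_vote
    from .grading import grade_from_sum

    out = pd.DataFrame(index=dls_components.index)
    out["dls_sum_cont"] = (
        dls_components["mc_cont"] + dls_components["np_cont"] + dls_components["tf_cont"]
    )
    out["dls_sum_disc"] = (
        dls_components["mc_disc"] + dls_components["np_disc"] + dls_components["tf_disc"]
    ).astype(int)
    out["dls_grade"] = out["dls_sum_disc"].map(grade_from_sum)

    if panels_by_component is not None:
        single = {}
        majority = {}
        for case in dls_components.index:
            s_sum, m_sum = 0, 0
            ok_s, ok_m = True, True
            for comp in ("MC", "NP", "TF"):
                labels = panels_by_component.get(comp, {}).get(case)
                if not labels or len(labels) != 3:
                    ok_s = ok_m = False
                    break
                s_sum += labels[0]
                vote = majority_vote(
                    RaterPanel(str(case), comp, [(f"r{i}", s) for i, s in enumerate(labels)])
                )
                if vote is NO_MAJORITY:
                    ok_m = False
                else:
                    m_sum += int(vote)
            single[case] = s_sum if ok_s else np.nan
            majority[case] = m_sum if ok_m else np.nan
        out["path_single_sum"] = pd.Series(single)
        out["path_majority_sum"] = pd.Series(majority)
        out["path_majority_grade"] = out["path_majority_sum"].map(
            lambda s: grade_from_sum(int(s)) if not np.isnan(s) else np.nan
        )

    if historic is not None:
        cols = {"mc", "np", "tf"}
        if cols <= set(historic.columns):
            hist_sum = historic[["mc", "np", "tf"]].sum(axis=1)
            out["path_historic_sum"] = hist_sum
            out["path_historic_grade"] = hist_sum.map(
                lambda s: grade_from_sum(int(s)) if not np.isnan(s) else np.nan
            )
        else:
            warnings.warn("historic scores missing mc/np/tf columns; skipped")
    return out
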