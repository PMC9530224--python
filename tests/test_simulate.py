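"""Synthetic cohort generator: determinism, planted structure, noise targets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aigrading.masking import compute_tumor_mask, mask_area_mm2
from aigrading.simulate import (
    DEFAULT_RATER_CONFUSION,
    DEFAULT_SCORE_PRIORS,
    SimulationConfig,
    expected_pairwise_kappa,
    select_regions,
    simulate_cohort,
    simulate_covariates,
    simulate_rater_panel,
    simulate_slide,
    simulate_survival,
)
from aigrading.survival import cindex
from aigrading.agreement import weighted_kappa


def _scores(mc=2, np_=2, tf=2):
    return {"MC": mc, "NP": np_, "TF": tf}


# ------------------------------------------------------------ slide synthesis


def test_noise_free_deterministic_count_is_rate_times_area():
    cfg = SimulationConfig(heatmap_noise_sd=0.0, deterministic_counts=True,
                          invasive_fraction=0.6)
    slide = simulate_slide(cfg, _scores(mc=3), seed=5)
    mask = compute_tumor_mask(slide.invasive_map)
    area = mask_area_mm2(mask)
    # at zero map noise the argmax mask recovers the truth, so the planted
    # count equals round(rate * area) exactly
    truth_area = slide.invasive_mask_truth.sum() * (cfg.patch_um / 1000.0) ** 2
    assert len(slide.planted_mitoses) == round(15.0 * truth_area)
    assert area == pytest.approx(truth_area)


def test_rate_monotone_in_score():
    cfg = SimulationConfig(deterministic_counts=True)
    low = simulate_slide(cfg, _scores(mc=1), seed=9)
    high = simulate_slide(cfg, _scores(mc=3), seed=9)
    assert len(high.planted_mitoses) > len(low.planted_mitoses)


def test_planted_mitoses_inside_invasive_truth():
    cfg = SimulationConfig()
    slide = simulate_slide(cfg, _scores(mc=3), seed=2)
    patch_um = cfg.patch_um
    for x, y in slide.planted_mitoses:
        r, c = int(y // patch_um), int(x // patch_um)
        assert slide.invasive_mask_truth[r, c]


def test_zero_invasive_area_with_rate_errors():
    cfg = SimulationConfig(invasive_fraction=0.0)
    with pytest.raises(ValueError, match="no tumor"):
        simulate_slide(cfg, _scores(mc=2), seed=0)


def test_argmax_recovers_truth_mask(small_cohort):
    total = correct = 0
    for slide in small_cohort.slides:
        mask = compute_tumor_mask(slide.invasive_map)
        correct += np.sum(mask.grid == slide.invasive_mask_truth)
        total += mask.grid.size
    assert correct / total >= 0.99


def test_likelihoods_in_unit_interval(small_cohort):
    s = small_cohort.slides[0]
    assert s.mitosis_heatmap.grid.min() >= 0 and s.mitosis_heatmap.grid.max() <= 1
    assert np.all(s.np_softmax.grid.sum(axis=2) == pytest.approx(1.0))


def test_score_conditional_counts_are_poisson():
    """Chi-square GOF of planted counts against the configured Poisson rate."""
    cfg = SimulationConfig()
    counts = [
        len(simulate_slide(cfg, _scores(mc=2), seed=1000 + i).planted_mitoses)
        for i in range(120)
    ]
    area = round(cfg.invasive_fraction * 100) * (cfg.patch_um / 1000.0) ** 2
    lam = 5.0 * area
    # bin the Poisson support so expected counts are >= 5 per bin;
    # half-integer edges keep histogram and CDF binning consistent
    inner = stats.poisson.ppf([0.2, 0.4, 0.6, 0.8], lam) + 0.5
    edges = np.concatenate([[-0.5], inner, [np.inf]])
    observed, _ = np.histogram(counts, bins=edges)
    probs = np.diff(stats.poisson.cdf(edges, lam))
    chi2 = stats.chisquare(observed, probs / probs.sum() * len(counts))
    assert chi2.pvalue > 0.01


# ----------------------------------------------------------------- raters


def test_identity_confusion_reproduces_truth(rng):
    conf = {c: np.eye(3) for c in ("MC", "NP", "TF")}
    panels = simulate_rater_panel(_scores(1, 2, 3), conf, rng, "u")
    assert panels["MC"].scores == [1, 1, 1]
    assert panels["NP"].scores == [2, 2, 2]
    assert panels["TF"].scores == [3, 3, 3]


def test_uniform_confusion_gives_chance_kappa(rng):
    conf = {c: np.full((3, 3), 1 / 3) for c in ("MC", "NP", "TF")}
    a, b = [], []
    for i in range(800):
        panels = simulate_rater_panel(_scores(), conf, rng, f"u{i}")
        s = panels["NP"].scores
        a.append(s[0])
        b.append(s[1])
    assert abs(weighted_kappa(a, b).kappa) < 0.08


def test_panel_kappa_matches_enumeration_expectation(rng):
    """600 panels under the default NP confusion: pooled pairwise quadratic
    kappa within +-0.08 of the closed-form expectation, computed here by
    exhaustive enumeration over truth and label pairs."""
    prior = DEFAULT_SCORE_PRIORS["NP"]
    conf = DEFAULT_RATER_CONFUSION["NP"]
    # independent enumeration oracle
    joint = np.zeros((3, 3))
    for t, a, b in itertools.product(range(3), repeat=3):
        joint[a, b] += prior[t] * conf[t, a] * conf[t, b]
    marg_a, marg_b = joint.sum(1), joint.sum(0)
    num = den = 0.0
    for i, j in itertools.product(range(3), repeat=2):
        w = ((i - j) / 2) ** 2
        num += w * joint[i, j]
        den += w * marg_a[i] * marg_b[j]
    analytic = 1 - num / den
    assert analytic == pytest.approx(
        expected_pairwise_kappa(prior, conf), abs=1e-12
    )

    pairs = []
    for i in range(600):
        t = int(rng.choice(3, p=prior)) + 1
        panels = simulate_rater_panel(
            {"MC": t, "NP": t, "TF": t}, DEFAULT_RATER_CONFUSION, rng, f"u{i}"
        )
        s = panels["NP"].scores
        pairs.extend([(s[0], s[1]), (s[0], s[2]), (s[1], s[2])])
    arr = np.asarray(pairs)
    empirical = weighted_kappa(arr[:, 0], arr[:, 1]).kappa
    assert empirical == pytest.approx(analytic, abs=0.08)


def test_default_confusions_target_reported_agreement_levels():
    """Calibrated defaults put the expected pairwise quadratic kappa at the
    moderate agreement levels 0.56 / 0.36 / 0.55 for MC / NP / TF."""
    targets = {"MC": 0.56, "NP": 0.36, "TF": 0.55}
    for comp, tgt in targets.items():
        got = expected_pairwise_kappa(
            DEFAULT_SCORE_PRIORS[comp], DEFAULT_RATER_CONFUSION[comp]
        )
        assert got == pytest.approx(tgt, abs=1e-4)


def test_panels_reproduce_marginal_prior(rng):
    prior = np.asarray(DEFAULT_SCORE_PRIORS["TF"])
    conf = DEFAULT_RATER_CONFUSION["TF"]
    labels = []
    for i in range(700):
        t = int(rng.choice(3, p=prior)) + 1
        p = simulate_rater_panel(
            {"MC": t, "NP": t, "TF": t}, DEFAULT_RATER_CONFUSION, rng, f"u{i}"
        )
        labels.extend(p["TF"].scores)
    freq = np.bincount(labels, minlength=4)[1:] / len(labels)
    expected = prior @ conf
    # binomial error at n = 2100 draws: 3 sigma on each class frequency
    se = np.sqrt(expected * (1 - expected) / len(labels))
    assert np.all(np.abs(freq - expected) < 3.5 * se + 0.01)


def test_three_raters_from_pool_of_ten(small_cohort):
    rater_ids = set()
    for panel in small_cohort.slide_panels["MC"].values():
        ids = [r for r, _ in panel.labels]
        assert len(set(ids)) == 3
        rater_ids.update(ids)
    assert len(rater_ids) <= 10


# --------------------------------------------------------------- survival


def _score_table(rng, n):
    cov = simulate_covariates(n, rng)
    cov.insert(0, "case_id", [f"c{i}" for i in range(n)])
    for col in ("mc_disc", "np_disc", "tf_disc"):
        cov[col] = rng.choice([1, 2, 3], size=n)
    return cov


def test_null_hazard_gives_chance_cindex(rng):
    cfg = SimulationConfig(cox_log_hr={})
    table = _score_table(rng, 2000)
    recs = simulate_survival(table, cfg, rng)
    c = cindex(table["mc_disc"].to_numpy(float), recs)
    assert c == pytest.approx(0.5, abs=0.03)


def test_new_primary_fraction_exact(rng):
    cfg = SimulationConfig(frac_new_primary=0.2)
    table = _score_table(rng, 500)
    recs = simulate_survival(table, cfg, rng)
    n_events = sum(r.event for r in recs)
    n_new = sum(r.event_type == "new_primary" for r in recs)
    assert n_new == round(0.2 * n_events)
    for r in recs:
        if r.event_type == "new_primary":
            assert r.dfi_days is not None and r.dfi_days < r.time_days


def test_incomplete_covariates_rejected(rng):
    cfg = SimulationConfig()
    table = _score_table(rng, 20)
    table.loc[3, "age"] = np.nan
    with pytest.raises(ValueError, match="complete covariates"):
        simulate_survival(table, cfg, rng)


def test_covariate_marginals(rng):
    cov = simulate_covariates(3000, rng)
    assert cov["age"].between(25, 90).all()
    assert cov["age"].mean() == pytest.approx(58, abs=1.5)
    assert cov["er"].mean() == pytest.approx(0.77, abs=0.03)
    assert (cov["t_cat"] == "T2").mean() == pytest.approx(0.57, abs=0.04)


# ----------------------------------------------------------------- cohort


def test_cohort_determinism_and_structure():
    cfg = SimulationConfig(seed=31, n_cases=4)
    c1 = simulate_cohort(cfg)
    c2 = simulate_cohort(cfg)
    for s1, s2 in zip(c1.slides, c2.slides):
        assert np.array_equal(s1.mitosis_heatmap.grid, s2.mitosis_heatmap.grid)
        assert np.array_equal(s1.planted_mitoses, s2.planted_mitoses)
        assert s1.true_component_scores == s2.true_component_scores
    assert [r.time_days for r in c1.survival] == [r.time_days for r in c2.survival]
    # one survival record per case; triplicate panels per slide
    assert len(c1.survival) == cfg.n_cases
    assert all(len(p.labels) == 3 for p in c1.slide_panels["NP"].values())


def test_slide_stream_does_not_perturb_survival():
    """Named RNG substreams: changing slide rendering leaves the rater,
    covariate and survival draws untouched."""
    a = simulate_cohort(SimulationConfig(seed=8, n_cases=3))
    b = simulate_cohort(SimulationConfig(seed=8, n_cases=3, heatmap_noise_sd=0.05))
    assert not np.array_equal(a.slides[0].mitosis_heatmap.grid,
                              b.slides[0].mitosis_heatmap.grid)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    assert [r.time_days for r in a.survival] == [r.time_days for r in b.survival]
    for sid in a.slide_panels["MC"]:
        assert a.slide_panels["MC"][sid].labels == b.slide_panels["MC"][sid].labels


def test_regions_are_nonoverlapping_and_mitosis_rich():
    cfg = SimulationConfig(seed=77, n_cases=1,
                          true_score_priors={"MC": (0, 0, 1), "NP": (0, 1, 0),
                                             "TF": (0, 1, 0)})
    cohort = simulate_cohort(cfg)
    slide = cohort.slides[0]
    regions = cohort.regions[slide.slide_id]
    assert len(regions) == 3
    for (x0, y0), (x1, y1) in itertools.combinations(regions, 2):
        assert abs(x0 - x1) >= 1000 or abs(y0 - y1) >= 1000
    # the selected windows match a brute-force best-first scan
    assert regions == select_regions(slide)
    # top region contains at least as many mitoses as any selected one
    def count(orig):
        x0, y0 = orig
        pts = slide.planted_mitoses
        return np.sum((pts[:, 0] >= x0) & (pts[:, 0] < x0 + 1000)
                      & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + 1000))
    counts = [count(r) for r in regions]
    assert counts[0] >= counts[1] >= counts[2]
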