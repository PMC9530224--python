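# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `aigrading`, in the spirit of the model documentation of
packages like lifelines or statsmodels: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## Pipeline model

The package operates entirely on patch-level likelihood surfaces with
physical calibration (μm/pixel); the upstream convolutional models that
produce such surfaces from whole-slide images are out of scope.

### Invasive-carcinoma mask

Each cell of the 3-class map (non-tumor, CIS, invasive) is assigned its
argmax class; a cell enters the binary invasive mask iff that class is
invasive. **Tie-break:** ties resolve toward the *earlier* class in the
canonical order, i.e. conservatively against a false invasive call. No
hole-filling or minimum-area cleanup is applied. Grid geometry is
non-overlapping 1024-px patches, row-major, origin at the slide top-left.

### Mitosis detection

Threshold → erode → label → centroid:

1. binary map = (likelihood ≥ 0.915). The comparison is `≥` and the
   threshold is configurable.
2. Morphological erosion with a square structuring element of physical side
   16 μm. The pixel size is `ceil(16/mpp)` **forced odd** (adding one when
   even) so the element has a true centre; erosion follows the direct
   definition (a pixel survives iff every pixel under the element is on,
   with out-of-grid neighbourhoods off). Erosion with a cell-sized element
   is what splits two partially overlapping figures into two points. Note a
   purely axis-aligned overlap of two squares forms a rectangle whose
   erosion is a single connected segment; separation requires offset in both
   axes, which is the generic case for two distinct cells.
3. Connected components with 8-connectivity by default (diagonal blob
   contact counts as one figure; 4-connectivity is available), centroid =
   mean of member pixel centres converted to μm.

**Matching** of detections to reference figures (boxes confirmed by ≥ 2 of 3
raters) is optimal min-cost, maximum-cardinality one-to-one assignment among
pairs within 16 μm (Hungarian algorithm). Optimal assignment is
deterministic and independent of input order, unlike greedy matching.

**Density**: tiles of 1.8 × 1.8 mm on a 0.9 mm lattice anchored at the slide
origin; a tile is included iff it intersects ≥ 1 invasive cell (a
centre-in-mask rule is available). Density = detections inside tile ∩ mask
divided by the full tile area 3.24 mm² (a per-tile invasive-area denominator
is available behind `density_denominator="invasive"`; the choice only
rescales features that the standardized stage-2 models are invariant to).
Percentiles {5, 25, 50, 75, 95} use linear interpolation.

### Stage-2 scoring

MC uses multinomial logistic regression on the five density percentiles;
NP and TF use ridge regression on the numeric labels 1/2/3 applied to the
mean softmax 3-vector over invasive patches. Choices that were genuinely
open and are fixed here:

- features are standardized to zero mean/unit variance on the training set
  before either model — without this the shared L2 penalty is meaningless;
- the L2 strength is selected from 13 log-spaced values 10⁻³…10³ by 5-fold
  CV (log-loss for logistic, MSE for ridge), folds stratified by label and
  shuffled by a fixed `cv_seed`, so refits are exactly reproducible;
- the logistic model is multinomial rather than ordinal;
- continuous score: for logistic, the expected class value 1·p₁+2·p₂+3·p₃
  (the canonical choice matching the ridge output's scale); for ridge, the
  raw prediction clipped to [1, 3];
- discretization: logistic argmax with ties toward the *higher* score;
  ridge thresholds at 1.5/2.5 with half-open intervals [1,1.5) → 1,
  [1.5,2.5) → 2, [2.5,3] → 3;
- ridge fitted on constant labels degenerates to a constant predictor and is
  flagged rather than rejected.

Summed scores add the three components; the combined grade maps 3–5 → 1,
6–7 → 2, 8–9 → 3.

### Agreement

Weighted Cohen's κ uses disagreement weights wᵢⱼ = ((i−j)/(k−1))²
(quadratic, the default — confusing scores 1 and 3 is graver than adjacent
confusion), |i−j|/(k−1) (linear) or 1{i≠j} (unweighted). When both raters
are constant and identical the expected disagreement vanishes; κ is then
defined as 1 and flagged. One-vs-rest rater agreement pools, for each focal
rater, the two (focal, other) pairs per unit ("pair pooling"; a
vs-the-other-two-majority mode is available); the automated grader's row
pools (grader score, each rater label) over all units. Bootstrap CIs are
percentile (2.5/97.5, 1000 resamples by default) over slides or cases as
appropriate; a resample on which a statistic is undefined is redrawn up to
10 times.

### Survival analysis

- New-primary events are censored at the disease-free-interval time
  (event = 0, time = DFI); the operation is idempotent and never raises a
  time or creates an event.
- Cox models are maximum partial likelihood with Efron tie handling
  (lifelines). Covariate encoding: age continuous in years; ER binary;
  T with reference T1, indicators T2 and T3+ (T3/T4 merged); N with
  reference N0, indicator N1+ (N2+ additionally available); M binary.
  Cases with missing baseline covariates are dropped from baseline-adjusted
  analyses only.
- Harrell's c-index counts comparable pairs with half credit for risk ties
  (lifelines' estimator; verified against exhaustive pair enumeration).
- Leave-one-out CV for multivariable models: one Cox fit per held-out case;
  the held-out linear-predictor risk is converted to its percentile among
  the training risks, because absolute risk scales are not comparable across
  folds; pooled percentiles are scored by the c-index. With a single
  positive-effect covariate the percentile transform preserves the
  covariate's order exactly, so the CV c-index equals the raw covariate's.
- Likelihood-ratio tests compare strictly nested feature sets on the same
  records, χ² with df = Δ#parameters.
- Non-inferiority: Δ = C(a) − C(b), paired percentile bootstrap over cases
  (1000 resamples), one-sided 95% lower bound = 5th percentile, concluded
  non-inferior iff the bound exceeds −0.075 (the pre-specified margin).
- Correlation comparison (e.g. MC score vs Ki-67 expression): Spearman by
  default (the scores are ordinal; Pearson available), null generated by
  swapping the two scores within each case with probability ½, two-sided
  add-one p-value, so p ≥ 1/(n_perm+1).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
histology. Defaults (all in `SimulationConfig`, chosen once):

- **Geometry**: 2.56 × 2.56 mm slides of 10 × 10 patches (1024 px at
  0.25 μm/px), mitosis heatmap at 2 μm/px — the smallest geometry admitting
  the full 1.8 mm density tiling while keeping arrays light.
- **Latent truth**: per case, component scores drawn from priors shaped like
  a held-out test cohort's marginals (MC 0.42/0.26/0.32, NP 0.06/0.47/0.47,
  TF 0.10/0.18/0.72).
- **Invasive region**: a patch-aligned rectangle of exactly
  round(0.5 · cells) cells at a random position, observed through logit
  noise (gap 2.5, sd 0.45) whose argmax recovers the truth on > 99% of
  patches.
- **Mitoses**: a hard-core (min separation 24 μm) uniform point process in
  the invasive region with Poisson count at rate 1/5/15 per mm² for MC
  score 1/2/3. The marginal mitotic-density distribution of real cohorts is
  not publicly reported; these rates are free parameters chosen to span the
  ordinal range, not calibrated to a dataset. A `deterministic_counts` flag
  plants exactly round(rate·area) figures for exact-recovery experiments.
- **Heatmap rendering**: each figure is a filled square blob of likelihood
  0.99 whose pixel footprint equals the detector's forced-odd structuring
  element (9 px = 18 μm at 2 μm/px) over Beta(1, 20) background
  (mean ≈ 0.05), plus Gaussian noise sd 0.02. A blob rendered at the exact
  element footprint erodes to precisely its centre pixel, making noise-free
  recovery exact while the 0.915 threshold is still genuinely exercised by
  the noise; a blob one pixel smaller than the element would be annihilated,
  which is why the footprint, not the literal 16 μm, defines blob size.
- **NP/TF softmax maps**: logits = 2·onehot(true score) + N(0, 1) per patch
  inside the invasive region, pure noise outside.
- **Raters**: 3 raters per slide drawn from a pool of 10; labels drawn from
  per-component row-stochastic confusion matrices. The default matrices keep
  the true score with probability a and spill the rest mostly to the
  adjacent score (85/15 from the extremes, symmetric from the middle), with
  a solved per component — via the closed-form expected pairwise κ
  (`expected_pairwise_kappa`) under the score priors — so that expected
  pairwise quadratic κ equals 0.56 (MC), 0.36 (NP), 0.55 (TF), the moderate
  inter-pathologist agreement regime reported for slide-level grading.
- **Regions of interest**: per slide, the three non-overlapping 1 × 1 mm
  windows richest in planted mitoses (ties in raster order), each with its
  own triplicate panel; reference mitosis boxes carry 2–3 rater-positive
  counts plus a few sub-majority decoys.
- **Outcomes**: PFI times are exponential with hazard
  h₀·exp(Σ log-HR · x) on centred features (component scores centred at 2,
  age at 58, indicators as-is); default log-HRs follow reported univariable
  effects (MC 1.30 per unit, ER+ 0.60, T2 0.90, T3+ 2.39, N1+ 2.10,
  M1 14.09, age 1.01/yr). Censoring is independent exponential. Defaults
  h₀ = 1.2·10⁻⁴/day and censor rate 1.5·10⁻⁴/day describe a follow-up-rich
  registry-like cohort (roughly 40% events) so that parameter-recovery and
  calibration experiments are informative; a short-follow-up cohort can be
  emulated by raising the censor rate. A configurable fraction (default
  10%) of events is relabelled new-primary with DFI = Uniform(0.4, 0.95) ×
  PFI time. Covariates: age ~ N(58, 13) truncated to [25, 90]; ER+ 77%;
  T1/T2/T3+ 27/57/16%; N0/N1/N2+ 50/32/18%; M1 1.6%.
- **Reproducibility**: one master seed feeds named substreams (scores,
  slides — one per slide index —, raters, survival, covariates), so
  changing slide rendering never perturbs panel or outcome draws, and
  identical configurations are byte-identical.

### What the synthetic experiments show — and don't

Passing tests demonstrate that every algorithmic stage is correct against
independent oracles (direct-definition erosion, exhaustive matching,
contingency-table κ, O(n²) concordance, closed-form panel agreement,
analytic Cox effects) and that the pipeline recovers planted structure under
the configured noise. They do **not** demonstrate performance on real
slides: the generator renders geometric blobs rather than H&E texture, its
invasive regions are rectangles, its rater errors are conditionally
independent given the truth, and its hazards are exactly proportional.
Reported headline numbers from clinical studies (detection F1 ≈ 0.6,
slide-level κ in the 0.5–0.8 range, c-indices ≈ 0.6) depend on private
annotations and are intentionally not targets here.

## Problem sizes

Simulation sizes used by the test suite and `scripts/acceptance.py` — 20
slides for detection recovery, 600 panels for agreement calibration,
n = 2000 cases for Cox recovery, n = 300–500 for leave-one-out CV, 200
replicate runs for the non-inferiority operating characteristics, and an
80-case cohort for the end-to-end check — were chosen as the smallest sizes
at which the statistical tolerances quoted in the tests are comfortably
separated from their null distributions.

## Known limitations

- The detector's forced-odd structuring element can exceed the nominal
  16 μm by up to one heatmap pixel; at 2 μm/px the element is 18 μm.
- Percentile bootstrap (not BCa) throughout; one-sided bounds are bootstrap
  percentiles.
- The ridge-scored components provide no class probabilities, so
  probability-profile analyses apply to logistic-scored components.
- `loo_cv_cindex` refits one Cox model per case (O(n) fits); for n beyond a
  few thousand a grouped cross-validation would be preferable.
- The stage-2 logistic model expands missing training classes with −∞
  logits: a class never seen in training is never predicted.
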