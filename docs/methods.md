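# Methods

This note documents the models behind `agegap`: what is computed, what the
synthetic cohorts do and do not emulate, the numerical choices, and the
places where the design was genuinely open.

## 1. Prediction model and separation statistics

Each diagnostic group's predictions (predicted age `y` against
chronological age `x`) are summarized by an ordinary least-squares line of
best fit (LOBF) and a *single* residual standard deviation `σ` — the
prediction distribution is modeled as homoscedastic over the age window,
`y | x ~ N(slope·x + intercept, σ²)`. This static-σ assumption is a known
simplification: in real cohorts prediction spread typically grows at the
age extremes, and a heteroscedastic PDF construction is deliberately out of
scope here.

**BAD** (brain age difference, years) is the average vertical distance
between the AD and CU lines over the window `[x_min, x_max]`. For straight
lines this integral collapses to the difference evaluated at the window
midpoint, which is how it is computed (exact, no quadrature error). BAD is
averaged over the window rather than over subjects so that the
concentration of test subjects near the upper age limit does not dominate
the value. BAD is signed: it goes negative past the age where the two
lines cross.

**ID** (integrated difference, dimensionless) is the normalized integral of
`|f_AD(x,y) − f_CU(x,y)|` over the window — equivalently the window-average
of the total-variation distance between the two conditional normals, hence
always in `[0, 1]`. The normalizing constant `2·(x_max − x_min)` (40 on the
default 55–75 window) is exactly what makes the statistic reach 1 for
disjoint distributions; the absolute value in the inner integral is
essential (without it the integrand integrates to zero identically).

### Numerical evaluation of ID

- Inner `y`-integral: closed form. The difference of two normal densities
  changes sign at the points where the densities cross — one point for
  equal σ (the midpoint of the means), up to two for unequal σ (roots of
  the quadratic obtained by equating log-densities). The integral of
  `|f − g|` is then a sum of `|ΔCDF|` terms over the intervals those roots
  delimit, evaluated with `scipy.stats.norm` CDFs. No truncation error in
  `y`.
- Outer `x`-integral: 64-node Gauss–Legendre quadrature. The integrand
  (total variation as a function of `x`) is smooth, and 64 nodes agree with
  256 nodes to better than 1e-9 in tests; the result is clipped to `[0, 1]`
  to absorb floating-point overshoot.
- Degenerate `σ = 0` groups: a point mass has total-variation distance 1
  from any distribution that is not an identical point mass, so the
  per-age ID contribution is 1 where the LOBFs differ and 0 where they
  agree. `build_group_pdf` refuses σ = 0 (no density exists); `compute_id`
  handles it by this rule.
- Residual σ uses the population convention (divide by n). The sample
  convention is available via `fit_lobf(..., ddof=1)`; at the cohort sizes
  involved the difference is far below reporting precision.
- Windowed ID partitions the window into `increment`-wide sub-windows
  (4 years by default usage); if the increment does not divide the span
  the final sub-window is truncated at the upper edge rather than dropped.

## 2. Synthetic cohorts

The generator produces the data-generating structure the analysis assumes,
not a realistic MRI segmentation pipeline. Each subject receives a latent
*brain age* `b`:

- CU: `b = x` (chronological age);
- AD: `b = x + gap(x) + carrier_extra_gap·[APOE4 carrier]
  + female_extra_gap·[female]`, with `gap(x) = g0 − g1·(x − 55)`.

Volumetric feature `j` is `baseline_j − slope_j·b + N(0, noise_j)`; the 19
"medical attribute" columns are age-independent standard-normal noise, and
chronological age itself is never a predictor. With `g1 > 0` the population
AD gap declines linearly and the CU/AD lines cross at `55 + g0/g1` —
reproducing the empirical pattern in which models lose discriminative power
at high ages and eventually predict AD subjects *younger* than CU. The gap
is allowed to go negative by default (`floor_gap_at_zero=False`) precisely
to emulate that crossing.

Defaults (one row per choice, with rationale):

| Parameter | Default | Why |
|---|---|---|
| `n_cu`, `n_ad` | 1100, 602 | the study population sizes being emulated |
| age | truncated normal 76.1 ± 8.3 on [50, 95] | matches the emulated cohort demographics |
| APOE4 carrier prevalence | 0.32 CU / 0.58 AD | matches the emulated cohort |
| female fraction | 0.64 CU / 0.47 AD | matches the emulated cohort |
| education | N(15.5, 3.6) CU / N(14.7, 3.8) AD, truncated at 0 | non-volumetric covariate with a realistic group difference |
| `g0` (gap at age 55) | 12.6 y | with `g1` below, gives a window-average gap ≈ 8 y on 55–75, inside the 6.5–10 y range such studies report |
| `g1` (gap shrink rate) | 0.46 y/y | puts the line crossing at 55 + 12.6/0.46 ≈ 82.4, in the empirically observed 80–85 band |
| `carrier_extra_gap` | 1.0 y | small positive carrier effect, the order of the carrier/noncarrier BAD differences reported in stratified analyses |
| `female_extra_gap` | 0.5 y | likewise, smaller: gender is the weaker factor |
| feature baselines | log-spaced 2 → 200 | features span magnitudes (cortical thickness in mm to structure volumes in cc) |
| feature age slopes | 0.2%–1% of baseline per year, log-spaced | annual atrophy rates differ across structures, so features differ in signal-to-noise |
| `feature_noise_scale` | 0.25 of baseline | age-unrelated anatomical variation + measurement error; yields CU residual σ of a few years under the linear model, the order seen in practice |
| seed | 20240943 | fixed default for reproducibility |

What the generator does **not** emulate: correlation between features
beyond the single shared latent brain age, non-linear feature–age
trajectories, longitudinal structure, missing data, or site/scanner
effects. Consequently a passing simulation study demonstrates that the
pipeline recovers the parameters of *this* generative family — linear
atrophy driven by one latent age — not that any particular model family
would win on real MRI data. Indeed, because the features are linear in the
latent brain age, ordinary linear regression is the oracle model here and
tree ensembles can only approximate it; on real data the ranking can
differ.

## 3. Regression engine

- Training is restricted to CU rows by contract (violations raise, they are
  not silently filtered): the regressor must learn *normal* aging so that
  its transfer to AD subjects measures accelerated atrophy.
- Grid search for the tree families: small standard grids (random forest:
  200/500 trees × depth ∞/10 × min-leaf 1/5; gradient boosting: 200/500
  trees × learning rate 0.05/0.1 × depth 3/6), 5-fold CV scored by mean
  absolute error — the conventional loss for age prediction — with ties
  broken by the first grid cell in declaration order. A single-cell grid
  skips CV and fits directly. Search is re-run inside every training fold
  (conservative: no information leaks across folds).
- APOE4 and gender are stratification variables, not predictors, by
  default; predictors are exactly the volumetric + medical columns.
- Everything is deterministic under a fixed seed (estimator seeds, fold
  shuffles, stratified subsampling).

### Attenuation of recovered gaps

Tree-ensemble predictions regress toward the training mean, so the
recovered BAD understates an injected gap by a noise-dependent factor
(about 40% at the realistic default noise, under 5% at 2% noise). This is
a property of the regressors, not a bug; the simulation studies that check
gap *recovery* therefore run in a low-noise regime (`feature_noise_scale =
0.02`) where recovery is near-unbiased, and the realistic default is kept
for everything else. No post-hoc age-bias correction is applied, matching
the protocol being implemented.

## 4. Cross-validation harness

- The "25 iterations" are realized as 5 independent repeats of the 5-fold
  procedure, each repeat with a fold seed derived from the experiment seed
  via `SeedSequence`.
- Training uses CU subjects of **all** ages; the 55–75 window filter is
  applied to test subjects only. AD subjects are tested in every fold;
  each CU subject is held out exactly once per repeat.
- Within a repeat, held-out CU predictions are pooled across the five
  folds and the AD predictions of all five fold-models are stacked; one
  metrics row is computed per repeat and the repeats averaged
  (`pool_folds=True`, the default). Computing metrics inside every fold
  (`pool_folds=False`) is supported but fits the CU line on ~1/5 of the CU
  test population, which inflates the finite-sample ID floor under null
  conditions (LOBF estimation noise creates spurious separation ≈ 0.12 at
  600 CU / 300 AD, versus ≈ 0.08 pooled; the floor shrinks with cohort
  size either way and is monitored, not assumed to be zero).
- Stratified designs: compositions are recomputed from each fold's CU
  training subset, so the 80/20 split happens first. D-stratum size is
  `ceil(n_level1 / 2)` per level; E targets B's size at 50–50 and falls
  back to (all of level 1, remainder from level 2) when level 1 cannot
  supply half. D/E subsets are drawn uniformly within stratum and
  re-drawn per repeat/fold. The mixed design C is fit once per fold and
  tested on each level separately (fitting it per test level would change
  nothing statistically and double the compute).

## 5. Problem sizes used in the shipped studies

The shipped simulation studies (test suite and worked example) run at 600
CU / 300 AD with a 200-tree random forest, five folds and five repeats —
large enough that binomial and LOBF sampling error are small relative to
the asserted bands, and representative of the full-size protocol, which is
a constant factor larger and exercised through identical code paths.

## 6. Known limitations

- The homoscedastic normal PDF is an approximation; ID inherits it.
- ID has a positive finite-sample floor under the null (section 4); report it
  alongside group sizes.
- The synthetic feature model is linear in the latent brain age; it cannot
  adjudicate between model families the way real, nonlinearly structured
  data might.
- `percent_id_increase` divides by the baseline ID and is undefined at 0;
  it reports the unrounded value alongside the conventionally rounded
  whole percent.
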