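# agegap

Brain-age-gap analysis for Alzheimer's risk studies: train machine-learning
regressors to predict "brain age" from volumetric MRI-style features using
cognitively unimpaired (CU) subjects only, transfer them to an Alzheimer's
disease (AD) group, and quantify how far apart the two groups' prediction
distributions sit — including APOE4- and gender-stratified training designs.

The package is aimed at biostatisticians and neuroimaging methodologists who
want a tested, seedable implementation of this protocol. Because the cohort
data such studies use (e.g. the access-restricted NACC database) cannot be
redistributed, `agegap` ships a synthetic-cohort generator that reproduces
the statistical structure the analysis assumes, so every stage is testable
end to end.

## The statistics

For each diagnostic group, predictions are summarized by the ordinary
least-squares line of best fit (LOBF) of predicted age $y$ on chronological
age $x$, plus the standard deviation $\sigma$ of the residuals about it.

**Brain age difference (BAD)** — the window-averaged vertical gap between
the AD and CU lines, in years (positive = AD predicted older):

$$\mathrm{BAD} = \frac{1}{x_{\max}-x_{\min}} \int_{x_{\min}}^{x_{\max}}
\left[\mathrm{LOBF}_{AD}(x) - \mathrm{LOBF}_{CU}(x)\right] dx$$

**Integrated difference (ID)** — model each group's predictions at age $x$
as $\mathcal{N}(\mathrm{LOBF}(x), \sigma^2)$ and integrate the absolute
difference of the two density surfaces:

$$\mathrm{ID} = \frac{1}{2\,(x_{\max}-x_{\min})} \int_{x_{\min}}^{x_{\max}}
\int_{-\infty}^{\infty} \left|f_{AD}(x,y) - f_{CU}(x,y)\right|\, dy\, dx$$

ID is the window-average total-variation distance between the two
conditional normals: 0 for identical prediction distributions, 1 for
disjoint ones. It rewards both a large gap *and* tight predictions, and can
be evaluated on sub-windows (e.g. four-year increments) to localize where a
model discriminates. The default target window is ages 55–75.

## The protocol

* Regressors (linear regression, random forest, XGBoost) train on CU
  subjects of **all** ages; tree families are tuned by cross-validated grid
  search on mean absolute error.
* CU data is split 80/20 five ways (5-fold CV); per fold the model is
  applied to the held-out CU 20% and to the full AD group. Held-out
  predictions are pooled within each repeat, metrics computed on the target
  window, and everything repeated five times with fresh fold assignments
  (25 iterations) and averaged.
* For a binary factor (APOE4 carrier status, gender) five training
  compositions A–E are compared: level-specific (A, B), fully mixed (C),
  and 50–50 mixed sets size-matched to A and B (D, E), each tested
  per level.

## Worked example

```python
from agegap import (SimulationConfig, generate_cohort,
                    ExperimentConfig, run_baseline)
from agegap.models import ModelSpec

cohort = generate_cohort(SimulationConfig(n_cu=600, n_ad=300, seed=7))
config = ExperimentConfig(
    n_repeats=2,
    models=[ModelSpec("random_forest", grid={"n_estimators": [200]}, seed=7),
            ModelSpec("linear", seed=7)],
    seed=7,
)
result = run_baseline(cohort, config)
print(result.averaged[["model", "bad", "sigma_cu", "sigma_ad", "id"]]
      .round(3).to_string(index=False))
```

```
        model   bad  sigma_cu  sigma_ad    id
random_forest 2.667     1.654     1.700 0.557
       linear 7.474     4.015     3.646 0.646
```

The simulated cohort injects an AD brain-age gap averaging ≈ 8.5 years over
the 55–75 window. The linear model nearly recovers it (BAD 7.5 y) but with
loose predictions (σ ≈ 4 y); the random forest regresses predictions toward
the training mean under this noise level, shrinking its BAD to 2.7 y while
producing much tighter distributions (σ ≈ 1.7 y). ID weighs both effects at
once — here the two models land at 0.56 and 0.65, i.e. moderate overlap
between the CU and AD prediction distributions either way.

The same pipeline is available from the shell:

```bash
agegap simulate --out cohort.csv --seed 7
agegap baseline --cohort cohort.csv --manifest cohort.manifest.yaml \
                --models linear --folds 5 --repeats 5 --out metrics.csv
agegap stratify --cohort cohort.csv --manifest cohort.manifest.yaml \
                --factor apoe4 --out strat.csv
agegap report   --metrics strat.csv
```

## Layout

| Module            | Contents                                                  |
|-------------------|-----------------------------------------------------------|
| `agegap.cohort`   | synthetic cohort generator and summaries                  |
| `agegap.models`   | CU-trained regressors with grid search                    |
| `agegap.metrics`  | LOBF fits, BAD, prediction PDFs, (windowed) ID            |
| `agegap.harness`  | repeated-CV protocol, A–E stratified designs              |
| `agegap.io`       | CSV/YAML readers and writers, column manifests            |
| `agegap.cli`      | `agegap simulate / baseline / stratify / report`          |

See `docs/methods.md` for modeling assumptions, parameter defaults and
numerical choices.
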