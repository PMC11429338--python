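"""Experimental protocol: repeated 5-fold CU cross-validation, the
three-model baseline comparison, and factor-stratified training designs.

The protocol mirrors the published workflow.  The CU data is split 80/20
five ways; in each fold the regressor trains on the 80% (all ages) and is
applied to the held-out CU 20% and to the whole AD group.  Metrics are
computed on test subjects inside the target chronological-age window only,
averaged over folds, and the whole procedure is repeated with fresh fold
assignments (5 folds x 5 repeats = 25 iterations) and averaged again.

For a binary stratification factor (APOE4 carrier status or gender) five
training-set compositions are compared:

* **A** — level-1-specific (all carriers / all females)
* **B** — level-2-specific (all noncarriers / all males)
* **C** — mixed: every CU subject
* **D** — mixed-condensed, size-matched to A: a 50-50 mix totalling |A|
* **E** — mixed-condensed, size-matched to B: a 50-50 mix totalling |B|,
  falling back to (all of level 1, remainder from level 2) when level 1
  cannot supply half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._errors import (
    ConfigurationError,
    EmptyGroupError,
    InsufficientStratumError,
    UndefinedRatioError,
)
from .cohort import CARRIER, DIAG_AD, DIAG_CU, FEMALE, MALE, NONCARRIER, Cohort
from .metrics import (
    AgeWindow,
    MetricsResult,
    TARGET_WINDOW,
    compute_bad,
    compute_id,
    fit_lobf,
)
from .models import FittedModel, ModelSpec, default_model_specs, fit_model, predict_age

__all__ = [
    "ExperimentConfig",
    "StratificationPlan",
    "HarnessResult",
    "split_cu",
    "run_baseline",
    "compose_training_groups",
    "run_stratified",
    "percent_id_increase",
]

#: level-1 / level-2 labels per stratification factor (level 1 is the
#: higher-risk level: carriers, females)
FACTOR_LEVELS = {"apoe4": (CARRIER, NONCARRIER), "gender": (FEMALE, MALE)}

METRIC_COLUMNS = ["bad", "sigma_cu", "sigma_ad", "id", "n_cu_tested", "n_ad_tested"]
KEY_COLUMNS = ["model", "training_group", "test_group"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol knobs for the repeated cross-validation harness.

    With ``pool_folds`` (the default) each repeat's held-out CU predictions
    are pooled across its folds — every CU subject contributes exactly one
    held-out prediction per repeat, and every AD subject one prediction per
    fold — and metrics are computed once per repeat, then averaged over
    repeats.  Setting it False computes metrics within every fold instead
    and averages all fold x repeat rows; per-fold CU test sets are then
    small, which inflates the finite-sample ID floor.
    """

    n_folds: int = 5
    n_repeats: int = 5
    target_window: AgeWindow = TARGET_WINDOW
    models: list[ModelSpec] = field(default_factory=default_model_specs)
    pool_folds: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ConfigurationError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if not self.models:
            raise ConfigurationError("models list must be nonempty")


@dataclass(frozen=True)
class StratificationPlan:
    """Training-group compositions A-E for one binary factor.

    ``groups`` maps each group name to its (level-1 count, level-2 count);
    ``test_levels`` maps each group name to the factor levels it is
    evaluated on (single level for the specific models A and B, both levels
    for the mixed designs C, D and E).
    """

    factor: str
    level1: str
    level2: str
    n_level1: int
    n_level2: int
    groups: dict[str, tuple[int, int]]
    test_levels: dict[str, tuple[str, ...]]


@dataclass
class HarnessResult:
    """Per-fold metric rows plus their mean over folds and repeats."""

    per_fold: pd.DataFrame
    averaged: pd.DataFrame

    def id_by_key(self) -> dict[tuple, float]:
        """Map (model, training_group, test_group) -> averaged ID."""
        return {
            tuple(row[k] for k in KEY_COLUMNS): row["id"]
            for _, row in self.averaged.iterrows()
        }

    def lookup(self, **labels) -> pd.Series:
        mask = np.ones(len(self.averaged), dtype=bool)
        for k, v in labels.items():
            mask &= self.averaged[k] == v
        hits = self.averaged[mask]
        if len(hits) != 1:
            raise KeyError(f"{labels} matched {len(hits)} rows")
        return hits.iloc[0]


def _average(per_fold: pd.DataFrame) -> pd.DataFrame:
    avg = (
        per_fold.groupby(KEY_COLUMNS, sort=False)[METRIC_COLUMNS]
        .mean()
        .reset_index()
    )
    return avg


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0] % (2**31))


def split_cu(
    cohort: Cohort, fold_index: int, n_folds: int, seed: int
) -> tuple[Cohort, Cohort]:
    """80/20-style CU split for one fold of a shuffled k-fold partition.

    The ``n_folds`` test subsets partition the CU data; train and test are
    disjoint and their union is the full CU set.  Deterministic in ``seed``.
    """
    cu = cohort.cu
    if n_folds > len(cu):
        raise ConfigurationError(
            f"n_folds={n_folds} exceeds the {len(cu)} available CU subjects"
        )
    if not 0 <= fold_index < n_folds:
        raise ConfigurationError(
            f"fold_index must be in [0, {n_folds}), got {fold_index}"
        )
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    train_idx, test_idx = list(kf.split(np.arange(len(cu))))[fold_index]
    mask_train = np.zeros(len(cu), dtype=bool)
    mask_train[train_idx] = True
    return cu.subset(mask_train), cu.subset(~mask_train)


def _window_metrics(
    preds_cu: pd.DataFrame,
    preds_ad: pd.DataFrame,
    window: AgeWindow,
    labels: dict,
) -> MetricsResult:
    """Fit per-group LOBFs on window-filtered predictions and score them."""
    in_cu = preds_cu[(preds_cu["age"] >= window.x_min) & (preds_cu["age"] <= window.x_max)]
    in_ad = preds_ad[(preds_ad["age"] >= window.x_min) & (preds_ad["age"] <= window.x_max)]
    fit_cu = fit_lobf((in_cu["age"], in_cu["predicted_age"]))
    fit_ad = fit_lobf((in_ad["age"], in_ad["predicted_age"]))
    return MetricsResult(
        bad=compute_bad(fit_cu, fit_ad, window),
        id=compute_id(fit_cu, fit_ad, window),
        sigma_cu=fit_cu.sigma,
        sigma_ad=fit_ad.sigma,
        window=window,
        n_cu_tested=len(in_cu),
        n_ad_tested=len(in_ad),
        labels=labels,
    )


def _require_both_diagnoses(cohort: Cohort) -> None:
    present = set(cohort.data["diagnosis"].unique())
    missing = {DIAG_CU, DIAG_AD} - present
    if missing:
        raise EmptyGroupError(f"cohort lacks diagnosis level(s): {sorted(missing)}")


def run_baseline(cohort: Cohort, config: ExperimentConfig) -> HarnessResult:
    """Compare the configured model families under the repeated-CV protocol.

    Training uses CU subjects of all ages; the target-window filter applies
    only at test time.  AD subjects are re-tested in every fold; each CU
    subject lands in a test fold exactly once per repeat.
    """
    _require_both_diagnoses(cohort)
    ad = cohort.ad
    rows = []
    for spec in config.models:
        key = {"model": spec.family, "training_group": "all_cu", "test_group": "all"}
        for repeat in range(config.n_repeats):
            fold_seed = _derive_seed(config.seed, repeat)
            cu_parts, ad_parts = [], []
            for fold in range(config.n_folds):
                train, test_cu = split_cu(cohort, fold, config.n_folds, fold_seed)
                model = fit_model(spec, train)
                preds_cu = predict_age(model, test_cu)
                preds_ad = predict_age(model, ad)
                if config.pool_folds:
                    cu_parts.append(preds_cu)
                    ad_parts.append(preds_ad)
                else:
                    m = _window_metrics(
                        preds_cu,
                        preds_ad,
                        config.target_window,
                        labels={**key, "repeat": repeat, "fold": fold},
                    )
                    rows.append(m.to_row())
            if config.pool_folds:
                m = _window_metrics(
                    pd.concat(cu_parts, ignore_index=True),
                    pd.concat(ad_parts, ignore_index=True),
                    config.target_window,
                    labels={**key, "repeat": repeat, "fold": "pooled"},
                )
                rows.append(m.to_row())
    per_fold = pd.DataFrame(rows)
    return HarnessResult(per_fold=per_fold, averaged=_average(per_fold))


def compose_training_groups(cu_cohort: Cohort, factor: str) -> StratificationPlan:
    """Training-group compositions A-E from the CU stratum sizes.

    With n1 subjects at level 1 and n2 at level 2:
    A = (n1, 0); B = (0, n2); C = (n1, n2); D = (k, k) with k = ceil(n1/2);
    E targets B's size at 50-50, i.e. (h, h) with h = ceil(n2/2), falling
    back to (n1, n2 - n1) when level 1 has fewer than h subjects.
    """
    if factor not in FACTOR_LEVELS:
        raise ConfigurationError(
            f"factor must be one of {sorted(FACTOR_LEVELS)}, got {factor!r}"
        )
    level1, level2 = FACTOR_LEVELS[factor]
    col = cu_cohort.data[factor]
    n1 = int((col == level1).sum())
    n2 = int((col == level2).sum())
    for name, n in ((level1, n1), (level2, n2)):
        if n < 4:
            raise InsufficientStratumError(
                f"stratum {name!r} has only {n} CU subjects (need >= 4)"
            )
    k = math.ceil(n1 / 2)
    h = math.ceil(n2 / 2)
    e_comp = (h, h) if n1 >= h else (n1, n2 - n1)
    groups = {
        "A": (n1, 0),
        "B": (0, n2),
        "C": (n1, n2),
        "D": (k, k),
        "E": e_comp,
    }
    test_levels = {
        "A": (level1,),
        "B": (level2,),
        "C": (level1, level2),
        "D": (level1, level2),
        "E": (level1, level2),
    }
    return StratificationPlan(
        factor=factor,
        level1=level1,
        level2=level2,
        n_level1=n1,
        n_level2=n2,
        groups=groups,
        test_levels=test_levels,
    )


def _sample_stratum(
    cu: Cohort, factor: str, level: str, count: int, rng: np.random.Generator
) -> pd.DataFrame:
    pool = cu.data[cu.data[factor] == level]
    if count > len(pool):
        raise InsufficientStratumError(
            f"requested {count} subjects from stratum {level!r} with only {len(pool)}"
        )
    if count == len(pool):
        return pool
    idx = rng.choice(len(pool), size=count, replace=False)
    return pool.iloc[np.sort(idx)]


def run_stratified(
    cohort: Cohort, factor: str, config: ExperimentConfig
) -> HarnessResult:
    """Evaluate the A-E training designs for one binary factor.

    Per fold, compositions are recomputed from that fold's CU training
    subset (so the 80/20 split happens first) and the condensed designs D/E
    subsample uniformly within stratum, re-drawn each repeat.  Each group's
    single fitted model (the first configured spec — random forest by
    default) is tested separately on each designated level: held-out CU plus
    all AD subjects of that level, inside the target window.
    """
    _require_both_diagnoses(cohort)
    spec = config.models[0]
    level1, level2 = FACTOR_LEVELS.get(factor, (None, None))
    if level1 is None:
        raise ConfigurationError(
            f"factor must be one of {sorted(FACTOR_LEVELS)}, got {factor!r}"
        )
    ad = cohort.ad
    rows = []
    for repeat in range(config.n_repeats):
        fold_seed = _derive_seed(config.seed, repeat)
        pooled: dict[tuple, tuple[list, list]] = {}
        for fold in range(config.n_folds):
            train_cu, test_cu = split_cu(cohort, fold, config.n_folds, fold_seed)
            plan = compose_training_groups(train_cu, factor)
            for group, (c1, c2) in plan.groups.items():
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (config.seed, repeat, fold, ord(group))
                    )
                )
                parts = []
                if c1:
                    parts.append(_sample_stratum(train_cu, factor, level1, c1, rng))
                if c2:
                    parts.append(_sample_stratum(train_cu, factor, level2, c2, rng))
                train = Cohort(
                    pd.concat(parts, ignore_index=True), train_cu.predictors
                )
                model = fit_model(spec, train)
                for level in plan.test_levels[group]:
                    cu_level = test_cu.subset(test_cu.data[factor] == level)
                    ad_level = ad.subset(ad.data[factor] == level)
                    preds_cu = predict_age(model, cu_level)
                    preds_ad = predict_age(model, ad_level)
                    if config.pool_folds:
                        cu_parts, ad_parts = pooled.setdefault(
                            (group, level), ([], [])
                        )
                        cu_parts.append(preds_cu)
                        ad_parts.append(preds_ad)
                    else:
                        m = _window_metrics(
                            preds_cu,
                            preds_ad,
                            config.target_window,
                            labels={
                                "model": spec.family,
                                "training_group": group,
                                "test_group": level,
                                "repeat": repeat,
                                "fold": fold,
                            },
                        )
                        rows.append(m.to_row())
        for (group, level), (cu_parts, ad_parts) in pooled.items():
            m = _window_metrics(
                pd.concat(cu_parts, ignore_index=True),
                pd.concat(ad_parts, ignore_index=True),
                config.target_window,
                labels={
                    "model": spec.family,
                    "training_group": group,
                    "test_group": level,
                    "repeat": repeat,
                    "fold": "pooled",
                },
            )
            rows.append(m.to_row())
    per_fold = pd.DataFrame(rows)
    return HarnessResult(per_fold=per_fold, averaged=_average(per_fold))


def percent_id_increase(ids, group_a_key, group_b_key) -> tuple[float, int]:
    """Percent by which ID under key A exceeds ID under key B.

    ``ids`` is either a mapping from key to ID value or a
    :class:`HarnessResult` (keys are then (model, training_group,
    test_group) tuples).  Returns ``(unrounded_percent, rounded_percent)``.
    """
    if isinstance(ids, HarnessResult):
        ids = ids.id_by_key()
    for key in (group_a_key, group_b_key):
        if key not in ids:
            raise KeyError(f"key {key!r} not present in results")
    id_a, id_b = float(ids[group_a_key]), float(ids[group_b_key])
    if id_b == 0:
        raise UndefinedRatioError("baseline ID is 0; percent increase undefined")
    pct = 100.0 * (id_a - id_b) / id_b
    return pct, int(round(pct))
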