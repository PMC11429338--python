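"""Seeded synthetic cohorts emulating an aging / Alzheimer's study population.

The generator produces subject tables with the statistical structure the
downstream analysis assumes: a cognitively-unimpaired (CU) group and an
Alzheimer's (AD) group matched in chronological age, volumetric predictor
columns that decline with a latent *brain age*, and an AD brain-age gap that
shrinks linearly with chronological age so that the two groups' prediction
lines cross at high ages.

Generative model
----------------
Each subject draws a chronological age ``x`` from a truncated normal.  The
latent brain age is

* CU:  ``b = x``
* AD:  ``b = x + gap(x) + carrier_extra_gap·[carrier] + female_extra_gap·[female]``

with ``gap(x) = g0 − g1·(x − reference_age)`` — a gap of ``g0`` years at the
reference age that shrinks by ``g1`` years per year and (by default) is
allowed to go negative, so the population CU/AD lines cross at
``reference_age + g0/g1``.

Volumetric feature ``j`` is ``baseline_j − slope_j·b + Normal(0, noise_sd_j)``;
medical-attribute columns are age-independent noise.  Chronological age is
never a predictor column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._errors import ConfigurationError, EmptyGroupError

__all__ = [
    "SimulationConfig",
    "Cohort",
    "CohortSummary",
    "generate_cohort",
    "summarize_cohort",
    "DIAG_CU",
    "DIAG_AD",
]

DIAG_CU = "CU"
DIAG_AD = "AD"
CARRIER = "carrier"
NONCARRIER = "noncarrier"
FEMALE = "female"
MALE = "male"

#: Columns every cohort table carries besides the predictor vector.
DEMOGRAPHIC_COLUMNS = ("subject_id", "age", "diagnosis", "apoe4", "gender", "education")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-cohort generator.

    Defaults emulate the published NACC-derived study population: 1100 CU and
    602 AD subjects aged 76.1 ± 8.3 on [50, 95], APOE4 carrier prevalence
    32% (CU) / 58% (AD), 64% / 47% female, 156 volumetric + 19 medical
    predictors, and an AD gap of 12.6 years at age 55 shrinking by 0.46
    years per year (population crossing near age 82).
    """

    n_cu: int = 1100
    n_ad: int = 602
    age_mean: float = 76.1
    age_sd: float = 8.3
    age_min: float = 50.0
    age_max: float = 95.0
    n_volumetric: int = 156
    n_medical: int = 19
    carrier_prevalence_cu: float = 0.32
    carrier_prevalence_ad: float = 0.58
    female_fraction_cu: float = 0.64
    female_fraction_ad: float = 0.47
    gap_intercept: float = 12.6
    gap_slope: float = 0.46
    reference_age: float = 55.0
    carrier_extra_gap: float = 1.0
    female_extra_gap: float = 0.5
    floor_gap_at_zero: bool = False
    education_mean_cu: float = 15.5
    education_sd_cu: float = 3.6
    education_mean_ad: float = 14.7
    education_sd_ad: float = 3.8
    feature_baselines: np.ndarray | None = None
    feature_age_slopes: np.ndarray | None = None
    feature_noise_sd: np.ndarray | float | None = None
    feature_noise_scale: float = 0.25
    seed: int = 20240943

    def __post_init__(self) -> None:
        for name in ("n_cu", "n_ad", "n_volumetric"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_medical < 0:
            raise ConfigurationError(f"n_medical must be >= 0, got {self.n_medical}")
        for name in (
            "carrier_prevalence_cu",
            "carrier_prevalence_ad",
            "female_fraction_cu",
            "female_fraction_ad",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.age_min < self.age_max:
            raise ConfigurationError(
                f"age_min must be < age_max, got [{self.age_min}, {self.age_max}]"
            )
        if self.age_sd <= 0:
            raise ConfigurationError(f"age_sd must be > 0, got {self.age_sd}")
        noise = self.feature_noise_sd
        if noise is not None and np.any(np.asarray(noise) < 0):
            raise ConfigurationError("feature_noise_sd must be >= 0")
        if self.feature_noise_scale < 0:
            raise ConfigurationError(
                f"feature_noise_scale must be >= 0, got {self.feature_noise_scale}"
            )

    # -- resolved per-feature parameter vectors ------------------------------

    def resolved_baselines(self) -> np.ndarray:
        if self.feature_baselines is not None:
            arr = np.asarray(self.feature_baselines, dtype=float)
        else:
            # log-spaced levels so features span magnitudes (cortical
            # thickness in mm up to large structure volumes in cc)
            arr = np.logspace(np.log10(2.0), np.log10(200.0), self.n_volumetric)
        if arr.shape != (self.n_volumetric,):
            raise ConfigurationError(
                f"feature_baselines must have length n_volumetric={self.n_volumetric}"
            )
        return arr

    def resolved_slopes(self) -> np.ndarray:
        if self.feature_age_slopes is not None:
            arr = np.asarray(self.feature_age_slopes, dtype=float)
        else:
            # annual decline between 0.2% and 1% of baseline, log-spaced so
            # features differ in signal-to-noise
            rates = np.logspace(np.log10(0.002), np.log10(0.01), self.n_volumetric)
            arr = rates * self.resolved_baselines()
        if arr.shape != (self.n_volumetric,):
            raise ConfigurationError(
                f"feature_age_slopes must have length n_volumetric={self.n_volumetric}"
            )
        return arr

    def resolved_noise_sd(self) -> np.ndarray:
        if self.feature_noise_sd is None:
            # age-unrelated anatomical variation + measurement error,
            # proportional to each feature's baseline level
            arr = self.feature_noise_scale * self.resolved_baselines()
        else:
            arr = np.broadcast_to(
                np.asarray(self.feature_noise_sd, dtype=float), (self.n_volumetric,)
            ).copy()
        return arr

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("feature_baselines", "feature_age_slopes", "feature_noise_sd"):
            if isinstance(d.get(key), list):
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass(frozen=True)
class Cohort:
    """A subject table plus the names of its predictor columns.

    ``data`` holds one row per subject: the demographic columns
    (``subject_id, age, diagnosis, apoe4, gender, education``) followed by
    the numeric predictor vector.
    """

    data: pd.DataFrame
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"cohort table missing column(s): {missing}")
        missing_pred = [c for c in self.predictors if c not in self.data.columns]
        if missing_pred:
            raise ConfigurationError(f"predictor column(s) absent from table: {missing_pred}")

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.data.loc[mask].reset_index(drop=True), self.predictors)

    @property
    def cu(self) -> "Cohort":
        return self.subset(self.data["diagnosis"] == DIAG_CU)

    @property
    def ad(self) -> "Cohort":
        return self.subset(self.data["diagnosis"] == DIAG_AD)

    def feature_matrix(self) -> pd.DataFrame:
        return self.data[list(self.predictors)]


@dataclass(frozen=True)
class CohortSummary:
    """Per-diagnosis demographic and per-feature summary statistics."""

    demographics: pd.DataFrame
    features: pd.DataFrame


def _sample_truncnorm(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _group_frame(rng, cfg: SimulationConfig, diagnosis: str, n: int, id_offset: int):
    is_cu = diagnosis == DIAG_CU
    age = _sample_truncnorm(rng, n, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max)
    p_carrier = cfg.carrier_prevalence_cu if is_cu else cfg.carrier_prevalence_ad
    p_female = cfg.female_fraction_cu if is_cu else cfg.female_fraction_ad
    carrier = rng.random(n) < p_carrier
    female = rng.random(n) < p_female
    edu_mean = cfg.education_mean_cu if is_cu else cfg.education_mean_ad
    edu_sd = cfg.education_sd_cu if is_cu else cfg.education_sd_ad
    education = np.clip(rng.normal(edu_mean, edu_sd, size=n), 0.0, None)

    if is_cu:
        brain_age = age.copy()
    else:
        gap = cfg.gap_intercept - cfg.gap_slope * (age - cfg.reference_age)
        if cfg.floor_gap_at_zero:
            gap = np.maximum(gap, 0.0)
        brain_age = (
            age
            + gap
            + cfg.carrier_extra_gap * carrier
            + cfg.female_extra_gap * female
        )

    baselines = cfg.resolved_baselines()
    slopes = cfg.resolved_slopes()
    noise_sd = cfg.resolved_noise_sd()
    vol = (
        baselines[None, :]
        - slopes[None, :] * brain_age[:, None]
        + rng.normal(0.0, 1.0, size=(n, cfg.n_volumetric)) * noise_sd[None, :]
    )
    med = rng.normal(0.0, 1.0, size=(n, cfg.n_medical))

    demo = pd.DataFrame(
        {
            "subject_id": [f"{diagnosis}-{id_offset + i:05d}" for i in range(n)],
            "age": age,
            "diagnosis": diagnosis,
            "apoe4": np.where(carrier, CARRIER, NONCARRIER),
            "gender": np.where(female, FEMALE, MALE),
            "education": education,
        }
    )
    vol_frame = pd.DataFrame(
        vol, columns=[f"vol_{j + 1:03d}" for j in range(cfg.n_volumetric)]
    )
    med_frame = pd.DataFrame(
        med, columns=[f"med_{j + 1:02d}" for j in range(cfg.n_medical)]
    )
    return pd.concat([demo, vol_frame, med_frame], axis=1)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a seeded cohort; same config and seed give identical tables."""
    rng = np.random.default_rng(config.seed)
    cu = _group_frame(rng, config, DIAG_CU, config.n_cu, 0)
    ad = _group_frame(rng, config, DIAG_AD, config.n_ad, 0)
    data = pd.concat([cu, ad], ignore_index=True)
    predictors = tuple(
        [f"vol_{j + 1:03d}" for j in range(config.n_volumetric)]
        + [f"med_{j + 1:02d}" for j in range(config.n_medical)]
    )
    return Cohort(data=data, predictors=predictors)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Per-diagnosis group sizes, demographics and per-feature mean ± SD.

    Standard deviations use the population (ddof=0) convention, matching the
    residual-SD convention used by the separation metrics.
    """
    if len(cohort) == 0:
        raise EmptyGroupError("cannot summarize an empty cohort")
    demo_rows = {}
    feat_cols = {}
    for diagnosis, grp in cohort.data.groupby("diagnosis", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            raise EmptyGroupError(f"group {diagnosis} is empty")
        demo_rows[diagnosis] = {
            "n": len(grp),
            "age_mean": grp["age"].mean(),
            "age_sd": grp["age"].std(ddof=0),
            "pct_carrier": 100.0 * (grp["apoe4"] == CARRIER).mean(),
            "pct_female": 100.0 * (grp["gender"] == FEMALE).mean(),
            "education_mean": grp["education"].mean(),
            "education_sd": grp["education"].std(ddof=0),
        }
        feats = grp[list(cohort.predictors)]
        feat_cols[f"{diagnosis.lower()}_mean"] = feats.mean()
        feat_cols[f"{diagnosis.lower()}_sd"] = feats.std(ddof=0)
    demographics = pd.DataFrame.from_dict(demo_rows, orient="index")
    demographics.index.name = "diagnosis"
    features = pd.DataFrame(feat_cols)
    features.index.name = "feature"
    return CohortSummary(demographics=demographics, features=features)
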