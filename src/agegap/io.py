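"""Cohort and metrics readers/writers.

Cohorts travel as plain CSV (UTF-8, comma-separated, header row, '.'
decimal) with a YAML or JSON sidecar manifest assigning each column a role:
``id``, ``age``, ``diagnosis``, ``apoe4``, ``gender``, ``education`` or
``predictor``.  Metrics tables are written as CSV with a stable column
order plus a full-precision JSON mirror.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import SchemaError
from .cohort import (
    CARRIER,
    DIAG_AD,
    DIAG_CU,
    FEMALE,
    MALE,
    NONCARRIER,
    Cohort,
    SimulationConfig,
)

__all__ = [
    "ColumnManifest",
    "read_cohort",
    "write_cohort",
    "write_metrics",
    "read_manifest",
    "load_simulation_config",
]

ROLES = ("id", "age", "diagnosis", "apoe4", "gender", "education", "predictor")
#: roles that must appear exactly once; ``id`` may be omitted (ids are then
#: generated) and ``predictor`` must appear at least once
UNIQUE_ROLES = ("age", "diagnosis", "apoe4", "gender", "education")

CATEGORICAL_LEVELS = {
    "diagnosis": {DIAG_CU, DIAG_AD},
    "apoe4": {CARRIER, NONCARRIER},
    "gender": {FEMALE, MALE},
}

METRICS_COLUMN_ORDER = [
    "model",
    "training_group",
    "test_group",
    "window",
    "bad",
    "sigma_cu",
    "sigma_ad",
    "id",
    "n_cu_tested",
    "n_ad_tested",
]


@dataclass(frozen=True)
class ColumnManifest:
    """Column-name → role map describing a cohort CSV."""

    roles: dict  # column name -> role

    def __post_init__(self) -> None:
        bad = {c: r for c, r in self.roles.items() if r not in ROLES}
        if bad:
            raise SchemaError(f"unknown column role(s): {bad}")
        for role in UNIQUE_ROLES:
            cols = self.columns_for(role)
            if len(cols) != 1:
                raise SchemaError(
                    f"manifest must assign exactly one column the role {role!r}; "
                    f"found {cols or 'none'}"
                )
        if len(self.columns_for("id")) > 1:
            raise SchemaError("manifest assigns more than one 'id' column")
        if not self.columns_for("predictor"):
            raise SchemaError("manifest must assign at least one 'predictor' column")

    def columns_for(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    def column(self, role: str) -> str:
        return self.columns_for(role)[0]

    @classmethod
    def for_cohort(cls, cohort: Cohort) -> "ColumnManifest":
        roles = {
            "subject_id": "id",
            "age": "age",
            "diagnosis": "diagnosis",
            "apoe4": "apoe4",
            "gender": "gender",
            "education": "education",
        }
        roles.update({c: "predictor" for c in cohort.predictors})
        return cls(roles=roles)


def read_manifest(path) -> ColumnManifest:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"manifest at {path} is not a mapping")
    return ColumnManifest(roles=dict(data))


def write_manifest(manifest: ColumnManifest, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(manifest.roles, fh, indent=1)
        else:
            yaml.safe_dump(manifest.roles, fh, sort_keys=False)


def read_cohort(path, manifest: ColumnManifest) -> Cohort:
    """Read a cohort CSV under a column manifest into a typed table.

    Raises
    ------
    SchemaError
        A manifest column is absent from the file, a categorical column
        holds a value outside its enumeration, or a predictor cell is not
        numeric (the message names the row and column).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    missing = [c for c in manifest.roles if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if raw.isna().any().any():
        cells = [
            (int(i), c) for c in manifest.roles for i in raw.index[raw[c].isna()]
        ]
        raise SchemaError(f"{path}: missing values at (row, column): {cells[:10]}")

    rename = {manifest.column(role): role for role in UNIQUE_ROLES}
    if manifest.columns_for("id"):
        rename[manifest.column("id")] = "subject_id"
    data = raw.rename(columns=rename)
    if "subject_id" not in data.columns:
        data.insert(0, "subject_id", [f"S-{i:05d}" for i in range(len(data))])
    data = data.rename(columns={"subject_id": "subject_id"})

    for col, levels in CATEGORICAL_LEVELS.items():
        bad = set(data[col].astype(str).unique()) - levels
        if bad:
            raise SchemaError(
                f"{path}: column {col!r} contains invalid level(s) {sorted(bad)}; "
                f"expected {sorted(levels)}"
            )

    predictors = manifest.columns_for("predictor")
    for col in predictors + ["age", "education"]:
        coerced = pd.to_numeric(data[col], errors="coerce")
        if coerced.isna().any():
            row = int(data.index[coerced.isna()][0])
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {row}: "
                f"{data[col].iloc[row]!r}"
            )
        data[col] = coerced.astype(float)

    ordered = ["subject_id", "age", "diagnosis", "apoe4", "gender", "education"]
    data = data[ordered + predictors]
    return Cohort(data=data, predictors=tuple(predictors))


def write_cohort(cohort: Cohort, path, manifest_path=None) -> ColumnManifest:
    """Write a cohort as CSV plus (optionally) its sidecar manifest."""
    path = Path(path)
    cohort.data.to_csv(path, index=False)
    manifest = ColumnManifest.for_cohort(cohort)
    if manifest_path is not None:
        write_manifest(manifest, manifest_path)
    return manifest


def _as_frame(result) -> pd.DataFrame:
    if hasattr(result, "averaged"):
        result = result.averaged
    frame = pd.DataFrame(result)
    if frame.empty and len(frame.columns) == 0:
        return pd.DataFrame(columns=METRICS_COLUMN_ORDER)
    cols = [c for c in METRICS_COLUMN_ORDER if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    return frame[cols]


def write_metrics(result, path) -> pd.DataFrame:
    """Write a metrics table as CSV and a full-precision JSON mirror.

    ``result`` may be a :class:`~agegap.harness.HarnessResult` (its averaged
    table is written), a DataFrame, or a list of row dicts.  An empty result
    yields a header-only CSV.  Returns the frame written.
    """
    path = Path(path)
    frame = _as_frame(result)
    frame.to_csv(path, index=False)
    records = json.loads(frame.to_json(orient="records", double_precision=15))
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)
    return frame


def load_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"simulation config at {path} is not a mapping")
    return SimulationConfig.from_dict(data)
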