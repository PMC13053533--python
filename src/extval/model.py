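"""Logistic prediction scores: linear predictors, risks, exclusions, variants.

A prediction score is a fitted logistic model transported as frozen numbers:
an intercept plus one coefficient per predictor. The linear predictor (LP) of
an admission is the intercept plus the coefficient-weighted sum of its
predictor values, and the predicted risk of the outcome (here, in-hospital
death during an admission for an acute COPD exacerbation) is the inverse
logit of the LP.

Cohorts are tabular: one row per hospital admission, one column per variable,
``NaN`` marking a missing value. Recurrent admissions of the same patient are
treated as independent records. Model definitions are read from YAML/JSON
config files so that the actual published coefficients — which this package
deliberately does not hard-code — can be supplied by the user.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "PredictorSpec",
    "LogisticPredictionModel",
    "AdmissionRecord",
    "ExclusionTally",
    "linear_predictor",
    "predicted_risk",
    "zero_predictor",
    "apply_exclusions",
    "load_model",
    "save_model",
    "read_cohort",
    "write_cohort",
    "clip_risk",
]

#: Probabilities are clipped to this open interval before any logit transform
#: downstream, so logits stay finite.
RISK_EPS = 1e-10

OUTCOME_COL = "outcome"
AGE_COL = "age"
SPIROMETRY_COL = "fev1_fvc_ratio"


@dataclass(frozen=True)
class PredictorSpec:
    """Declaration of one model predictor.

    Parameters
    ----------
    name
        Column name of the predictor, unique within a model.
    kind
        ``"continuous"`` or ``"binary"`` (binary values must be 0/1).
    unit
        Measurement unit (mm Hg, years, mg/dL, ...); required for
        continuous predictors.
    """

    name: str
    kind: str = "continuous"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "continuous" and not self.unit:
            raise ValueError(f"continuous predictor {self.name!r} needs a unit")


@dataclass(frozen=True)
class LogisticPredictionModel:
    """A logistic risk score: intercept + named coefficients.

    ``predicted risk = expit(intercept + sum_j coef_j * x_j)``.
    """

    intercept: float
    coefficients: Mapping[str, float]
    predictors: Sequence[PredictorSpec] = ()
    label: str = "model"

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        coefs = dict(self.coefficients)
        for name, value in coefs.items():
            if not math.isfinite(value):
                raise ValueError(f"coefficient for {name!r} is not finite")
        object.__setattr__(self, "coefficients", coefs)
        if self.predictors:
            names = [p.name for p in self.predictors]
            if len(set(names)) != len(names):
                raise ValueError("duplicate predictor names")
            unknown = set(coefs) - set(names)
            if unknown:
                raise ValueError(f"coefficients without predictor spec: {sorted(unknown)}")
        else:
            object.__setattr__(
                self,
                "predictors",
                tuple(PredictorSpec(n, "continuous", "unspecified") for n in coefs),
            )

    @property
    def predictor_names(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, records) -> np.ndarray | float:
        return linear_predictor(self, records)

    def predicted_risk(self, records) -> np.ndarray | float:
        return predicted_risk(self, records)

    def zero_predictor(self, name: str) -> "LogisticPredictionModel":
        return zero_predictor(self, name)


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalized admission: predictor values, auxiliaries, outcome.

    Missing values are ``None``/``NaN`` — never a sentinel number. ``outcome``
    is 1 for a non-surviving admission, 0 for a surviving one, and must be
    present.
    """

    admission_id: str
    patient_id: str
    values: Mapping[str, float | None]
    outcome: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")

    def get(self, name: str) -> float | None:
        v = self.values.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)


def _as_frame(records) -> pd.DataFrame:
    """Accept a DataFrame, a single AdmissionRecord/mapping, or a sequence."""
    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, AdmissionRecord):
        return _as_frame([records])
    if isinstance(records, Mapping):
        return pd.DataFrame([dict(records)])
    rows = []
    for r in records:
        if isinstance(r, AdmissionRecord):
            row = dict(r.values)
            row.setdefault("admission_id", r.admission_id)
            row.setdefault("patient_id", r.patient_id)
            row[OUTCOME_COL] = r.outcome
        else:
            row = dict(r)
        rows.append(row)
    return pd.DataFrame(rows)


def linear_predictor(model: LogisticPredictionModel, records) -> np.ndarray | float:
    """Intercept plus coefficient-weighted sum of the record's predictors.

    Raises ``ValueError`` naming the first offending predictor if any model
    predictor is missing (imputation must run first).
    """
    scalar = isinstance(records, (AdmissionRecord, Mapping))
    df = _as_frame(records)
    lp = np.full(len(df), float(model.intercept))
    for name, coef in model.coefficients.items():
        if name not in df.columns:
            raise ValueError(f"predictor {name!r} absent from records")
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(
                f"predictor {name!r} has missing values; impute before scoring"
            )
        lp = lp + coef * col
    return float(lp[0]) if scalar else lp


def predicted_risk(model: LogisticPredictionModel, records) -> np.ndarray | float:
    """Inverse-logit of the linear predictor, strictly inside (0, 1)."""
    lp = linear_predictor(model, records)
    return clip_risk(expit(lp))


def clip_risk(p):
    """Clip probabilities into [RISK_EPS, 1-RISK_EPS] for safe logits."""
    return np.clip(p, RISK_EPS, 1.0 - RISK_EPS)


def zero_predictor(model: LogisticPredictionModel, name: str) -> LogisticPredictionModel:
    """Sensitivity variant with one coefficient set to zero.

    The returned model's LP is invariant to that predictor's value; used for
    leave-one-predictor-out sensitivity analyses (e.g. scoring without serum
    albumin when it is heavily missing).
    """
    if name not in model.coefficients:
        raise KeyError(f"{name!r} is not a predictor of {model.label!r}")
    coefs = dict(model.coefficients)
    coefs[name] = 0.0
    return replace(model, coefficients=coefs)


@dataclass(frozen=True)
class ExclusionTally:
    """Per-reason exclusion counts from the cohort filter."""

    age: int
    spirometry: int

    @property
    def total(self) -> int:
        return self.age + self.spirometry


def apply_exclusions(
    records: pd.DataFrame,
    *,
    age_col: str = AGE_COL,
    ratio_col: str = SPIROMETRY_COL,
    min_age: float = 40.0,
    max_ratio: float = 0.7,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the cohort eligibility filter.

    Drops admissions with age strictly below ``min_age`` (default 40 years),
    then admissions whose observed FEV1/FVC ratio is strictly above
    ``max_ratio`` (default 0.7, i.e. spirometry incompatible with COPD).
    Admissions with missing spirometry are retained — the diagnosis then
    rests on the discharge coding. Age must be observed for every record.
    """
    df = _as_frame(records)
    age = pd.to_numeric(df[age_col], errors="coerce")
    if age.isna().any():
        raise ValueError("age is missing for some records; cannot apply exclusions")
    young = age < min_age
    kept = df.loc[~young]
    if ratio_col in kept.columns:
        ratio = pd.to_numeric(kept[ratio_col], errors="coerce")
        bad_spiro = ratio.notna() & (ratio > max_ratio)
    else:
        bad_spiro = pd.Series(False, index=kept.index)
    retained = kept.loc[~bad_spiro].reset_index(drop=True)
    tally = ExclusionTally(age=int(young.sum()), spirometry=int(bad_spiro.sum()))
    return retained, tally


# ---------------------------------------------------------------------------
# Config and cohort I/O
# ---------------------------------------------------------------------------

def load_model(path: str | Path) -> LogisticPredictionModel:
    """Load a model definition from a YAML or JSON config file.

    Schema::

        label: str
        intercept: float
        coefficients: {name: float, ...}
        predictors:          # optional; defaults to continuous/unspecified
          - {name: str, kind: continuous|binary, unit: str}
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(raw)


def model_from_dict(raw: Mapping) -> LogisticPredictionModel:
    for key in ("intercept", "coefficients"):
        if key not in raw:
            raise ValueError(f"model config missing required field {key!r}")
    predictors = tuple(
        PredictorSpec(p["name"], p.get("kind", "continuous"), p.get("unit", ""))
        for p in raw.get("predictors", [])
    )
    return LogisticPredictionModel(
        intercept=float(raw["intercept"]),
        coefficients={str(k): float(v) for k, v in raw["coefficients"].items()},
        predictors=predictors,
        label=str(raw.get("label", "model")),
    )


def model_to_dict(model: LogisticPredictionModel) -> dict:
    return {
        "label": model.label,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "predictors": [
            {"name": p.name, "kind": p.kind, "unit": p.unit} for p in model.predictors
        ],
    }


def save_model(model: LogisticPredictionModel, path: str | Path) -> None:
    path = Path(path)
    raw = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read an admission-level cohort CSV; empty cells become NaN (missing)."""
    return pd.read_csv(path)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
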