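"""Normative modelling: per-feature GLMs on controls and Z-scoring.

A Gaussian identity-link GLM (ordinary least squares) with design
``[1, age, sex]`` is fitted per feature on the control cohort. Patient
deviations are expressed as residuals from the control prediction; nodal and
thalamic features are further standardized into Z-scores using the mean and
standard deviation of the control residuals. The abnormal-node burden counts
parcels whose Z-score falls strictly outside ±threshold (default ±2).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "NormativeModel",
    "NormativeModelSet",
    "BurdenResult",
    "fit_normative_model",
    "fit_normative_models",
    "zscore_patient",
    "abnormal_burden",
    "global_residual_table",
]

log = logging.getLogger(__name__)

SEX_CODES = {"male": 0.0, "female": 1.0}


@dataclass(frozen=True)
class NormativeModel:
    """OLS fit of one feature on control age and sex, plus residual moments.

    ``sex_coefficient`` is the effect of female relative to male (sex coded
    0 = male, 1 = female). The residual SD uses the n−1 denominator, so
    Z-scoring the training controls gives sample mean 0 and SD 1 exactly.
    """

    feature: str
    intercept: float
    age_coefficient: float
    sex_coefficient: float
    control_residual_mean: float
    control_residual_sd: float
    age_range: tuple[float, float]
    age2_coefficient: float | None = None

    def predict(self, age: float | np.ndarray, sex) -> np.ndarray:
        sex_num = _encode_sex(sex)
        pred = self.intercept + self.age_coefficient * np.asarray(age, dtype=float)
        pred = pred + self.sex_coefficient * sex_num
        if self.age2_coefficient is not None:
            pred = pred + self.age2_coefficient * np.asarray(age, dtype=float) ** 2
        return pred

    def residual(self, value, age, sex) -> np.ndarray:
        return np.asarray(value, dtype=float) - self.predict(age, sex)

    def zscore(self, value, age, sex) -> np.ndarray:
        r = self.residual(value, age, sex)
        return (r - self.control_residual_mean) / self.control_residual_sd


def _encode_sex(sex) -> np.ndarray:
    if isinstance(sex, str):
        return np.asarray(SEX_CODES[sex])
    arr = np.asarray(sex)
    if arr.dtype.kind in "UO":
        return np.asarray([SEX_CODES[s] for s in arr.ravel()]).reshape(arr.shape)
    return arr.astype(float)


def fit_normative_model(
    values: np.ndarray,
    ages: np.ndarray,
    sexes,
    feature: str = "feature",
    include_age2: bool = False,
) -> NormativeModel:
    """Fit a Gaussian identity-link GLM of one feature on [1, age, sex].

    Requires at least three more controls than parameters, both sexes
    represented, and non-constant age; a feature that is constant in
    controls (residual SD 0) is rejected.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sex_num = _encode_sex(sexes).astype(float)
    n_params = 4 if include_age2 else 3
    if len(values) < n_params + 3:
        raise ValueError(
            f"{feature}: need at least {n_params + 3} controls, got {len(values)}"
        )
    if np.unique(sex_num).size < 2:
        raise ValueError(f"{feature}: single sex in controls — degenerate design")
    if np.ptp(ages) == 0:
        raise ValueError(f"{feature}: constant age in controls — degenerate design")
    cols = [np.ones_like(ages), ages, sex_num]
    if include_age2:
        cols.append(ages**2)
    x = np.column_stack(cols)
    fit = sm.OLS(values, x).fit()
    resid = np.asarray(fit.resid)
    sd = float(resid.std(ddof=1))
    # relative floor: an exact linear fit leaves only rounding noise behind
    if sd <= 1e-10 * max(1.0, float(np.abs(values).mean())):
        raise ValueError(f"{feature}: feature constant in controls (residual sd 0)")
    return NormativeModel(
        feature=feature,
        intercept=float(fit.params[0]),
        age_coefficient=float(fit.params[1]),
        sex_coefficient=float(fit.params[2]),
        age2_coefficient=float(fit.params[3]) if include_age2 else None,
        control_residual_mean=float(resid.mean()),
        control_residual_sd=sd,
        age_range=(float(ages.min()), float(ages.max())),
    )


@dataclass
class NormativeModelSet:
    """A bundle of per-feature normative models sharing one control design."""

    models: dict[str, NormativeModel] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> NormativeModel:
        return self.models[feature]

    def __contains__(self, feature: str) -> bool:
        return feature in self.models

    def features(self) -> list[str]:
        return list(self.models)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            name: {
                "intercept": m.intercept,
                "age_coefficient": m.age_coefficient,
                "sex_coefficient": m.sex_coefficient,
                "age2_coefficient": m.age2_coefficient,
                "control_residual_mean": m.control_residual_mean,
                "control_residual_sd": m.control_residual_sd,
                "age_range": list(m.age_range),
            }
            for name, m in self.models.items()
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModelSet":
        payload = json.loads(Path(path).read_text())
        models = {
            name: NormativeModel(
                feature=name,
                intercept=d["intercept"],
                age_coefficient=d["age_coefficient"],
                sex_coefficient=d["sex_coefficient"],
                age2_coefficient=d.get("age2_coefficient"),
                control_residual_mean=d["control_residual_mean"],
                control_residual_sd=d["control_residual_sd"],
                age_range=tuple(d["age_range"]),
            )
            for name, d in payload.items()
        }
        return cls(models=models)


def fit_normative_models(
    feature_table: pd.DataFrame,
    ages: np.ndarray,
    sexes,
    include_age2: bool = False,
) -> NormativeModelSet:
    """Fit one model per column of ``feature_table`` (rows = controls)."""
    out = NormativeModelSet()
    for col in feature_table.columns:
        out.models[str(col)] = fit_normative_model(
            feature_table[col].to_numpy(), ages, sexes, feature=str(col), include_age2=include_age2
        )
    return out


def zscore_patient(model: NormativeModel, feature_value: float, age: float, sex) -> float:
    """Z-score one patient observation against the control normative model.

    z = ((value − predicted) − control_residual_mean) / control_residual_sd.
    Ages outside the control training range are extrapolated with a warning.
    """
    lo, hi = model.age_range
    if not lo <= age <= hi:
        msg = (
            f"{model.feature}: age {age:.2f} outside control range "
            f"[{lo:.2f}, {hi:.2f}]; extrapolating"
        )
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return float(model.zscore(feature_value, age, sex))


@dataclass(frozen=True)
class BurdenResult:
    """Counts of parcels with Z-scores strictly outside ±threshold."""

    n_abnormal_total: int
    n_above: int
    n_below: int
    threshold: float

    def __post_init__(self) -> None:
        if self.n_abnormal_total != self.n_above + self.n_below:
            raise ValueError("total must equal above + below")


def abnormal_burden(z: np.ndarray, threshold: float = 2.0) -> BurdenResult:
    """Count nodes with z > +threshold and z < −threshold (strict)."""
    z = np.asarray(z, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        raise ValueError(f"non-finite z-scores at indices {bad.tolist()}")
    above = int((z > threshold).sum())
    below = int((z < -threshold).sum())
    return BurdenResult(
        n_abnormal_total=above + below, n_above=above, n_below=below, threshold=threshold
    )


def global_residual_table(
    feature_table: pd.DataFrame,
    models: NormativeModelSet,
) -> pd.DataFrame:
    """Residuals and Z-scores for every (subject, timepoint) row.

    ``feature_table`` must carry columns ``subject_id``, ``timepoint``,
    ``age``, ``sex`` plus one column per modelled feature. Returns a tidy
    frame with one row per (subject, timepoint, feature).
    """
    meta_cols = ["subject_id", "timepoint", "age", "sex"]
    rows = []
    for col in feature_table.columns:
        if col in meta_cols:
            continue
        if str(col) not in models:
            continue
        m = models[str(col)]
        resid = m.residual(
            feature_table[col].to_numpy(),
            feature_table["age"].to_numpy(dtype=float),
            feature_table["sex"].to_numpy(),
        )
        z = (resid - m.control_residual_mean) / m.control_residual_sd
        part = feature_table[["subject_id", "timepoint"]].copy()
        part["feature"] = str(col)
        part["residual"] = resid
        part["z"] = z
        rows.append(part)
    return pd.concat(rows, ignore_index=True)
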