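"""Normative residualization and training-anchored scaling.

Covariate regressors (intercept, age, sex, ICV) are estimated per feature on
the healthy controls of the training folds only, then used to remove the
covariate component from all training and test data. Residualized features
are z-scaled with the training-set mean and standard deviation. When
harmonization is enabled the pipeline always residualizes the harmonized
features — never the reverse order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .errors import ConfigError, FitError

N_COVARIATES = 3  # age, sex, icv


def _design(roster: pd.DataFrame) -> np.ndarray:
    age = roster["age"].to_numpy(float)
    male = (roster["sex"] == "M").to_numpy(float)
    icv = roster["icv"].to_numpy(float) / 1e6
    if np.isnan(age).any() or np.isnan(icv).any():
        bad = roster.loc[roster["age"].isna() | roster["icv"].isna(),
                         "subject_id"].tolist()
        raise ConfigError(f"missing covariates for subjects {bad}")
    return np.column_stack([np.ones(len(roster)), age, male, icv])


@dataclass
class NormativeResults:
    """Frozen normative-model estimates from the training folds."""

    coef: np.ndarray        # (4, p): intercept, age, sex_male, icv
    train_mean: np.ndarray  # (p,) mean of training residuals
    train_sd: np.ndarray    # (p,) sd of training residuals
    feature_names: list
    n_hc: int

    def transform(self, fm: FeatureMatrix, roster: pd.DataFrame) -> FeatureMatrix:
        """Subtract the covariate component and apply the stored scaling."""
        if not fm.mask.all():
            raise ConfigError("residualization requires fully observed data")
        X = _design(roster)
        resid = fm.values - X @ self.coef
        scaled = (resid - self.train_mean) / self.train_sd
        return FeatureMatrix(list(fm.subjects), fm.schema, scaled,
                             np.ones_like(fm.mask))

    def to_json(self, path=None) -> str:
        payload = {
            "coef": self.coef.tolist(),
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "feature_names": self.feature_names,
            "n_hc": self.n_hc,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "NormativeResults":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(coef=np.asarray(payload["coef"]),
                   train_mean=np.asarray(payload["train_mean"]),
                   train_sd=np.asarray(payload["train_sd"]),
                   feature_names=payload["feature_names"],
                   n_hc=payload["n_hc"])


def fit_normative(fm_train: FeatureMatrix,
                  roster_train: pd.DataFrame) -> NormativeResults:
    """Fit per-feature OLS on training healthy controls, then record the
    mean/sd of the residualized training set for scaling."""
    if not fm_train.mask.all():
        raise ConfigError("residualization requires fully observed data")
    hc = (roster_train["dx"] == "HC").to_numpy()
    n_hc = int(hc.sum())
    if n_hc == 0:
        raise FitError("training folds contain no healthy controls; "
                       "cannot fit the normative model")
    if n_hc < N_COVARIATES + 2:
        raise FitError(f"only {n_hc} healthy controls in training folds; "
                       f"need at least {N_COVARIATES + 2}")
    X = _design(roster_train)
    coef, *_ = np.linalg.lstsq(X[hc], fm_train.values[hc], rcond=None)
    resid = fm_train.values - X @ coef
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=0)
    # a residual sd at numerical-noise level means the feature is constant
    # (given the covariates) and cannot be scaled
    tol = 1e-9 * np.maximum(1.0, np.abs(fm_train.values).max(axis=0))
    if (sd <= tol).any():
        bad = [fm_train.schema.names[j] for j in np.nonzero(sd <= tol)[0]]
        raise FitError(f"constant residualized features, cannot scale: {bad}")
    return NormativeResults(coef=coef, train_mean=mean, train_sd=sd,
                            feature_names=list(fm_train.schema.names),
                            n_hc=n_hc)


def apply_normative(model: NormativeResults, fm: FeatureMatrix,
                    roster: pd.DataFrame) -> FeatureMatrix:
    """Apply frozen residualization + scaling to any data."""
    return model.transform(fm, roster)
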