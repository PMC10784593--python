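"""Subject-completeness filtering and per-cohort regression imputation.

Subjects providing less than 75% of the combined cortical and subcortical
features are excluded (strictly below: completeness of exactly 0.75 is
retained). Remaining missing entries are imputed per cohort by ordinary
least squares on age and sex of all subjects regardless of diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Dataset, FeatureMatrix
from .errors import ConfigError, FitError


@dataclass
class ExclusionReport:
    """Who was excluded by the completeness filter and why."""

    threshold: float
    excluded: pd.DataFrame          # subject_id, cohort, observed_fraction, reason
    n_before: int
    n_after: int

    @property
    def per_cohort(self) -> pd.Series:
        if len(self.excluded) == 0:
            return pd.Series(dtype=int)
        return self.excluded.groupby("cohort").size()

    def to_csv(self, path) -> None:
        self.excluded.to_csv(path, index=False)


def completeness_filter(dataset: Dataset,
                        threshold: float = 0.75) -> tuple[Dataset, ExclusionReport]:
    """Drop subjects whose observed-feature fraction is below threshold."""
    if not (0 < threshold <= 1):
        raise ConfigError("threshold must be in (0, 1]")
    frac = dataset.features.completeness()
    keep = frac >= threshold
    excluded = pd.DataFrame({
        "subject_id": dataset.roster.loc[~keep, "subject_id"].to_numpy(),
        "cohort": dataset.roster.loc[~keep, "site"].to_numpy(),
        "observed_fraction": frac[~keep],
        "reason": [f"completeness < {threshold:g}"] * int((~keep).sum()),
    })
    report = ExclusionReport(threshold=threshold, excluded=excluded,
                             n_before=dataset.n_subjects,
                             n_after=int(keep.sum()))
    return dataset.take(np.nonzero(keep)[0]), report


@dataclass
class ImputationLog:
    """Which (cohort, feature) cells used the fallback path."""

    n_imputed: int = 0
    fallbacks: list = field(default_factory=list)  # (cohort, feature, reason)


def impute_features(dataset: Dataset) -> tuple[Dataset, ImputationLog]:
    """Fill masked entries by cohort-local OLS on (intercept, age, sex).

    Diagnosis-blind: the regression pools HC and MDD. Degenerate cohorts
    fall back gracefully: a constant sex column is dropped from the design,
    and cohorts with fewer than 3 observed subjects for a feature use the
    cohort mean. A feature entirely missing within a cohort is an error.
    """
    fm = dataset.features.copy()
    roster = dataset.roster
    log = ImputationLog()
    age = roster["age"].to_numpy(float)
    female = (roster["sex"] == "F").to_numpy(float)

    for cohort, idx in roster.groupby("site").indices.items():
        idx = np.asarray(idx)
        sub_mask = fm.mask[idx]
        if sub_mask.all():
            continue
        X_full = np.column_stack([np.ones(len(idx)), age[idx], female[idx]])
        for j in np.nonzero(~sub_mask.all(axis=0))[0]:
            obs = sub_mask[:, j]
            miss = ~obs
            if not obs.any():
                raise FitError(
                    f"feature {fm.schema.names[j]!r} entirely missing in "
                    f"cohort {cohort!r}; cannot impute")
            y = fm.values[idx[obs], j]
            X = X_full[obs]
            Xm = X_full[miss]
            # drop constant predictors (e.g. single-sex cohorts)
            keep_cols = [0] + [c for c in (1, 2) if np.ptp(X[:, c]) > 0]
            pred = None
            if obs.sum() >= 3 and len(keep_cols) > 1:
                coef, _, rank, _ = np.linalg.lstsq(X[:, keep_cols], y, rcond=None)
                if rank == len(keep_cols):
                    pred = Xm[:, keep_cols] @ coef
                    if len(keep_cols) < 3:
                        log.fallbacks.append((cohort, fm.schema.names[j],
                                              "constant predictor dropped"))
            if pred is None:
                pred = np.full(miss.sum(), y.mean())
                log.fallbacks.append((cohort, fm.schema.names[j], "cohort mean"))
            fm.values[idx[miss], j] = pred
            fm.mask[idx[miss], j] = True
            log.n_imputed += int(miss.sum())
    return Dataset(roster, fm), log
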