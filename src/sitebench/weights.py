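"""Linear-SVM feature weights with bootstrap percentile confidence intervals.

The point estimate is the linear SVM trained on the full (preprocessed)
dataset; uncertainty comes from refitting the entire preprocessing +
classifier path on bootstrap resamples of subjects and taking per-feature
2.5/97.5 percentiles. Sign convention: a positive weight means larger
feature values push the decision toward MDD. Features with absolute point
weight above 0.1 are flagged informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Dataset
from .errors import ConfigError, FitError
from .combat import apply_combat, fit_combat
from .normative import apply_normative, fit_normative
from .rng import substream

INFORMATIVE_THRESHOLD = 0.1
COV_COLS = ["age", "sex", "icv"]


def _fit_weights(dataset: Dataset, harmonization: str, C: float,
                 seed: int) -> np.ndarray:
    """Full preprocessing + linear SVM on one dataset; returns the weight
    vector oriented so positive = toward MDD."""
    from sklearn.svm import LinearSVC

    roster = dataset.roster
    fm = dataset.features
    if harmonization != "none":
        model = fit_combat(fm, roster["site"].to_numpy(), roster[COV_COLS],
                           variant=harmonization)
        fm = apply_combat(model, fm, roster["site"].to_numpy(),
                          roster[COV_COLS])
    norm = fit_normative(fm, roster)
    X = apply_normative(norm, fm, roster).values
    y = (roster["dx"] == "MDD").to_numpy(int)
    clf = LinearSVC(C=C, class_weight="balanced", dual="auto",
                    max_iter=20000, random_state=seed)
    clf.fit(X, y)
    return clf.coef_.ravel()  # class 1 = MDD, so positive points to MDD


@dataclass
class WeightTable:
    """Per-feature weight, CI and informative flag."""

    table: pd.DataFrame
    harmonization: str
    B: int
    n_redraws: int
    C: float

    def informative_features(self) -> list:
        return self.table.loc[self.table["informative"], "feature"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bootstrap_weights(dataset: Dataset, harmonization: str = "none",
                      B: int = 599, seed: int = 0, C: float | None = None,
                      stratify_by_site: bool = True,
                      refit_harmonization: bool = True) -> WeightTable:
    """B bootstrap resamples of subjects; the full preprocessing and SVM fit
    are recomputed per resample.

    The SVM penalty C is frozen across resamples: either supplied, or chosen
    once on the full dataset by nested search. Resampling is stratified by
    site by default so cohort composition is preserved; a resample missing a
    class is redrawn (counted). With refit_harmonization=False the
    harmonization model from the full data is reused inside resamples.
    """
    if B < 2:
        raise ConfigError("B must be >= 2")
    roster = dataset.roster
    y_all = (roster["dx"] == "MDD").to_numpy(int)
    if len(np.unique(y_all)) < 2:
        raise ConfigError("dataset must contain both classes")

    if C is None:
        from .bench import ModelSpec, default_grid, nested_fit
        from .normative import fit_normative as _fitn
        fm = dataset.features
        frozen = None
        if harmonization != "none":
            frozen = fit_combat(fm, roster["site"].to_numpy(),
                                roster[COV_COLS], variant=harmonization)
            fm = apply_combat(frozen, fm, roster["site"].to_numpy(),
                              roster[COV_COLS])
        norm = _fitn(fm, roster)
        X = apply_normative(norm, fm, roster).values
        fitted = nested_fit(X, y_all, ModelSpec("svm_linear",
                                                default_grid("svm_linear")),
                            inner_k=10, seed=seed)
        C = float(fitted.params["C"])

    point = _fit_weights(dataset, harmonization, C, seed)

    rng = substream(seed, "bootstrap")
    n = dataset.n_subjects
    site_groups = ([np.asarray(idx) for _, idx
                    in roster.groupby("site").indices.items()]
                   if stratify_by_site else [np.arange(n)])
    frozen_model = None
    if harmonization != "none" and not refit_harmonization:
        frozen_model = fit_combat(dataset.features,
                                  roster["site"].to_numpy(),
                                  roster[COV_COLS], variant=harmonization)

    weights = np.empty((B, dataset.features.values.shape[1]))
    n_redraws = 0
    b = 0
    while b < B:
        rows = np.concatenate([rng.choice(g, size=len(g), replace=True)
                               for g in site_groups])
        if len(np.unique(y_all[rows])) < 2:
            n_redraws += 1
            if n_redraws > 100 * B:
                raise FitError("bootstrap resampling keeps missing a class")
            continue
        boot = dataset.take(np.sort(rows))
        if frozen_model is not None:
            fm = apply_combat(frozen_model, boot.features,
                              boot.roster["site"].to_numpy(),
                              boot.roster[COV_COLS])
            norm = fit_normative(fm, boot.roster)
            X = apply_normative(norm, fm, boot.roster).values
            from sklearn.svm import LinearSVC
            clf = LinearSVC(C=C, class_weight="balanced", dual="auto",
                            max_iter=20000, random_state=seed)
            clf.fit(X, (boot.roster["dx"] == "MDD").to_numpy(int))
            weights[b] = clf.coef_.ravel()
        else:
            weights[b] = _fit_weights(boot, harmonization, C, seed)
        b += 1

    lo = np.percentile(weights, 2.5, axis=0)
    hi = np.percentile(weights, 97.5, axis=0)
    schema = dataset.features.schema
    table = pd.DataFrame({
        "feature": list(schema.names),
        "class": list(schema.classes),
        "hemisphere": list(schema.hemispheres),
        "weight": point,
        "ci_low": lo,
        "ci_high": hi,
        "informative": np.abs(point) > INFORMATIVE_THRESHOLD,
        "ci_brackets_point": (lo <= point) & (point <= hi),
        "harmonization": harmonization,
    })
    return WeightTable(table=table, harmonization=harmonization, B=B,
                       n_redraws=n_redraws, C=C)
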