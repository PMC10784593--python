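"""Site-effect forensics.

These experiments localize where pre-harmonization classification accuracy
comes from: can a classifier identify the *site* (or the scanner group) from
the features; does removing demographic covariates change that; and does
rebalancing demographics across sites remove the confound (it should not,
if the site effect is scanner-driven).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Dataset
from .errors import ConfigError, FitError
from .combat import harmonize_in_cv
from .normative import apply_normative, fit_normative
from .rng import substream
from .splitting import split_by_age_sex


@dataclass
class LabelClassificationResult:
    """Per-fold multi-class balanced accuracy for a label task."""

    label: str
    harmonization: str
    residualize: str
    table: pd.DataFrame       # fold, balanced_accuracy, n_test
    n_classes: int
    y_true: np.ndarray | None = None   # pooled over folds
    y_pred: np.ndarray | None = None

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_classes

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(self.table["balanced_accuracy"].mean())

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["label"] = self.label
        out["harmonization"] = self.harmonization
        out["residualize"] = self.residualize
        out["chance_level"] = self.chance_level
        out["n_classes"] = self.n_classes
        return out


def _macro_recall(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Balanced accuracy generalized to many classes: macro-averaged recall
    over the classes present in the test data."""
    recalls = []
    for cls in np.unique(y_true):
        sel = y_true == cls
        recalls.append(float((y_pred[sel] == cls).mean()))
    return float(np.mean(recalls))


def label_classification(dataset: Dataset, label: str = "site",
                         harmonization: str = "none", seed: int = 0,
                         k: int = 10, residualize: str = "normative",
                         C: float = 1.0) -> LabelClassificationResult:
    """Classify subjects by site or scanner group with a linear SVM.

    Uses the age/sex splitting (every class present in every fold), the same
    preprocessing order as the main benchmark, and one-vs-rest linear SVM.
    residualize: 'normative' (healthy-control regressors, the benchmark
    default), 'train_all' (covariates regressed on all training subjects) or
    'none' (training-anchored scaling only).
    """
    from sklearn.svm import LinearSVC

    if label not in dataset.roster.columns:
        raise ConfigError(f"label column {label!r} absent from roster")
    labels_all = dataset.roster[label].astype(str).to_numpy()
    classes = np.unique(labels_all)
    if len(classes) < 2:
        raise ConfigError(f"label {label!r} has fewer than 2 classes")

    assignment = split_by_age_sex(dataset.roster, k=k, seed=seed)
    rows = []
    trues, preds = [], []
    for f, tr_idx, te_idx, tr_fm, te_fm in _preprocessed_iterations(
            dataset, assignment, harmonization):
        tr_roster = dataset.roster.iloc[tr_idx]
        te_roster = dataset.roster.iloc[te_idx]
        Xtr, Xte = _residualize(tr_fm, te_fm, tr_roster, te_roster,
                                residualize)
        ytr = labels_all[tr_idx]
        yte = labels_all[te_idx]
        clf = LinearSVC(C=C, class_weight="balanced", dual="auto",
                        max_iter=20000, random_state=seed)
        clf.fit(Xtr, ytr)
        yhat = clf.predict(Xte)
        trues.append(yte)
        preds.append(yhat)
        rows.append({"fold": f,
                     "balanced_accuracy": _macro_recall(yte, yhat),
                     "n_test": len(te_idx)})
    return LabelClassificationResult(
        label=label, harmonization=harmonization, residualize=residualize,
        table=pd.DataFrame(rows), n_classes=len(classes),
        y_true=np.concatenate(trues), y_pred=np.concatenate(preds))


def _preprocessed_iterations(dataset, assignment, harmonization):
    if harmonization != "none":
        yield from harmonize_in_cv(dataset, assignment, variant=harmonization)
        return
    roster = dataset.roster
    fold = roster["subject_id"].map(assignment.fold_of)
    assigned = fold.notna().to_numpy()
    fold = fold.to_numpy()
    for f in range(1, assignment.k + 1):
        te = np.nonzero(assigned & (fold == f))[0]
        tr = np.nonzero(assigned & (fold != f))[0]
        if len(te) == 0:
            continue
        yield f, tr, te, dataset.features.take(tr), dataset.features.take(te)


def _residualize(tr_fm, te_fm, tr_roster, te_roster, mode: str):
    if mode == "normative":
        norm = fit_normative(tr_fm, tr_roster)
        return (apply_normative(norm, tr_fm, tr_roster).values,
                apply_normative(norm, te_fm, te_roster).values)
    if mode == "train_all":
        from .normative import _design
        X = _design(tr_roster)
        coef, *_ = np.linalg.lstsq(X, tr_fm.values, rcond=None)
        rtr = tr_fm.values - X @ coef
        rte = te_fm.values - _design(te_roster) @ coef
        mean, sd = rtr.mean(axis=0), rtr.std(axis=0, ddof=0)
        sd = np.maximum(sd, 1e-12)
        return (rtr - mean) / sd, (rte - mean) / sd
    if mode == "none":
        mean = tr_fm.values.mean(axis=0)
        sd = np.maximum(tr_fm.values.std(axis=0, ddof=0), 1e-12)
        return ((tr_fm.values - mean) / sd, (te_fm.values - mean) / sd)
    raise ConfigError(f"unknown residualize mode {mode!r}")


def regress_covariates_then_classify(dataset: Dataset, label: str = "site",
                                     seed: int = 0, k: int = 10) -> dict:
    """Does removing demographic covariates kill site predictability?

    Runs the label task with no covariate control and with age/sex/ICV
    regressed out on the whole training folds, and reports the change. A
    scanner-driven site effect survives the regression; a purely demographic
    one collapses toward chance.
    """
    raw = label_classification(dataset, label=label, seed=seed, k=k,
                               residualize="none")
    regressed = label_classification(dataset, label=label, seed=seed, k=k,
                                     residualize="train_all")
    return {
        "raw": raw,
        "regressed": regressed,
        "delta": regressed.mean_balanced_accuracy - raw.mean_balanced_accuracy,
    }


def rebalance_age_sex(dataset: Dataset, seed: int = 0,
                      bin_width: float = 10.0) -> tuple[Dataset, pd.DataFrame]:
    """Subsample every site onto a common age-decade x sex grid.

    All sites end with the same cell proportions (those of the pooled data
    restricted to the common cells). Sites with disjoint demographics leave
    no common cell, which is an error naming the incompatible sites.
    Returns the rebalanced dataset and a per-site retention report.
    """
    rng = substream(seed, "rebalance")
    roster = dataset.roster
    cell = list(zip((roster["age"] // bin_width).astype(int), roster["sex"]))
    cells_by_site = {site: set(cell[i] for i in idx)
                     for site, idx in roster.groupby("site").indices.items()}
    common = set.intersection(*cells_by_site.values())
    if not common:
        ranges = {s: f"[{roster['age'].iloc[list(i)].min():.0f}-"
                     f"{roster['age'].iloc[list(i)].max():.0f}]"
                  for s, i in roster.groupby("site").indices.items()}
        raise ConfigError("no common age/sex support across sites: "
                          f"{ranges}")
    common = sorted(common)
    cell_of = pd.Series(cell)
    # pooled proportions over the common cells
    pooled = cell_of[cell_of.isin(common)].value_counts()
    w = pooled.loc[common] / pooled.loc[common].sum()

    keep_rows: list[int] = []
    report_rows = []
    for site, idx in roster.groupby("site").indices.items():
        idx = np.asarray(idx)
        site_cells = cell_of.iloc[idx]
        counts = {c: int((site_cells == c).sum()) for c in common}
        # largest n_target such that round(w_c * n) <= count_c for all c
        n_target = int(min(counts[c] / w[c] for c in common))
        kept = 0
        for c in common:
            take = min(int(round(w[c] * n_target)), counts[c])
            if take == 0:
                continue
            pool = idx[(site_cells == c).to_numpy()]
            chosen = rng.choice(pool, size=take, replace=False)
            keep_rows.extend(chosen.tolist())
            kept += take
        report_rows.append({"site": site, "n_before": len(idx),
                            "n_after": kept})
    if not keep_rows:
        raise ConfigError("rebalancing retained no subjects")
    out = dataset.take(np.sort(np.asarray(keep_rows)))
    return out, pd.DataFrame(report_rows)


def diagnostics_table(results: list[LabelClassificationResult]) -> pd.DataFrame:
    """Machine-readable experiment summary (one row per experiment)."""
    rows = []
    for r in results:
        rows.append({
            "experiment": f"{r.label}_classification",
            "label": r.label,
            "harmonization": r.harmonization,
            "residualize": r.residualize,
            "balanced_accuracy": r.mean_balanced_accuracy,
            "chance_level": r.chance_level,
            "n_classes": r.n_classes,
        })
    return pd.DataFrame(rows)
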