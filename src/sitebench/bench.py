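"""Case-control classification benchmark.

Executes, per cross-validation iteration, the fixed leakage-aware order:
(optional) harmonization fit on training folds and applied to both, then
normative residualization + training-anchored scaling, then nested
hyperparameter search and class-weighted fitting on the training folds,
then prediction of the held-out fold. Metrics: balanced accuracy,
sensitivity, specificity (MDD positive) and AUC from continuous scores.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Dataset
from .errors import ConfigError, FitError
from .combat import harmonize_in_cv
from .normative import apply_normative, fit_normative
from .rng import substream
from .splitting import FoldAssignment, split_by_age_sex, split_by_site

HARMONIZATION_CHOICES = ("none", "combat", "combat_gam", "covbat")
FEATURE_SUBSETS = ("all", "thickness", "surface_area", "subcortical")

POSITIVE = "MDD"


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class Metrics:
    balanced_accuracy: float
    auc: float
    sensitivity: float
    specificity: float


def compute_metrics(y_true, y_pred, score) -> Metrics:
    """Binary metrics with MDD as the positive class.

    AUC is the rank statistic of the score for MDD over HC (ties count 0.5),
    i.e. the Mann-Whitney estimate.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    score = np.asarray(score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(score)):
        raise ConfigError("metric inputs must have equal length")
    pos = y_true == 1
    if pos.all() or not pos.any():
        raise ConfigError("y_true contains a single class; balanced accuracy "
                          "is undefined")
    tp = int(((y_pred == 1) & pos).sum())
    fn = int(((y_pred == 0) & pos).sum())
    tn = int(((y_pred == 0) & ~pos).sum())
    fp = int(((y_pred == 1) & ~pos).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    from scipy.stats import rankdata
    ranks = rankdata(score)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return Metrics(balanced_accuracy=(sens + spec) / 2.0, auc=float(auc),
                   sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# model zoo

MODEL_NAMES = ("svm_linear", "svm_rbf", "svm_pca", "svm_ttest",
               "lasso", "ridge", "elastic_net", "random_forest")

_C_LADDER = [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
_GAMMA_LADDER = [1e-4, 1e-3, 1e-2, 1e-1, 1.0]


@dataclass
class ModelSpec:
    """A named classifier with its hyperparameter grid.

    Grid lists must be ordered from simplest (strongest regularization,
    smallest capacity) to most complex; ties in the inner search resolve to
    the earliest grid point.
    """

    name: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model {self.name!r}")
        if not self.grid:
            raise ConfigError(f"model {self.name}: empty hyperparameter grid")

    def combinations(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, vals))
                for vals in itertools.product(*(self.grid[k] for k in keys))]


def default_grid(name: str) -> dict:
    return {
        "svm_linear": {"C": list(_C_LADDER)},
        "svm_rbf": {"C": list(_C_LADDER), "gamma": list(_GAMMA_LADDER)},
        "svm_pca": {"pca_var": [0.8, 0.9, 0.95], "C": list(_C_LADDER)},
        "svm_ttest": {"top_pct": [25, 50, 75], "C": list(_C_LADDER)},
        "lasso": {"C": list(_C_LADDER)},
        "ridge": {"C": list(_C_LADDER)},
        "elastic_net": {"C": list(_C_LADDER), "l1_ratio": [0.25, 0.5, 0.75]},
        "random_forest": {"n_estimators": [200, 500],
                          "max_depth": [5, 10, None]},
    }[name]


def compact_grid(name: str) -> dict:
    """Single-point grids for fast benchmark runs (no inner search)."""
    return {
        "svm_linear": {"C": [1.0]},
        "svm_rbf": {"C": [1.0], "gamma": ["scale"]},
        "svm_pca": {"pca_var": [0.9], "C": [1.0]},
        "svm_ttest": {"top_pct": [50], "C": [1.0]},
        "lasso": {"C": [1.0]},
        "ridge": {"C": [1.0]},
        "elastic_net": {"C": [1.0], "l1_ratio": [0.5]},
        "random_forest": {"n_estimators": [200], "max_depth": [None]},
    }[name]


def model_zoo(names=MODEL_NAMES, compact: bool = False) -> list[ModelSpec]:
    maker = compact_grid if compact else default_grid
    return [ModelSpec(n, maker(n)) for n in names]


def build_estimator(name: str, params: dict, seed: int = 0):
    """Instantiate the sklearn estimator for one grid point.

    All classifiers weight classes inversely to their training frequency.
    """
    from sklearn.decomposition import PCA
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.feature_selection import SelectPercentile, f_classif
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import Pipeline
    from sklearn.svm import SVC, LinearSVC

    if name == "svm_linear":
        return LinearSVC(C=params["C"], class_weight="balanced",
                         dual="auto", max_iter=20000, random_state=seed)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                   class_weight="balanced", random_state=seed)
    if name == "svm_pca":
        return Pipeline([
            ("pca", PCA(n_components=params["pca_var"], svd_solver="full",
                        random_state=seed)),
            ("svm", LinearSVC(C=params["C"], class_weight="balanced",
                              dual="auto", max_iter=20000, random_state=seed)),
        ])
    if name == "svm_ttest":
        return Pipeline([
            ("select", SelectPercentile(f_classif,
                                        percentile=params["top_pct"])),
            ("svm", LinearSVC(C=params["C"], class_weight="balanced",
                              dual="auto", max_iter=20000, random_state=seed)),
        ])
    if name == "lasso":
        return LogisticRegression(l1_ratio=1.0, C=params["C"],
                                  solver="liblinear", class_weight="balanced",
                                  max_iter=5000, random_state=seed)
    if name == "ridge":
        return LogisticRegression(l1_ratio=0.0, C=params["C"],
                                  solver="lbfgs", class_weight="balanced",
                                  max_iter=5000, random_state=seed)
    if name == "elastic_net":
        return LogisticRegression(l1_ratio=params["l1_ratio"], C=params["C"],
                                  solver="saga", class_weight="balanced",
                                  max_iter=5000, tol=1e-3, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=params["n_estimators"],
                                      max_depth=params["max_depth"],
                                      class_weight="balanced", n_jobs=1,
                                      random_state=seed)
    raise ConfigError(f"unknown model {name!r}")


def decision_scores(estimator, X) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X))
    return np.asarray(estimator.predict_proba(X)[:, 1])


@dataclass
class FittedModel:
    spec_name: str
    params: dict
    estimator: object
    inner_score: float | None = None

    def predict(self, X):
        return self.estimator.predict(X)

    def scores(self, X):
        return decision_scores(self.estimator, X)


def nested_fit(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
               inner_k: int = 10, seed: int = 0) -> FittedModel:
    """Grid search by inner k-fold CV (random splits), refit on all data.

    The grid point maximizing mean inner balanced accuracy wins; ties go to
    the earliest (simplest) point. A singleton grid skips the inner loop.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise FitError("training data contains a single class")
    combos = spec.combinations()
    chosen, inner_score = combos[0], None
    if len(combos) > 1:
        from sklearn.model_selection import KFold
        folds = None
        for attempt in range(2):
            kf = KFold(n_splits=inner_k, shuffle=True,
                       random_state=seed + attempt)
            candidate = list(kf.split(X))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
                folds = candidate
                break
        if folds is None:
            raise FitError("inner CV folds lack a class even after a redraw")
        best = -np.inf
        for combo in combos:
            accs = []
            for tr, te in folds:
                if len(np.unique(y[te])) < 2:
                    continue  # balanced accuracy undefined on this inner fold
                est = build_estimator(spec.name, combo, seed=seed)
                est.fit(X[tr], y[tr])
                m = compute_metrics(y[te], est.predict(X[te]),
                                    decision_scores(est, X[te]))
                accs.append(m.balanced_accuracy)
            mean_acc = float(np.mean(accs)) if accs else -np.inf
            if mean_acc > best:
                best, chosen = mean_acc, combo
        inner_score = best
    est = build_estimator(spec.name, chosen, seed=seed)
    est.fit(X, y)
    return FittedModel(spec.name, chosen, est, inner_score)


# ---------------------------------------------------------------------------
# benchmark driver

@dataclass
class BenchmarkResults:
    """Per-(model, fold) metrics with configuration provenance."""

    table: pd.DataFrame
    provenance: dict
    models: dict = field(default_factory=dict)  # (model, fold) -> pickle bytes

    def mean_by_model(self) -> pd.DataFrame:
        """Across-fold aggregation, both simple and fold-size-weighted."""
        rows = []
        for model, g in self.table.groupby("model", sort=True):
            w = g["n_test"].to_numpy(float)
            rows.append({
                "model": model,
                "balanced_accuracy": g["balanced_accuracy"].mean(),
                "balanced_accuracy_weighted":
                    float(np.average(g["balanced_accuracy"], weights=w)),
                "auc": g["auc"].mean(),
                "sensitivity": g["sensitivity"].mean(),
                "specificity": g["specificity"].mean(),
                "balanced_accuracy_se":
                    float(g["balanced_accuracy"].std(ddof=1)
                          / np.sqrt(len(g))) if len(g) > 1 else 0.0,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        prov = ", ".join(f"{k}={v}" for k, v in self.provenance.items())
        agg = self.mean_by_model()
        lines = [f"Classification benchmark ({prov})",
                 agg.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for k, v in self.provenance.items():
            out[k] = str(v)
        out.to_csv(path, index=False)


@dataclass
class ClassificationBenchmark:
    """Benchmark of MDD-vs-HC classifiers under a fold assignment.

    Fixed stage order per CV iteration: harmonize (training-fold fit) ->
    normative residualization + scaling (training-fold fit) -> nested
    hyperparameter search -> test-fold prediction.
    """

    dataset: Dataset
    assignment: FoldAssignment
    harmonization: str = "none"
    models: list = None
    feature_subset: str = "all"
    seed: int = 0
    inner_k: int = 10
    store_models: bool = False

    def __post_init__(self):
        if self.harmonization not in HARMONIZATION_CHOICES:
            raise ConfigError(
                f"harmonization must be one of {HARMONIZATION_CHOICES}")
        if self.feature_subset not in FEATURE_SUBSETS:
            raise ConfigError(
                f"feature_subset must be one of {FEATURE_SUBSETS}")
        if self.models is None:
            self.models = model_zoo()
        if not self.models:
            raise ConfigError("no models specified")

    def _iterations(self, data: Dataset):
        """Yield (fold, train_idx, test_idx, train_fm, test_fm) with the
        harmonization stage already applied when requested."""
        if self.harmonization != "none":
            variant = self.harmonization
            yield from harmonize_in_cv(data, self.assignment, variant=variant)
            return
        roster = data.roster
        fold = roster["subject_id"].map(self.assignment.fold_of)
        assigned = fold.notna().to_numpy()
        fold = fold.to_numpy()
        for f in range(1, self.assignment.k + 1):
            test_idx = np.nonzero(assigned & (fold == f))[0]
            train_idx = np.nonzero(assigned & (fold != f))[0]
            if len(test_idx) == 0:
                continue
            yield (f, train_idx, test_idx, data.features.take(train_idx),
                   data.features.take(test_idx))

    def fit(self) -> BenchmarkResults:
        data = self.dataset.subset_features(self.feature_subset)
        rows = []
        stored = {}
        rng = substream(self.seed, "bench")
        for f, tr_idx, te_idx, tr_fm, te_fm in self._iterations(data):
            tr_roster = data.roster.iloc[tr_idx]
            te_roster = data.roster.iloc[te_idx]
            try:
                norm = fit_normative(tr_fm, tr_roster)
            except FitError as err:
                raise FitError(f"fold {f}: {err}") from err
            Xtr = apply_normative(norm, tr_fm, tr_roster).values
            Xte = apply_normative(norm, te_fm, te_roster).values
            ytr = (tr_roster["dx"] == POSITIVE).to_numpy(int)
            yte = (te_roster["dx"] == POSITIVE).to_numpy(int)
            fold_seed = int(rng.integers(2 ** 31 - 1))
            for spec in self.models:
                try:
                    fitted = nested_fit(Xtr, ytr, spec,
                                        inner_k=self.inner_k, seed=fold_seed)
                    m = compute_metrics(yte, fitted.predict(Xte),
                                        fitted.scores(Xte))
                except (FitError, ConfigError) as err:
                    raise FitError(
                        f"fold {f}, model {spec.name}: {err}") from err
                rows.append({
                    "model": spec.name, "fold": f,
                    "balanced_accuracy": m.balanced_accuracy, "auc": m.auc,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "n_test": len(te_idx),
                    "chosen_params": str(fitted.params),
                })
                if self.store_models:
                    stored[(spec.name, f)] = pickle.dumps(fitted.estimator)
        table = pd.DataFrame(rows)
        prov = {"strategy": self.assignment.strategy,
                "harmonization": self.harmonization,
                "feature_subset": self.feature_subset,
                "seed": self.seed}
        return BenchmarkResults(table=table, provenance=prov, models=stored)


def run_benchmark(dataset: Dataset, assignment: FoldAssignment,
                  harmonization: str = "none", models=None,
                  feature_subset: str = "all", seed: int = 0,
                  inner_k: int = 10,
                  store_models: bool = False) -> BenchmarkResults:
    """Functional surface over :class:`ClassificationBenchmark`."""
    return ClassificationBenchmark(
        dataset, assignment, harmonization=harmonization, models=models,
        feature_subset=feature_subset, seed=seed, inner_k=inner_k,
        store_models=store_models).fit()


# ---------------------------------------------------------------------------
# stratified runs and ratio equalization

STRATA = {
    "sex_M": ("sex", "M", "demographic"),
    "sex_F": ("sex", "F", "demographic"),
    "onset_adolescent": ("onset_group", "adolescent", "clinical"),
    "onset_adult": ("onset_group", "adult", "clinical"),
    "antidepressant_yes": ("antidepressant", "yes", "clinical"),
    "antidepressant_no": ("antidepressant", "no", "clinical"),
    "first_episode": ("episodes", "first", "clinical"),
    "recurrent": ("episodes", "recurrent", "clinical"),
}


def stratum_subset(dataset: Dataset, stratum: str) -> Dataset:
    """Subjects entering a stratified run.

    Demographic strata (sex) filter all subjects; clinical strata keep every
    HC plus the MDD subjects with the matching value. Subjects with missing
    information on the factor are excluded from the stratified run only.
    """
    if stratum not in STRATA:
        raise ConfigError(f"unknown stratum {stratum!r}; "
                          f"expected one of {sorted(STRATA)}")
    col, value, kind = STRATA[stratum]
    roster = dataset.roster
    if kind == "demographic":
        keep = (roster[col] == value).to_numpy()
    else:
        is_hc = (roster["dx"] == "HC").to_numpy()
        keep = is_hc | (roster[col] == value).to_numpy()
    if not keep.any():
        raise ConfigError(f"stratum {stratum!r} selects no subjects")
    return dataset.take(np.nonzero(keep)[0])


def stratified_benchmark(dataset: Dataset, stratum: str,
                         strategy: str = "age_sex", k: int = 10,
                         harmonization: str = "none", models=None,
                         feature_subset: str = "all",
                         seed: int = 0, inner_k: int = 10) -> BenchmarkResults:
    """Subset to a demographic/clinical stratum, re-split, and benchmark."""
    sub = stratum_subset(dataset, stratum)
    if strategy == "age_sex":
        assignment = split_by_age_sex(sub.roster, k=k, seed=seed)
    elif strategy == "site":
        assignment = split_by_site(sub.roster, k=k)
    else:
        raise ConfigError(f"unknown strategy {strategy!r}")
    res = run_benchmark(sub, assignment, harmonization=harmonization,
                        models=models, feature_subset=feature_subset,
                        seed=seed, inner_k=inner_k)
    res.provenance["stratum"] = stratum
    return res


def equalize_ratio(dataset: Dataset, seed: int = 0) -> Dataset:
    """Subsample each site's majority class to a 1:1 MDD:HC ratio.

    Sites lacking one of the classes entirely are dropped.
    """
    rng = substream(seed, "equalize-ratio")
    roster = dataset.roster
    keep_rows: list[int] = []
    for site, idx in roster.groupby("site").indices.items():
        idx = np.asarray(idx)
        dx = roster["dx"].to_numpy()[idx]
        mdd_idx = idx[dx == "MDD"]
        hc_idx = idx[dx == "HC"]
        n = min(len(mdd_idx), len(hc_idx))
        if n == 0:
            continue
        if len(mdd_idx) > n:
            mdd_idx = rng.choice(mdd_idx, size=n, replace=False)
        if len(hc_idx) > n:
            hc_idx = rng.choice(hc_idx, size=n, replace=False)
        keep_rows.extend(mdd_idx.tolist())
        keep_rows.extend(hc_idx.tolist())
    if not keep_rows:
        raise ConfigError("no site has both classes; cannot equalize")
    return dataset.take(np.sort(np.asarray(keep_rows)))
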