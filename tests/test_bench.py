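"""Metrics arithmetic, nested search, class handling and stratified runs."""

import numpy as np
import pandas as pd
import pytest

import sitebench as sb
from sitebench.bench import (ModelSpec, compute_metrics, equalize_ratio,
                             model_zoo, nested_fit, run_benchmark,
                             stratified_benchmark, stratum_subset)
from sitebench.errors import ConfigError, FitError
from sitebench.simulate import ScenarioConfig, SiteSpec, generate_features, generate_roster
from sitebench.containers import Dataset
from conftest import make_tiny_dataset


def test_metrics_arithmetic():
    y = np.array([1, 1, 0, 0])
    m = compute_metrics(y, y, np.array([2.0, 1.5, -1.0, -2.0]))
    assert (m.balanced_accuracy, m.auc, m.sensitivity, m.specificity) == \
        (1.0, 1.0, 1.0, 1.0)

    # confusion counts TP=30, FN=10, TN=40, FP=20
    y_true = np.array([1] * 40 + [0] * 60)
    y_pred = np.array([1] * 30 + [0] * 10 + [0] * 40 + [1] * 20)
    m = compute_metrics(y_true, y_pred, y_pred.astype(float))
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(2 / 3)
    assert m.balanced_accuracy == pytest.approx((0.75 + 2 / 3) / 2, abs=1e-12)
    assert m.balanced_accuracy == pytest.approx(
        (m.sensitivity + m.specificity) / 2, abs=1e-12)

    with pytest.raises(ConfigError):
        compute_metrics(np.ones(10), np.ones(10), np.ones(10))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 1_000_000))
def test_metrics_invariants_hold_for_random_outcomes(n_pos, n_neg, seed):
    """Balanced accuracy is exactly the sensitivity/specificity mean, all
    metrics live in [0, 1], and AUC flips under score negation."""
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    pred = rng.integers(0, 2, n_pos + n_neg)
    score = rng.normal(size=n_pos + n_neg)
    m = compute_metrics(y, pred, score)
    assert m.balanced_accuracy == pytest.approx(
        (m.sensitivity + m.specificity) / 2, abs=1e-12)
    for v in (m.balanced_accuracy, m.auc, m.sensitivity, m.specificity):
        assert 0.0 <= v <= 1.0
    flipped = compute_metrics(y, pred, -score)
    assert flipped.auc == pytest.approx(1.0 - m.auc, abs=1e-12)


def test_auc_is_null_for_uninformative_scores():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 4000)
    score = rng.normal(size=4000)
    m = compute_metrics(y, (score > 0).astype(int), score)
    assert abs(m.auc - 0.5) < 0.03
    # tied scores give exactly 0.5
    m2 = compute_metrics(y, np.zeros(4000, int), np.zeros(4000))
    assert m2.auc == pytest.approx(0.5)


def test_nested_fit_singleton_and_separable():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(-3, 0.5, (50, 10)), rng.normal(3, 0.5, (50, 10))])
    y = np.array([0] * 50 + [1] * 50)
    spec = ModelSpec("svm_linear", {"C": [1.0]})
    fitted = nested_fit(X, y, spec, seed=0)
    assert fitted.params == {"C": 1.0}
    assert fitted.inner_score is None   # singleton grid skips the inner loop
    m = compute_metrics(y, fitted.predict(X), fitted.scores(X))
    assert m.balanced_accuracy == 1.0

    with pytest.raises(FitError):
        nested_fit(X, np.zeros(100, int), spec)


def test_lasso_prunes_null_features():
    """With 5 informative of 152 features, the selected penalty zeroes most
    null coefficients."""
    rng = np.random.default_rng(2)
    n = 400
    X = rng.normal(size=(n, 152))
    beta = np.zeros(152)
    beta[:5] = 1.5
    y = (X @ beta + rng.normal(0, 1.0, n) > 0).astype(int)
    spec = ModelSpec("lasso", {"C": [1e-3, 1e-2, 1e-1, 1.0, 10.0]})
    fitted = nested_fit(X, y, spec, inner_k=5, seed=3)
    coef = fitted.estimator.coef_.ravel()
    assert (coef[5:] == 0).mean() >= 0.8
    assert (np.abs(coef[:5]) > 0).all()


def test_class_weighting_handles_imbalance():
    """Heavily imbalanced training data still yields sensible balanced
    accuracy because classes are reweighted."""
    sites = [SiteSpec("a", 600, pct_mdd=0.15)]
    theta = np.zeros(152)
    theta[:30] = 0.8
    cfg = ScenarioConfig(sites=sites, theta=theta, seed=87)
    roster = generate_roster(sites, 87)
    ds = Dataset(roster, generate_features(roster, cfg))
    asn = sb.split_by_age_sex(ds.roster, k=5, seed=0)
    res = run_benchmark(ds, asn, models=[ModelSpec("svm_linear", {"C": [1.0]})],
                        seed=0)
    agg = res.mean_by_model()
    assert agg["balanced_accuracy"].iloc[0] > 0.6
    assert agg["sensitivity"].iloc[0] > 0.4   # minority class not ignored


def test_benchmark_determinism(confounded_small):
    asn = sb.split_by_age_sex(confounded_small.roster, k=5, seed=2)
    models = [ModelSpec("svm_linear", {"C": [1.0]})]
    a = run_benchmark(confounded_small, asn, models=models, seed=5)
    b = run_benchmark(confounded_small, asn, models=models, seed=5)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_feature_subsets_change_dimensionality(confounded_small):
    asn = sb.split_by_age_sex(confounded_small.roster, k=5, seed=2)
    models = [ModelSpec("svm_linear", {"C": [1.0]})]
    res = run_benchmark(confounded_small, asn, models=models,
                        feature_subset="subcortical", seed=5,
                        store_models=True)
    import pickle
    est = pickle.loads(next(iter(res.models.values())))
    assert est.coef_.shape[1] == 16


def test_equalize_ratio_counts_and_dropping():
    roster = sb.validate_roster(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(79 + 20)],
        "site": ["mixed"] * 79 + ["patients_only"] * 20,
        "age": np.linspace(20, 60, 99),
        "sex": ["F", "M"] * 49 + ["F"],
        "dx": ["MDD"] * 33 + ["HC"] * 46 + ["MDD"] * 20,
        "icv": np.full(99, 1.5e6),
    }))
    values = np.zeros((99, 152))
    fm = sb.FeatureMatrix(list(roster.subject_id), sb.canonical_schema(),
                          values, np.ones((99, 152), bool))
    ds = Dataset(roster, fm)
    out = equalize_ratio(ds, seed=0)
    counts = out.roster.groupby(["site", "dx"]).size()
    assert counts.loc[("mixed", "MDD")] == 33
    assert counts.loc[("mixed", "HC")] == 33
    assert "patients_only" not in set(out.roster.site)
    # seeded determinism
    out2 = equalize_ratio(ds, seed=0)
    assert list(out.roster.subject_id) == list(out2.roster.subject_id)


def test_stratum_subset_semantics(confounded_small):
    roster = confounded_small.roster
    females = stratum_subset(confounded_small, "sex_F")
    assert (females.roster.sex == "F").all()

    sub = stratum_subset(confounded_small, "antidepressant_yes")
    mdd = sub.roster[sub.roster.dx == "MDD"]
    assert (mdd.antidepressant == "yes").all()
    # every HC is retained in clinical strata
    assert (sub.roster.dx == "HC").sum() == (roster.dx == "HC").sum()
    # MDD subjects with missing info are excluded from this run only
    missing = roster[(roster.dx == "MDD") & roster.antidepressant.isna()]
    assert len(missing) > 0
    assert not set(missing.subject_id) & set(sub.roster.subject_id)


def test_stratified_benchmark_runs(confounded_small):
    res = stratified_benchmark(confounded_small, "sex_F", strategy="age_sex",
                               k=5, models=[ModelSpec("ridge", {"C": [1.0]})],
                               seed=1)
    assert res.provenance["stratum"] == "sex_F"
    assert len(res.table) == 5
    assert res.table["balanced_accuracy"].between(0, 1).all()


def test_invalid_configurations_rejected(confounded_small):
    asn = sb.split_by_age_sex(confounded_small.roster, k=5, seed=2)
    with pytest.raises(ConfigError):
        run_benchmark(confounded_small, asn, harmonization="magic")
    with pytest.raises(ConfigError):
        run_benchmark(confounded_small, asn, feature_subset="everything")
    with pytest.raises(ConfigError):
        ModelSpec("svm_linear", {})
    with pytest.raises(ConfigError):
        ModelSpec("perceptron", {"C": [1.0]})
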