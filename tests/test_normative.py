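"""Normative residualization: HC-only fits, frozen scaling, label blindness."""

import numpy as np
import pandas as pd
import pytest

import sitebench as sb
from sitebench.containers import Dataset, FeatureMatrix
from sitebench.errors import FitError
from sitebench.normative import apply_normative, fit_normative
from conftest import make_tiny_dataset


def _exact_age_dataset():
    n = 40
    rng = np.random.default_rng(0)
    roster = sb.validate_roster(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "site": ["c"] * n,
        "age": rng.uniform(20, 60, n),
        "sex": rng.choice(["F", "M"], n).tolist(),
        "dx": ["HC"] * (n // 2) + ["MDD"] * (n // 2),
        "icv": rng.normal(1.5e6, 1e5, n),
    }))
    values = rng.normal(2.0, 0.5, size=(n, 152))
    # near-exact linear age relation; the tiny noise keeps the residual sd
    # above the constant-feature guard
    values[:, 0] = (3.0 * roster["age"].to_numpy()
                    + rng.normal(0, 1e-5, n))
    # give MDD subjects an offset on feature 1 so residual sd is positive
    values[:, 1] = 1.0 + (roster["dx"] == "MDD").to_numpy(float)
    fm = FeatureMatrix(list(roster.subject_id), sb.canonical_schema(),
                       values, np.ones((n, 152), bool))
    return Dataset(roster, fm)


def test_exact_linear_relation_residualizes_to_zero():
    """feature = 3*age on everyone: HC-fit coefficients recover the slope
    and both HC and MDD subjects residualize to the same point."""
    ds = _exact_age_dataset()
    model = fit_normative(ds.features, ds.roster)
    # coef rows: intercept, age, sex_male, icv(/1e6)
    assert model.coef[1, 0] == pytest.approx(3.0, abs=1e-5)
    X = np.column_stack([np.ones(ds.n_subjects), ds.roster.age,
                         (ds.roster.sex == "M").astype(float),
                         ds.roster.icv / 1e6])
    resid = ds.features.values[:, 0] - X @ model.coef[:, 0]
    assert np.abs(resid).max() < 1e-4   # MDD rows included


def test_training_scaling_is_exact_and_reapplication_consistent():
    ds = make_tiny_dataset(n_per_site=100, n_sites=1, seed=61)
    model = fit_normative(ds.features, ds.roster)
    scaled = apply_normative(model, ds.features, ds.roster)
    assert np.abs(scaled.values.mean(0)).max() < 1e-10
    assert np.abs(scaled.values.std(0, ddof=0) - 1).max() < 1e-10
    again = apply_normative(model, ds.features, ds.roster)
    np.testing.assert_array_equal(scaled.values, again.values)


def test_known_covariate_effects_recovered():
    """Fitted age coefficients match the generative betas within noise."""
    ds = make_tiny_dataset(n_per_site=800, n_sites=1, seed=67)
    model = fit_normative(ds.features, ds.roster)
    # generator: beta_age = -0.20 sd per decade = -0.02*sigma per year
    sigma = np.array([{"thickness": 0.12, "surface_area": 300.0,
                       "subcortical_volume": 700.0}[c]
                      for c in ds.features.schema.classes])
    expected = -0.02 * sigma
    err = (model.coef[1] - expected) / sigma
    assert np.abs(err).mean() < 0.01


def test_out_of_sample_hc_scale_and_age_decorrelation():
    train = make_tiny_dataset(n_per_site=1200, n_sites=1, seed=71)
    test = make_tiny_dataset(n_per_site=1000, n_sites=1, seed=72)
    model = fit_normative(train.features, train.roster)
    hc = (test.roster.dx == "HC").to_numpy()
    out = apply_normative(model, test.features, test.roster).values[hc]
    assert np.abs(out.mean(0)).max() < 0.25
    assert np.abs(out.mean(0)).mean() < 0.1
    assert np.abs(out.std(0) - 1).mean() < 0.1
    age = test.roster.age.to_numpy()[hc]
    corr = np.array([np.corrcoef(out[:, j], age)[0, 1]
                     for j in range(out.shape[1])])
    # null max |corr| over 152 features at n_hc ~ 500 is about 3.5/sqrt(n)
    n_hc = hc.sum()
    assert np.abs(corr).mean() < 0.05
    assert np.abs(corr).max() < 4.0 / np.sqrt(n_hc)


def test_label_blindness_of_apply():
    ds = make_tiny_dataset(n_per_site=80, n_sites=1, seed=73)
    model = fit_normative(ds.features, ds.roster)
    shuffled = ds.roster.copy()
    shuffled["dx"] = np.random.default_rng(0).permutation(
        shuffled["dx"].to_numpy())
    a = apply_normative(model, ds.features, ds.roster)
    b = apply_normative(model, ds.features, shuffled)
    np.testing.assert_array_equal(a.values, b.values)


def test_errors_no_hc_and_constant_feature():
    ds = make_tiny_dataset(n_per_site=40, n_sites=1, seed=79)
    all_mdd = ds.roster.copy()
    all_mdd["dx"] = "MDD"
    with pytest.raises(FitError, match="healthy controls"):
        fit_normative(ds.features, all_mdd)

    fm = ds.features.copy()
    fm.values[:, 3] = 7.0
    with pytest.raises(FitError, match=fm.schema.names[3]):
        fit_normative(fm, ds.roster)


def test_benchmark_order_harmonize_then_residualize():
    """The pipeline's metrics equal a hand-built harmonize -> residualize ->
    classify sequence, confirming the fixed stage order."""
    from sitebench.bench import ModelSpec, compute_metrics, run_benchmark
    from sitebench.combat import harmonize_in_cv

    # n_train > n_features keeps the liblinear primal solver, which is
    # deterministic, so the manual replay must match exactly
    ds = make_tiny_dataset(n_per_site=80, n_sites=3, seed=83,
                           gamma_shift=0.5, delta_scale=1.2)
    asn = sb.split_by_age_sex(ds.roster, k=3, seed=0)
    spec = ModelSpec("svm_linear", {"C": [1.0]})
    res = run_benchmark(ds, asn, harmonization="combat", models=[spec],
                        seed=9)

    from sklearn.svm import LinearSVC
    manual = {}
    for f, tr_idx, te_idx, tr_h, te_h in harmonize_in_cv(ds, asn,
                                                         variant="combat"):
        tr_roster = ds.roster.iloc[tr_idx]
        te_roster = ds.roster.iloc[te_idx]
        norm = fit_normative(tr_h, tr_roster)
        Xtr = apply_normative(norm, tr_h, tr_roster).values
        Xte = apply_normative(norm, te_h, te_roster).values
        ytr = (tr_roster.dx == "MDD").to_numpy(int)
        yte = (te_roster.dx == "MDD").to_numpy(int)
        clf = LinearSVC(C=1.0, class_weight="balanced", dual="auto",
                        max_iter=20000, random_state=0)
        clf.fit(Xtr, ytr)
        m = compute_metrics(yte, clf.predict(Xte), clf.decision_function(Xte))
        manual[f] = m.balanced_accuracy
    got = res.table.set_index("fold")["balanced_accuracy"]
    for f, v in manual.items():
        assert got.loc[f] == pytest.approx(v, abs=1e-9)
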