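"""Harmonization: EB shrinkage correctness, train/test semantics, variants."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import sitebench as sb
from sitebench.combat import CombatResults, fit_combat, apply_combat, harmonize_in_cv
from sitebench.containers import Dataset, FeatureMatrix
from sitebench.errors import FitError
from sitebench.simulate import (ScenarioConfig, SiteSpec, draw_site_effects,
                                generate_features, generate_roster)

COV = ["age", "sex", "icv"]


def _dataset(sites, seed):
    cfg = ScenarioConfig(sites=sites, seed=seed)
    roster = generate_roster(sites, seed)
    return Dataset(roster, generate_features(roster, cfg)), cfg


def test_null_case_two_identical_sites():
    """Two sites drawn from the same distribution: location ~0, scale ~1."""
    ds, _ = _dataset([SiteSpec("a", 500), SiteSpec("b", 500)], seed=31)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    assert np.abs(m.gamma_star).max() < 0.2
    assert np.abs(m.gamma_star).mean() < 0.05
    assert np.abs(m.delta_star - 1).mean() < 0.05


def test_exact_additive_shift_direct_variant():
    """feature = 10 + 2*site2 (noise at 1e-6): the direct location estimate
    of the between-site difference is 2 in original units."""
    rng = np.random.default_rng(0)
    n = 100
    Y = np.tile(10.0, (2 * n, 152)) + rng.normal(0, 1e-6, (2 * n, 152))
    Y[n:] += 2.0
    schema = sb.canonical_schema()
    fm = FeatureMatrix([f"s{i}" for i in range(2 * n)], schema, Y,
                       np.ones_like(Y, bool))
    sites = np.array(["one"] * n + ["two"] * n)
    m = fit_combat(fm, sites, None, variant="direct")
    i1, i2 = m.site_names.index("one"), m.site_names.index("two")
    diff = (m.gamma_star[i2] - m.gamma_star[i1]) * m.sigma_hat
    np.testing.assert_allclose(diff, 2.0, atol=1e-3)


def test_direct_variant_matches_closed_form_standardization():
    """2 sites, no covariates, no EB: output is the per-site
    standardization ((y - m_i)/s_i) * s_pool + m_pool."""
    rng = np.random.default_rng(1)
    n1, n2 = 80, 120
    Y = np.vstack([rng.normal(1.0, 1.0, (n1, 152)),
                   rng.normal(3.0, 2.0, (n2, 152))])
    schema = sb.canonical_schema()
    fm = FeatureMatrix([f"x{i}" for i in range(n1 + n2)], schema, Y,
                       np.ones_like(Y, bool))
    sites = np.array(["a"] * n1 + ["b"] * n2)
    m = fit_combat(fm, sites, None, variant="direct")
    out = apply_combat(m, fm, sites, None).values

    m1, m2 = Y[:n1].mean(0), Y[n1:].mean(0)
    s1, s2 = Y[:n1].std(0, ddof=1), Y[n1:].std(0, ddof=1)
    m_pool = (n1 * m1 + n2 * m2) / (n1 + n2)
    within = Y - np.vstack([np.tile(m1, (n1, 1)), np.tile(m2, (n2, 1))])
    s_pool = np.sqrt((within ** 2).mean(0))
    oracle = np.vstack([(Y[:n1] - m1) / s1,
                        (Y[n1:] - m2) / s2]) * s_pool + m_pool
    np.testing.assert_allclose(out, oracle, atol=1e-10)


def test_parameter_recovery_against_generating_effects():
    """Known per-(site,feature) gamma/delta are recovered at n=500/site."""
    sites = [SiteSpec(f"s{i}", 500, gamma_shift=0.6, delta_scale=1.2)
             for i in range(4)]
    ds, cfg = _dataset(sites, seed=11)
    gamma, delta = draw_site_effects(sites, cfg.schema, cfg.seed)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    g_true = np.vstack([gamma[s] for s in m.site_names])
    d_true = np.vstack([delta[s] for s in m.site_names])
    w = np.array([m.n_per_site[s] for s in m.site_names], float)
    w /= w.sum()
    scale = m.sigma_hat / cfg.sigma      # convert to generator sd units
    g_est = m.gamma_star * scale
    g_true_c = g_true - w @ g_true       # model gammas are size-centered
    assert np.sqrt(((g_est - g_true_c) ** 2).mean()) <= 0.05
    d_est = m.delta_star * scale
    rel = (d_est - d_true) / d_true
    assert np.sqrt((rel ** 2).mean()) <= 0.05


def test_matches_reference_bioconductor_implementation():
    """Full EB ComBat agrees with sva::ComBat on a small fixture."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; reference comparison impossible")
    sites = [SiteSpec("a", 60, gamma_shift=0.5, delta_scale=1.3),
             SiteSpec("b", 80, gamma_shift=0.5, delta_scale=0.9),
             SiteSpec("c", 50, gamma_shift=0.5, delta_scale=1.1)]
    ds, _ = _dataset(sites, seed=7)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    ours = apply_combat(m, ds.features, ds.roster.site.to_numpy(),
                        ds.roster[COV]).values

    import tempfile, os
    d = tempfile.mkdtemp()
    np.savetxt(os.path.join(d, "Y.csv"), ds.features.values.T, delimiter=",")
    mod = np.column_stack([ds.roster.age,
                           (ds.roster.sex == "M").astype(float),
                           ds.roster.icv / 1e6])
    np.savetxt(os.path.join(d, "mod.csv"), mod, delimiter=",")
    with open(os.path.join(d, "batch.txt"), "w") as fh:
        fh.write("\n".join(ds.roster.site))
    script = (
        'suppressMessages(library(sva));'
        f'Y <- as.matrix(read.csv("{d}/Y.csv", header=FALSE));'
        f'mod <- as.matrix(read.csv("{d}/mod.csv", header=FALSE));'
        f'batch <- readLines("{d}/batch.txt");'
        'out <- ComBat(dat=Y, batch=batch, mod=mod, par.prior=TRUE);'
        f'write.table(out, "{d}/out.csv", sep=",", row.names=FALSE,'
        'col.names=FALSE)')
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    theirs = np.loadtxt(os.path.join(d, "out.csv"), delimiter=",").T
    scale = ds.features.values.std(0)
    assert np.abs((ours - theirs) / scale).max() < 1e-4


def test_apply_is_near_idempotent():
    """Refitting on already-harmonized training data finds ~no site effect."""
    sites = [SiteSpec(f"s{i}", 300, gamma_shift=0.8, delta_scale=1.3)
             for i in range(3)]
    ds, _ = _dataset(sites, seed=5)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    harmonized = apply_combat(m, ds.features, ds.roster.site.to_numpy(),
                              ds.roster[COV])
    m2 = fit_combat(harmonized, ds.roster.site.to_numpy(), ds.roster[COV])
    assert np.abs(m2.gamma_star).mean() < 0.05
    assert np.abs(m2.delta_star - 1).mean() < 0.05


def test_single_site_model_is_identity():
    ds, _ = _dataset([SiteSpec("only", 80)], seed=19)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    assert np.all(m.gamma_star == 0) and np.all(m.delta_star == 1)
    out = apply_combat(m, ds.features, ds.roster.site.to_numpy(),
                       ds.roster[COV])
    np.testing.assert_allclose(out.values, ds.features.values, rtol=1e-8)


def test_location_scale_removed_on_training_data():
    sites = [SiteSpec(f"s{i}", 500, gamma_shift=0.7, delta_scale=1.3)
             for i in range(3)]
    ds, _ = _dataset(sites, seed=23)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    out = apply_combat(m, ds.features, ds.roster.site.to_numpy(),
                       ds.roster[COV]).values
    # residualize covariates using the model's own fit before comparing sites
    z, _ = m.standardize(out, ds.roster[COV])
    pooled_sd = z.std(0)
    site_means = np.vstack([z[(ds.roster.site == s).to_numpy()].mean(0)
                            for s in m.site_names])
    assert np.abs(site_means / pooled_sd).max() < 0.15
    assert np.abs(site_means / pooled_sd).mean() < 0.05
    site_vars = np.vstack([z[(ds.roster.site == s).to_numpy()].var(0, ddof=1)
                           for s in m.site_names])
    assert np.abs(site_vars / z.var(0) - 1).mean() < 0.10


def test_covariate_variance_preserved():
    """The within-site age slope survives harmonization (< 5% change)."""
    sites = [SiteSpec(f"s{i}", 600, gamma_shift=0.6, delta_scale=1.2)
             for i in range(3)]
    ds, cfg = _dataset(sites, seed=29)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV])
    out = apply_combat(m, ds.features, ds.roster.site.to_numpy(),
                       ds.roster[COV]).values
    age = ds.roster.age.to_numpy()
    sel = (ds.roster.site == "s0").to_numpy()
    a = age[sel] - age[sel].mean()
    denom = (a ** 2).sum()
    slope_pre = a @ ds.features.values[sel] / denom
    slope_post = a @ out[sel] / denom
    # compare on features with a real age effect
    strong = np.abs(slope_pre) > np.abs(slope_pre).mean()
    rel = np.abs(slope_post[strong] - slope_pre[strong]) / np.abs(slope_pre[strong])
    assert np.median(rel) < 0.05


def test_unseen_site_policy_and_label_blindness():
    """Site-strategy folds: unseen test sites are adjusted with frozen
    standardization; shuffling test diagnosis labels changes nothing."""
    sites = [SiteSpec(f"s{i}", 60, gamma_shift=0.6, delta_scale=1.2)
             for i in range(6)]
    ds, _ = _dataset(sites, seed=37)
    asn = sb.split_by_site(ds.roster, k=3)
    runs = list(harmonize_in_cv(ds, asn, variant="combat"))
    assert len(runs) == 3
    f, tr_idx, te_idx, tr_h, te_h = runs[0]
    # test sites are genuinely unseen in training
    assert not (set(ds.roster.site.iloc[te_idx])
                & set(ds.roster.site.iloc[tr_idx]))
    # swapping test dx labels leaves harmonized test features bit-identical
    roster2 = ds.roster.copy()
    te_mask = roster2.index.isin(te_idx)
    roster2.loc[te_mask, "dx"] = np.random.default_rng(0).permutation(
        roster2.loc[te_mask, "dx"].to_numpy())
    ds2 = Dataset(roster2, ds.features)
    runs2 = list(harmonize_in_cv(ds2, asn, variant="combat"))
    np.testing.assert_array_equal(te_h.values, runs2[0][4].values)
    # harmonized unseen sites are centered like training sites
    assert np.abs(te_h.values.mean(0) - tr_h.values.mean(0)).mean() \
        < np.abs(ds.features.take(te_idx).values.mean(0)
                 - ds.features.take(tr_idx).values.mean(0)).mean()


def test_seen_site_reuses_training_estimates():
    """Age/sex-strategy folds: test sites were seen in training, so stored
    (gamma*, delta*) are reused — harmonizing a training subject and a test
    subject from the same site applies the same adjustment."""
    sites = [SiteSpec(f"s{i}", 80, gamma_shift=0.5) for i in range(3)]
    ds, _ = _dataset(sites, seed=41)
    asn = sb.split_by_age_sex(ds.roster, k=4, seed=1)
    f, tr_idx, te_idx, tr_h, te_h = next(
        iter(harmonize_in_cv(ds, asn, variant="combat")))
    m = fit_combat(ds.features.take(tr_idx),
                   ds.roster.site.iloc[tr_idx].to_numpy(),
                   ds.roster.iloc[tr_idx][COV])
    manual = apply_combat(m, ds.features.take(te_idx),
                          ds.roster.site.iloc[te_idx].to_numpy(),
                          ds.roster.iloc[te_idx][COV])
    np.testing.assert_allclose(te_h.values, manual.values, rtol=1e-10)


def test_covbat_reduces_between_site_covariance_distance():
    """With site-specific residual correlation, CovBat brings site
    covariances closer than ComBat alone."""
    rng = np.random.default_rng(43)
    n, p = 400, 152
    base = rng.normal(size=(p, p))
    q1, _ = np.linalg.qr(base)
    corr_a = np.eye(p)
    corr_b = q1 @ np.diag(rng.uniform(0.3, 3.0, p)) @ q1.T
    Ya = rng.multivariate_normal(np.zeros(p), corr_a, size=n)
    Yb = rng.multivariate_normal(np.zeros(p), corr_b, size=n) + 1.0
    Y = np.vstack([Ya, Yb])
    schema = sb.canonical_schema()
    fm = FeatureMatrix([f"c{i}" for i in range(2 * n)], schema, Y,
                       np.ones_like(Y, bool))
    sites = np.array(["a"] * n + ["b"] * n)

    def site_cov_distance(values):
        ca = np.cov(values[:n].T)
        cb = np.cov(values[n:].T)
        return np.linalg.norm(ca - cb)

    mc = fit_combat(fm, sites, None, variant="combat")
    combat_out = apply_combat(mc, fm, sites, None).values
    mv = fit_combat(fm, sites, None, variant="covbat")
    covbat_out = apply_combat(mv, fm, sites, None).values
    assert site_cov_distance(covbat_out) < site_cov_distance(combat_out)


def test_combat_gam_runs_and_serializes(tmp_path):
    sites = [SiteSpec("a", 120, age_mean=30, age_sd=12, gamma_shift=0.5),
             SiteSpec("b", 120, age_mean=50, age_sd=12, gamma_shift=0.5)]
    ds, _ = _dataset(sites, seed=47)
    m = fit_combat(ds.features, ds.roster.site.to_numpy(), ds.roster[COV],
                   variant="combat_gam")
    assert m.spline_knots is not None
    out = apply_combat(m, ds.features, ds.roster.site.to_numpy(),
                       ds.roster[COV])
    assert np.isfinite(out.values).all()

    path = tmp_path / "model.json"
    m.to_json(path)
    back = CombatResults.from_json(path)
    out2 = apply_combat(back, ds.features, ds.roster.site.to_numpy(),
                        ds.roster[COV])
    np.testing.assert_allclose(out.values, out2.values, rtol=1e-12)


def test_fit_errors():
    ds, _ = _dataset([SiteSpec("a", 30), SiteSpec("b", 30)], seed=53)
    roster = ds.roster.copy()
    roster.loc[roster.index[-1], "site"] = "lonely"
    with pytest.raises(FitError, match="lonely"):
        fit_combat(ds.features, roster.site.to_numpy(), roster[COV])
    cov = ds.roster[COV].copy()
    cov["age"] = 40.0   # constant age is collinear with the site dummies
    with pytest.raises(FitError, match="age"):
        fit_combat(ds.features, ds.roster.site.to_numpy(), cov)
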