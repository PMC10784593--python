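"""ComBat-family harmonization of multi-site features.

ComBat models each feature v of subject j at site i as

    y_ijv = alpha_v + x_j' beta_v + gamma_iv + delta_iv * eps_ijv

and removes the site location (gamma) and scale (delta) effects while
preserving the covariate term x_j' beta_v (here age, sex and ICV; diagnosis
is deliberately not in the design). Per-site, per-feature estimates are
shrunk toward site-level priors by parametric empirical Bayes:
gamma_iv ~ N(gamma_bar_i, tau_i^2) and delta_iv^2 ~ InverseGamma(lambda_i,
theta_i), with hyperparameters estimated by method of moments across
features and the conditional posterior means iterated to convergence.

Variants:

- ``combat``: the parametric EB adjustment above.
- ``direct``: per-site estimates used without shrinkage.
- ``combat_gam``: the linear age column is replaced by a cubic B-spline
  basis (4 interior knots at training age quantiles).
- ``covbat``: after ComBat, site differences in residual covariance are
  reduced by harmonizing principal-component scores covering a fraction
  rho of residual variance.

Fitting uses training data only; ``transform`` applies frozen estimates to
new data. Sites absent from training are handled by the unseen-site policy:
their (gamma, delta) are estimated on the new data under the frozen
standardization, shrunk with pooled training hyperpriors. Diagnosis labels
are never read anywhere in this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Dataset, FeatureMatrix
from .errors import ConfigError, FitError
from .splitting import FoldAssignment

VARIANTS = ("combat", "combat_gam", "covbat", "direct")

_SPLINE_N_KNOTS = 6   # 4 interior knots for a cubic basis


def _spline_knots(age: np.ndarray) -> np.ndarray:
    qs = np.linspace(0, 1, _SPLINE_N_KNOTS)
    return np.quantile(age, qs)


def _spline_basis(age: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design columns for the given knot sequence.

    Ages outside the knot range are clamped to the boundary. The first basis
    column is dropped: the columns sum to one, which would be collinear with
    the site indicators.
    """
    from scipy.interpolate import BSpline
    k = 3
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(knots) < 2:
        raise FitError("age has no variation; cannot build a spline basis")
    t = np.r_[[knots[0]] * k, knots, [knots[-1]] * k]
    x = np.clip(age, knots[0], knots[-1])
    basis = BSpline.design_matrix(x, t, k).toarray()
    return basis[:, 1:]


def build_covariate_design(covariates: pd.DataFrame | None, variant: str,
                           spline_knots: np.ndarray | None = None,
                           n_rows: int | None = None
                           ) -> tuple[np.ndarray, list, np.ndarray | None]:
    """Covariate design matrix (no intercept; site dummies span it).

    Expects columns age, sex (F/M) and icv, or None for a covariate-free
    model. For the GAM variant the age column is expanded into a spline
    basis using the supplied knots (or knots placed at the quantiles of the
    given ages when fitting).
    """
    if covariates is None:
        if n_rows is None:
            raise ConfigError("n_rows required for a covariate-free design")
        return np.empty((n_rows, 0)), [], None
    for col in ("age", "sex", "icv"):
        if col not in covariates.columns:
            raise ConfigError(f"covariates are missing column {col!r}")
    age = covariates["age"].to_numpy(float)
    male = (covariates["sex"] == "M").to_numpy(float)
    icv = covariates["icv"].to_numpy(float) / 1e6
    if np.isnan(age).any() or np.isnan(icv).any():
        raise ConfigError("covariates contain missing values")
    if variant == "combat_gam":
        if spline_knots is None:
            spline_knots = _spline_knots(age)
        basis = _spline_basis(age, spline_knots)
        cols = [f"age_spline_{i}" for i in range(basis.shape[1])]
        C = np.column_stack([basis, male, icv])
        names = cols + ["sex_male", "icv"]
    else:
        C = np.column_stack([age, male, icv])
        names = ["age", "sex_male", "icv"]
        spline_knots = None
    return C, names, spline_knots


def _check_rank(B: np.ndarray, C: np.ndarray, names: list) -> None:
    X = np.hstack([B, C])
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify the first covariate column that does not add rank
    base = B
    for j in range(C.shape[1]):
        cand = np.hstack([base, C[:, : j + 1]])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            raise FitError(f"covariate {names[j]!r} is collinear with the "
                           "site indicators or preceding covariates")
    raise FitError("design matrix is rank deficient")


@dataclass
class CombatResults:
    """Frozen harmonization estimates, fit on training data only."""

    variant: str
    site_names: list
    feature_names: list
    alpha_hat: np.ndarray          # (p,)
    beta_hat: np.ndarray           # (c, p)
    sigma_hat: np.ndarray          # (p,)
    gamma_star: np.ndarray         # (S, p)
    delta_star: np.ndarray         # (S, p)
    priors: pd.DataFrame           # per site: gamma_bar, tau2, lambda, theta
    covariate_names: list
    spline_knots: np.ndarray | None = None
    covbat: dict | None = None     # pc mean/components/pooled sd/site stats/rho
    n_per_site: dict = field(default_factory=dict)
    eb_iterations: int = 0
    unseen_site_policy: str = "estimate"

    # ---- application -------------------------------------------------
    def standardize(self, values: np.ndarray,
                    covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        C, _, _ = build_covariate_design(covariates, self.variant,
                                         self.spline_knots,
                                         n_rows=values.shape[0])
        fitted_cov = C @ self.beta_hat
        z = (values - self.alpha_hat - fitted_cov) / self.sigma_hat
        return z, fitted_cov

    def _site_params(self, z_site: np.ndarray, site: str) -> tuple:
        if site in self.site_names:
            i = self.site_names.index(site)
            return self.gamma_star[i], self.delta_star[i]
        if self.unseen_site_policy == "strict":
            raise FitError(f"site {site!r} was not seen during fitting")
        return self._estimate_new_site(z_site)

    def _estimate_new_site(self, z: np.ndarray) -> tuple:
        """Unseen-site policy: estimate (gamma, delta) on the new data under
        the frozen standardization, with pooled training hyperpriors."""
        n = z.shape[0]
        g_hat = z.mean(axis=0)
        d2_hat = z.var(axis=0, ddof=1) if n > 1 else np.ones(z.shape[1])
        if self.variant == "direct" or len(self.priors) == 0:
            return g_hat, np.sqrt(np.maximum(d2_hat, 1e-12))
        pri = self.priors[["gamma_bar", "tau2", "lambda", "theta"]].mean(axis=0)
        g_star, d2_star, _ = _eb_posterior(
            z, g_hat, d2_hat, float(pri["gamma_bar"]), float(pri["tau2"]),
            float(pri["lambda"]), float(pri["theta"]))
        return g_star, np.sqrt(d2_star)

    def transform(self, fm: FeatureMatrix, sites,
                  covariates: pd.DataFrame) -> FeatureMatrix:
        """Remove site location/scale effects; covariate variance is
        preserved by construction."""
        if not fm.mask.all():
            raise ConfigError("harmonization requires fully observed features "
                              "(impute first)")
        sites = np.asarray(sites)
        z, fitted_cov = self.standardize(fm.values, covariates)
        out = np.empty_like(fm.values)
        for site in pd.unique(sites):
            rows = np.nonzero(sites == site)[0]
            gamma, delta = self._site_params(z[rows], str(site))
            out[rows] = (z[rows] - gamma) / delta
        if self.covbat is not None:
            out = self._covbat_adjust(out, sites)
        out = out * self.sigma_hat + self.alpha_hat + fitted_cov
        return FeatureMatrix(list(fm.subjects), fm.schema, out,
                             np.ones_like(fm.mask))

    def _covbat_adjust(self, z_adj: np.ndarray, sites: np.ndarray) -> np.ndarray:
        cb = self.covbat
        centered = z_adj - cb["center"]
        scores = centered @ cb["components"].T          # (n, q)
        resid = centered - scores @ cb["components"]
        new_scores = np.empty_like(scores)
        for site in pd.unique(sites):
            rows = np.nonzero(sites == site)[0]
            key = str(site)
            if key in cb["site_means"]:
                m = cb["site_means"][key]
                s = cb["site_sds"][key]
            else:
                m = scores[rows].mean(axis=0)
                s = scores[rows].std(axis=0, ddof=1) if len(rows) > 1 \
                    else np.ones(scores.shape[1])
            s = np.maximum(s, 1e-12)
            new_scores[rows] = (scores[rows] - m) / s * cb["pooled_sd"]
        return new_scores @ cb["components"] + resid + cb["center"]

    # ---- reporting / serialization ------------------------------------
    def summary(self) -> str:
        lines = [
            f"ComBat harmonization ({self.variant})",
            f"  sites: {len(self.site_names)}, features: {len(self.feature_names)}",
            f"  covariates preserved: {', '.join(self.covariate_names)}",
            f"  EB iterations to convergence: {self.eb_iterations}",
            "  per-site location shift (mean |gamma*|) and scale (mean delta*):",
        ]
        for i, site in enumerate(self.site_names):
            lines.append(f"    {site:>20s}  |gamma*|={np.abs(self.gamma_star[i]).mean():.3f}"
                         f"  delta*={self.delta_star[i].mean():.3f}"
                         f"  n={self.n_per_site.get(site, '?')}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        payload = {
            "variant": self.variant,
            "site_names": self.site_names,
            "feature_names": self.feature_names,
            "alpha_hat": arr(self.alpha_hat),
            "beta_hat": arr(self.beta_hat),
            "sigma_hat": arr(self.sigma_hat),
            "gamma_star": arr(self.gamma_star),
            "delta_star": arr(self.delta_star),
            "priors": self.priors.to_dict(orient="list"),
            "covariate_names": self.covariate_names,
            "spline_knots": arr(self.spline_knots),
            "covbat": None if self.covbat is None else {
                k: (arr(v) if isinstance(v, np.ndarray) else
                    ({kk: arr(vv) for kk, vv in v.items()}
                     if isinstance(v, dict) else v))
                for k, v in self.covbat.items()},
            "n_per_site": self.n_per_site,
            "eb_iterations": self.eb_iterations,
            "unseen_site_policy": self.unseen_site_policy,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "CombatResults":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        covbat = payload["covbat"]
        if covbat is not None:
            covbat = {
                "center": np.asarray(covbat["center"]),
                "components": np.asarray(covbat["components"]),
                "pooled_sd": np.asarray(covbat["pooled_sd"]),
                "site_means": {k: np.asarray(v) for k, v in covbat["site_means"].items()},
                "site_sds": {k: np.asarray(v) for k, v in covbat["site_sds"].items()},
                "rho": covbat["rho"],
            }
        return cls(
            variant=payload["variant"], site_names=payload["site_names"],
            feature_names=payload["feature_names"],
            alpha_hat=np.asarray(payload["alpha_hat"]),
            beta_hat=np.asarray(payload["beta_hat"]),
            sigma_hat=np.asarray(payload["sigma_hat"]),
            gamma_star=np.asarray(payload["gamma_star"]),
            delta_star=np.asarray(payload["delta_star"]),
            priors=pd.DataFrame(payload["priors"]),
            covariate_names=payload["covariate_names"],
            spline_knots=(None if payload["spline_knots"] is None
                          else np.asarray(payload["spline_knots"])),
            covbat=covbat, n_per_site=payload["n_per_site"],
            eb_iterations=payload["eb_iterations"],
            unseen_site_policy=payload["unseen_site_policy"])


def _eb_posterior(z: np.ndarray, g_hat: np.ndarray, d2_hat: np.ndarray,
                  gamma_bar: float, tau2: float, lam: float, theta: float,
                  tol: float = 1e-6, max_iter: int = 1000) -> tuple:
    """Iterate the conditional posterior means for one site.

    z: (n_i, p) standardized site data; returns (gamma_star, delta2_star,
    iterations).
    """
    n = z.shape[0]
    g_star = g_hat.copy()
    d2_star = d2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * tau2 * g_hat + d2_star * gamma_bar) / (n * tau2 + d2_star)
        ss = ((z - g_new) ** 2).sum(axis=0)
        d2_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
            np.max(np.abs(d2_new - d2_star) / (np.abs(d2_star) + 1e-12)))
        g_star, d2_star = g_new, d2_new
        if change < tol:
            return g_star, d2_star, it
    raise FitError(f"EB posterior iteration did not converge in {max_iter} steps")


@dataclass
class CombatModel:
    """Harmonization model in the fit/Results idiom.

    Parameters
    ----------
    fm : FeatureMatrix
        Fully observed training features.
    sites : sequence of site labels, one per subject.
    covariates : DataFrame with columns age, sex, icv.
    variant : one of combat, combat_gam, covbat, direct.
    rho : residual-variance fraction covered by harmonized PCs (covbat).
    tol, max_iter : EB fixed-point iteration controls.
    """

    fm: FeatureMatrix
    sites: np.ndarray
    covariates: pd.DataFrame
    variant: str = "combat"
    rho: float = 0.95
    tol: float = 1e-6
    max_iter: int = 1000
    unseen_site_policy: str = "estimate"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        self.sites = np.asarray([str(s) for s in self.sites])
        if len(self.sites) != self.fm.n_subjects:
            raise ConfigError("sites length does not match feature matrix")
        if (self.covariates is not None
                and len(self.covariates) != self.fm.n_subjects):
            raise ConfigError("covariates length does not match feature matrix")
        if not self.fm.mask.all():
            raise ConfigError("harmonization requires fully observed features "
                              "(impute first)")

    def fit(self) -> CombatResults:
        Y = self.fm.values
        n, p = Y.shape
        site_names = sorted(pd.unique(self.sites))
        counts = {s: int((self.sites == s).sum()) for s in site_names}
        for s, c in counts.items():
            if c < 2:
                raise FitError(f"site {s!r} has a single subject; cannot "
                               "estimate its scale")
        C, cov_names, knots = build_covariate_design(
            self.covariates, self.variant, n_rows=n)

        S = len(site_names)
        site_idx = {s: i for i, s in enumerate(site_names)}
        rows = np.array([site_idx[s] for s in self.sites])
        B = np.zeros((n, S))
        B[np.arange(n), rows] = 1.0
        if S > 1:
            _check_rank(B, C, cov_names)
        X = np.hstack([B, C])
        beta_full, *_ = np.linalg.lstsq(X, Y, rcond=None)
        gamma_ls = beta_full[:S]                    # per-site intercepts
        beta_cov = beta_full[S:]
        w = np.array([counts[s] for s in site_names], dtype=float) / n
        alpha = w @ gamma_ls                        # size-weighted grand mean
        resid = Y - X @ beta_full
        sigma2 = (resid ** 2).mean(axis=0)
        if (sigma2 <= 0).any():
            bad = [self.fm.schema.names[j] for j in np.nonzero(sigma2 <= 0)[0]]
            raise FitError(f"zero residual variance for features {bad}")
        sigma = np.sqrt(sigma2)

        Z = (Y - alpha - C @ beta_cov) / sigma
        gamma_hat = np.vstack([Z[rows == i].mean(axis=0) for i in range(S)])
        delta2_hat = np.vstack([
            Z[rows == i].var(axis=0, ddof=1) for i in range(S)])

        priors_rows = []
        gamma_star = np.zeros((S, p))
        delta_star = np.ones((S, p))
        iters = 0
        if S == 1:
            # single site: nothing to remove; transform is the identity
            priors = pd.DataFrame(
                columns=["site", "gamma_bar", "tau2", "lambda", "theta"])
        else:
            for i, s in enumerate(site_names):
                g, d2 = gamma_hat[i], delta2_hat[i]
                gamma_bar = float(g.mean())
                tau2 = float(g.var(ddof=1))
                m = float(d2.mean())
                s2 = float(d2.var(ddof=1))
                lam = (m * m + 2.0 * s2) / s2
                theta = (m * s2 + m ** 3) / s2
                priors_rows.append({"site": s, "gamma_bar": gamma_bar,
                                    "tau2": tau2, "lambda": lam,
                                    "theta": theta})
                if self.variant == "direct":
                    gamma_star[i] = g
                    delta_star[i] = np.sqrt(np.maximum(d2, 1e-12))
                else:
                    zi = Z[rows == i]
                    g_st, d2_st, it = _eb_posterior(
                        zi, g, d2, gamma_bar, tau2, lam, theta,
                        tol=self.tol, max_iter=self.max_iter)
                    gamma_star[i] = g_st
                    delta_star[i] = np.sqrt(d2_st)
                    iters = max(iters, it)
            priors = pd.DataFrame(priors_rows).set_index("site")

        covbat_extras = None
        if self.variant == "covbat" and S > 1:
            z_adj = np.empty_like(Z)
            for i in range(S):
                z_adj[rows == i] = (Z[rows == i] - gamma_star[i]) / delta_star[i]
            covbat_extras = self._fit_covbat(z_adj, rows, site_names)

        return CombatResults(
            variant=self.variant, site_names=site_names,
            feature_names=list(self.fm.schema.names),
            alpha_hat=alpha, beta_hat=beta_cov, sigma_hat=sigma,
            gamma_star=gamma_star, delta_star=delta_star,
            priors=priors.reset_index() if S > 1 else priors,
            covariate_names=cov_names, spline_knots=knots,
            covbat=covbat_extras, n_per_site=counts, eb_iterations=iters,
            unseen_site_policy=self.unseen_site_policy)

    def _fit_covbat(self, z_adj: np.ndarray, rows: np.ndarray,
                    site_names: list) -> dict:
        center = z_adj.mean(axis=0)
        E = z_adj - center
        U, sv, Vt = np.linalg.svd(E, full_matrices=False)
        var = sv ** 2
        frac = np.cumsum(var) / var.sum()
        q = int(np.searchsorted(frac, self.rho) + 1)
        components = Vt[:q]
        scores = E @ components.T
        pooled_sd = scores.std(axis=0, ddof=1)
        site_means, site_sds = {}, {}
        for i, s in enumerate(site_names):
            sc = scores[rows == i]
            site_means[s] = sc.mean(axis=0)
            site_sds[s] = np.maximum(sc.std(axis=0, ddof=1), 1e-12)
        return {"center": center, "components": components,
                "pooled_sd": pooled_sd, "site_means": site_means,
                "site_sds": site_sds, "rho": self.rho}


# ---------------------------------------------------------------------------
# functional surface

def fit_combat(fm: FeatureMatrix, sites, covariates: pd.DataFrame,
               variant: str = "combat", **options) -> CombatResults:
    """Fit harmonization estimates on training data."""
    return CombatModel(fm, np.asarray(sites), covariates, variant=variant,
                       **options).fit()


def apply_combat(model: CombatResults, fm: FeatureMatrix, sites,
                 covariates: pd.DataFrame) -> FeatureMatrix:
    """Apply frozen harmonization estimates to (new) data."""
    return model.transform(fm, sites, covariates)


def harmonize_in_cv(dataset: Dataset, assignment: FoldAssignment,
                    variant: str = "combat", **options):
    """Per CV iteration: fit on the training folds only, apply to both.

    Yields (fold, train_indices, test_indices, train_fm, test_fm). No test
    statistic enters the fit; sites unseen in training (site-strategy folds)
    engage the unseen-site policy automatically.
    """
    roster = dataset.roster
    fold = roster["subject_id"].map(assignment.fold_of)
    assigned = fold.notna().to_numpy()
    fold = fold.to_numpy()
    cov_cols = ["age", "sex", "icv"]
    for f in range(1, assignment.k + 1):
        test_idx = np.nonzero(assigned & (fold == f))[0]
        train_idx = np.nonzero(assigned & (fold != f))[0]
        if len(test_idx) == 0:
            continue
        tr_roster = roster.iloc[train_idx]
        te_roster = roster.iloc[test_idx]
        tr_fm = dataset.features.take(train_idx)
        te_fm = dataset.features.take(test_idx)
        try:
            model = fit_combat(tr_fm, tr_roster["site"].to_numpy(),
                               tr_roster[cov_cols], variant=variant, **options)
            tr_h = model.transform(tr_fm, tr_roster["site"].to_numpy(),
                                   tr_roster[cov_cols])
            te_h = model.transform(te_fm, te_roster["site"].to_numpy(),
                                   te_roster[cov_cols])
        except (FitError, ConfigError) as err:
            raise FitError(f"harmonization failed in CV fold {f}: {err}") from err
        yield f, train_idx, test_idx, tr_h, te_h
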