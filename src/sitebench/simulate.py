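"""Synthetic multi-site morphometry generator.

Stands in for consortium data that cannot be shared: per-feature covariate
effects (age, sex, ICV), small diagnosis effects in Cohen's d units,
additive per-site location shifts, multiplicative per-site scale factors,
and missingness. The generative model per subject j and feature v is

    y_jv = alpha_v + sigma_v * ( b_age_v * (age_j - 40)/10
                               + b_sex_v * male_j
                               + b_icv_v * (icv_j - 1.5e6)/1.5e5
                               + theta_v * mdd_j
                               + gamma_{s(j),v}
                               + delta_{s(j),v} * eps_jv ),   eps ~ N(0,1)

with gamma drawn once per (site, feature) from N(0, gamma_shift^2) in
residual-sd units and delta drawn log-normal around delta_scale, truncated
to [0.5, 2]. Sites sharing a scanner_group share most of their gamma
signature, emulating cohorts scanned on the same scanner model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Dataset, FeatureMatrix, validate_roster
from .errors import ConfigError
from .rng import substream
from .schema import (SUBCORTICAL_VOLUME, SURFACE_AREA, THICKNESS,
                     FeatureSchema, canonical_schema)

#: fraction of gamma variance shared between sites on the same scanner
SCANNER_SHARE = 0.8

ICV_MEAN_F = 1.45e6
ICV_MEAN_M = 1.55e6
ICV_SD = 1.5e5


@dataclass
class SiteSpec:
    """One simulated cohort."""

    name: str
    n: int
    age_mean: float = 40.0
    age_sd: float = 15.0
    pct_female: float = 0.5
    pct_mdd: float = 0.5
    gamma_shift: float = 0.0   # additive site effect scale, residual-sd units
    delta_scale: float = 1.0   # multiplicative site dispersion factor
    scanner_group: str | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError(f"site {self.name}: n must be >= 1")
        if not (0 <= self.pct_female <= 1 and 0 <= self.pct_mdd <= 1):
            raise ConfigError(f"site {self.name}: pct_female/pct_mdd in [0,1]")
        if self.delta_scale <= 0:
            raise ConfigError(f"site {self.name}: delta_scale must be > 0")


def _default_alpha(schema: FeatureSchema) -> np.ndarray:
    """Feature intercepts on morphometry-like scales."""
    alpha = np.empty(len(schema))
    for i, cls in enumerate(schema.classes):
        alpha[i] = {THICKNESS: 2.5, SURFACE_AREA: 2500.0,
                    SUBCORTICAL_VOLUME: 5000.0}[cls]
    return alpha


def _default_sigma(schema: FeatureSchema) -> np.ndarray:
    sigma = np.empty(len(schema))
    for i, cls in enumerate(schema.classes):
        sigma[i] = {THICKNESS: 0.12, SURFACE_AREA: 300.0,
                    SUBCORTICAL_VOLUME: 700.0}[cls]
    return sigma


def _default_betas(schema: FeatureSchema) -> dict[str, np.ndarray]:
    """Covariate effects in residual-sd units per standardized covariate.

    Age enters per decade, sex as a male indicator, ICV per 1.5e5 mm^3.
    Thickness shows weak sex/ICV dependence; areas and volumes scale with
    head size.
    """
    p = len(schema)
    is_thick = np.array([c == THICKNESS for c in schema.classes])
    beta_age = np.full(p, -0.20)          # gentle decline per decade
    beta_sex = np.where(is_thick, 0.05, 0.60)
    beta_icv = np.where(is_thick, 0.05, 0.40)
    return {"beta_age": beta_age, "beta_sex": beta_sex, "beta_icv": beta_icv}


@dataclass
class ScenarioConfig:
    """Full generative specification for one synthetic study."""

    sites: list[SiteSpec]
    beta_age: np.ndarray | None = None
    beta_sex: np.ndarray | None = None
    beta_icv: np.ndarray | None = None
    theta: np.ndarray | None = None       # diagnosis effect, Cohen's d per feature
    sigma: np.ndarray | None = None
    alpha: np.ndarray | None = None
    missing_rate: float = 0.0
    seed: int = 0
    schema: FeatureSchema = field(default_factory=canonical_schema)

    def __post_init__(self):
        p = len(self.schema)
        defaults = _default_betas(self.schema)
        if self.beta_age is None:
            self.beta_age = defaults["beta_age"]
        if self.beta_sex is None:
            self.beta_sex = defaults["beta_sex"]
        if self.beta_icv is None:
            self.beta_icv = defaults["beta_icv"]
        if self.theta is None:
            self.theta = np.zeros(p)
        if self.sigma is None:
            self.sigma = _default_sigma(self.schema)
        if self.alpha is None:
            self.alpha = _default_alpha(self.schema)
        for name in ("beta_age", "beta_sex", "beta_icv", "theta", "sigma", "alpha"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ConfigError(f"{name} must have length {p}, got {arr.shape}")
            setattr(self, name, arr)
        if not (self.sigma > 0).all():
            raise ConfigError("sigma must be positive elementwise")
        if not 0 <= self.missing_rate <= 1:
            raise ConfigError("missing_rate must be in [0,1]")


def scenario_config_from_dict(payload: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a plain dict (YAML/JSON), field for field.

    Site entries are dicts with the SiteSpec fields; effect vectors may be
    lists of length 152 or omitted for the defaults.
    """
    payload = dict(payload)
    sites_raw = payload.pop("sites", None)
    if not sites_raw:
        raise ConfigError("scenario config needs a non-empty 'sites' list")
    sites = [SiteSpec(**s) for s in sites_raw]
    known = {"beta_age", "beta_sex", "beta_icv", "theta", "sigma", "alpha",
             "missing_rate", "seed"}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown scenario config keys: {sorted(unknown)}")
    vectors = {k: np.asarray(v, dtype=float) if v is not None else None
               for k, v in payload.items()
               if k not in ("missing_rate", "seed")}
    return ScenarioConfig(sites=sites,
                          missing_rate=payload.get("missing_rate", 0.0),
                          seed=payload.get("seed", 0), **vectors)


def load_scenario_config(path) -> ScenarioConfig:
    """Read a ScenarioConfig from a YAML (or JSON) file."""
    import yaml
    with open(path) as fh:
        return scenario_config_from_dict(yaml.safe_load(fh))


def generate_roster(sites: list[SiteSpec], seed: int,
                    clinical_strata: bool = True) -> pd.DataFrame:
    """Draw a subject roster from the site specifications.

    Ages are normal, truncated to [10, 90]; sex and diagnosis are Bernoulli
    with the per-site proportions; ICV is normal with a fixed male-female
    offset. MDD subjects additionally receive clinical strata (age of onset
    group, antidepressant use, first vs recurrent episode), each missing
    with probability 0.15, emulating incompletely reported covariates.
    """
    if not sites:
        raise ConfigError("site list is empty")
    rng = substream(seed, "roster")
    records = []
    for site in sites:
        n = site.n
        ages = rng.normal(site.age_mean, site.age_sd, size=n)
        ages = np.clip(ages, 10.0, 90.0)
        female = rng.random(n) < site.pct_female
        mdd = rng.random(n) < site.pct_mdd
        icv = rng.normal(np.where(female, ICV_MEAN_F, ICV_MEAN_M), ICV_SD)
        icv = np.maximum(icv, 8e5)
        for i in range(n):
            rec = {
                "subject_id": f"{site.name}_{i:05d}",
                "site": site.name,
                "scanner_group": site.scanner_group or site.name,
                "age": float(ages[i]),
                "sex": "F" if female[i] else "M",
                "dx": "MDD" if mdd[i] else "HC",
                "icv": float(icv[i]),
                "onset_group": pd.NA,
                "antidepressant": pd.NA,
                "episodes": pd.NA,
            }
            if clinical_strata and mdd[i]:
                if rng.random() >= 0.15:
                    rec["onset_group"] = ("adolescent" if rng.random() < 0.4
                                          else "adult")
                if rng.random() >= 0.15:
                    rec["antidepressant"] = "yes" if rng.random() < 0.5 else "no"
                if rng.random() >= 0.15:
                    rec["episodes"] = ("recurrent" if rng.random() < 0.6
                                       else "first")
            records.append(rec)
    return validate_roster(pd.DataFrame.from_records(records))


def draw_site_effects(sites: list[SiteSpec], schema: FeatureSchema,
                      seed: int) -> tuple[dict, dict]:
    """Per-(site, feature) location shifts and scale factors.

    Returns (gamma, delta): dicts mapping site name to length-p arrays.
    gamma is in residual-sd units; delta is the multiplicative dispersion,
    log-normal around the site's delta_scale, truncated to [0.5, 2].
    """
    rng = substream(seed, "site-effects")
    p = len(schema)
    scanner_gamma: dict[str, np.ndarray] = {}
    gamma: dict[str, np.ndarray] = {}
    delta: dict[str, np.ndarray] = {}
    for site in sites:
        g_own = rng.normal(0.0, 1.0, size=p)
        if site.scanner_group is not None:
            if site.scanner_group not in scanner_gamma:
                scanner_gamma[site.scanner_group] = rng.normal(0.0, 1.0, size=p)
            g_shared = scanner_gamma[site.scanner_group]
            g = (np.sqrt(SCANNER_SHARE) * g_shared
                 + np.sqrt(1.0 - SCANNER_SHARE) * g_own)
        else:
            g = g_own
        gamma[site.name] = site.gamma_shift * g
        if site.delta_scale == 1.0 and site.gamma_shift == 0.0:
            # pristine site: no dispersion heterogeneity either
            delta[site.name] = np.ones(p)
        else:
            d = np.exp(rng.normal(np.log(site.delta_scale), 0.15, size=p))
            delta[site.name] = np.clip(d, 0.5, 2.0)
    return gamma, delta


def generate_features(roster: pd.DataFrame, cfg: ScenarioConfig) -> FeatureMatrix:
    """Generate the subjects x features matrix under the location/scale model."""
    site_names = {s.name for s in cfg.sites}
    unknown = set(roster["site"]) - site_names
    if unknown:
        raise ConfigError(f"roster contains sites not in config: {sorted(unknown)}")
    gamma, delta = draw_site_effects(cfg.sites, cfg.schema, cfg.seed)
    rng = substream(cfg.seed, "features")
    n, p = len(roster), len(cfg.schema)
    age_c = (roster["age"].to_numpy(float) - 40.0) / 10.0
    male = (roster["sex"] == "M").to_numpy(float)
    icv_c = (roster["icv"].to_numpy(float) - 1.5e6) / 1.5e5
    mdd = (roster["dx"] == "MDD").to_numpy(float)

    z = (np.outer(age_c, cfg.beta_age) + np.outer(male, cfg.beta_sex)
         + np.outer(icv_c, cfg.beta_icv) + np.outer(mdd, cfg.theta))
    eps = rng.normal(0.0, 1.0, size=(n, p))
    g = np.vstack([gamma[s] for s in roster["site"]])
    d = np.vstack([delta[s] for s in roster["site"]])
    values = cfg.alpha + cfg.sigma * (z + g + d * eps)
    fm = FeatureMatrix(list(roster["subject_id"]), cfg.schema, values,
                       np.ones((n, p), dtype=bool))
    if cfg.missing_rate > 0:
        fm = inject_missingness(fm, cfg.missing_rate, 0.0, cfg.seed)
    return fm


def inject_missingness(fm: FeatureMatrix, missing_rate: float,
                       block_rate: float, seed: int) -> FeatureMatrix:
    """Mask entries at random and give a fraction of subjects block dropout.

    Block-dropout subjects lose a random 30-60% of their features, pushing
    them below a 75% completeness threshold; entry-level missingness is
    applied independently at missing_rate.
    """
    if not (0 <= missing_rate <= 1) or not (0 <= block_rate <= 1):
        raise ConfigError("missing_rate and block_rate must be in [0,1]")
    rng = substream(seed, "missingness")
    out = fm.copy()
    n, p = out.values.shape
    if missing_rate > 0:
        out.mask &= rng.random((n, p)) >= missing_rate
    if block_rate > 0:
        block = rng.random(n) < block_rate
        for i in np.nonzero(block)[0]:
            frac = rng.uniform(0.30, 0.60)
            cols = rng.choice(p, size=int(round(frac * p)), replace=False)
            out.mask[i, cols] = False
    out.values[~out.mask] = np.nan
    return out


def generate_dataset(cfg: ScenarioConfig,
                     clinical_strata: bool = True) -> Dataset:
    """Roster + features in one call."""
    roster = generate_roster(cfg.sites, cfg.seed, clinical_strata)
    return Dataset(roster, generate_features(roster, cfg))
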