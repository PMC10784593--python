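"""Packaged cohort table and named simulation scenarios.

The cohort table encodes the published descriptors of the 30 ENIGMA MDD
cohorts used by the benchmark: group sizes, female counts and age
distributions for healthy controls (HC) and patients (MDD) separately.
Four cohorts are patient-only. The table is the anchor for the
``enigma_like`` site specifications and for an exact-count roster fixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import validate_roster
from .errors import ConfigError
from .rng import substream
from .simulate import (ICV_MEAN_F, ICV_MEAN_M, ICV_SD, ScenarioConfig,
                       SiteSpec)
from .schema import canonical_schema

# cohort, n_hc, n_mdd, f_hc, f_mdd, hc_age_mean, hc_age_sd, mdd_age_mean, mdd_age_sd
COHORT_TABLE_ROWS = [
    ("AFFDIS",         46,  33,  22,  14, 39.87, 14.29, 39.58, 15.18),
    ("Pharmo",          0,  51,   0,  51,  None,  None, 29.37,  4.64),
    ("Barcelona-StPau", 32,  62,  23,  49, 46.03,  8.00, 46.98,  7.68),
    ("CARDIFF",         0,  40,   0,  27,  None,  None, 46.55, 11.74),
    ("CSAN",           49,  60,  34,  40, 33.20, 12.07, 35.92, 13.38),
    ("Calgary",        52,  55,  29,  31, 15.81,  5.03, 18.19,  2.51),
    ("DCHS",           61,  18,  61,  18, 31.49,  6.82, 28.94,  5.89),
    ("ETPB",           26,  34,  16,  20, 33.88, 10.22, 35.91,  9.48),
    ("Episca",         30,  19,  26,  16, 14.73,  1.53, 15.42,  1.46),
    ("FIDMAG",         34,  35,  22,  22, 45.94, 11.49, 48.46, 12.90),
    ("Groningen",      21,  20,  16,  14, 44.05, 13.96, 44.50, 13.34),
    ("Houston",       186, 104, 105,  64, 26.76, 15.91, 32.23, 16.39),
    ("Jena",           77,  30,  36,  16, 47.75, 15.93, 44.20, 11.92),
    ("LOND",           61,  69,  32,  47, 51.72,  7.87, 47.86,  8.85),
    ("MODECT",          0,  42,   0,  28,  None,  None, 72.71,  9.25),
    ("MPIP",          211, 337, 124, 191, 49.53, 13.02, 48.12, 13.90),
    ("Melbourne",     102, 143,  54,  76, 19.58,  2.97, 19.31,  2.80),
    ("Minnesota",      40,  70,  26,  53, 15.68,  1.98, 15.36,  1.83),
    ("Moraldilemma",   46,  24,  46,  24, 18.50,  1.75, 19.42,  2.14),
    ("NESDA",          65, 154,  42, 103, 40.29,  9.67, 37.19, 10.45),
    ("QTIM",          284, 102, 190,  77, 22.11,  3.30, 22.01,  3.11),
    ("UCSF",           88,  75,  42,  49, 15.32,  1.28, 15.63,  1.33),
    ("SHIP_S2",       443, 136, 198,  96, 55.44, 12.80, 53.59, 11.68),
    ("SHIP_T0",       919, 310, 405, 202, 50.50, 14.18, 49.12, 12.04),
    ("SanRaffaele",     0,  45,   0,  32,  None,  None, 49.07, 13.51),
    ("Singapore",      16,  22,   8,  10, 38.69,  4.59, 40.09,  7.43),
    ("Socat_dep",     100,  79,  90,  71, 36.42, 13.57, 39.66, 12.81),
    ("StanfFAA",       18,  14,  18,  14, 30.44,  9.96, 35.63,  8.14),
    ("StanfT1wAggr",   59,  56,  36,  33, 37.24, 10.43, 37.11, 10.09),
    ("TIGER",          11,  49,   5,  33, 15.18,  1.03, 15.73,  1.38),
]

COHORT_TABLE = pd.DataFrame(COHORT_TABLE_ROWS, columns=[
    "cohort", "n_hc", "n_mdd", "f_hc", "f_mdd",
    "hc_age_mean", "hc_age_sd", "mdd_age_mean", "mdd_age_sd"])

#: default site-effect magnitudes for the confounded scenarios; chosen to
#: qualitatively reproduce the ~10-point accuracy gap between splitting
#: strategies, not as estimates of any real consortium's site effects.
DEFAULT_GAMMA_SHIFT = 0.6
DEFAULT_DELTA_SCALE = 1.2


def _cohort_age(row, group):
    m = row[f"{group}_age_mean"]
    s = row[f"{group}_age_sd"]
    if m is None or (isinstance(m, float) and np.isnan(m)):
        m, s = row["mdd_age_mean"], row["mdd_age_sd"]
    return float(m), float(s)


def cohort_roster(seed: int = 0) -> pd.DataFrame:
    """Exact-count roster emulating the published cohort table.

    Group sizes, diagnoses and female counts are exact integers from the
    table; ages and ICV are drawn from the per-group distributions.
    """
    rng = substream(seed, "cohort-roster")
    records = []
    for _, row in COHORT_TABLE.iterrows():
        for dx, n, n_f in (("HC", row["n_hc"], row["f_hc"]),
                           ("MDD", row["n_mdd"], row["f_mdd"])):
            if n == 0:
                continue
            mean, sd = _cohort_age(row, dx.lower())
            ages = np.clip(rng.normal(mean, sd, size=n), 10.0, 90.0)
            for i in range(n):
                female = i < n_f
                icv = rng.normal(ICV_MEAN_F if female else ICV_MEAN_M, ICV_SD)
                records.append({
                    "subject_id": f"{row['cohort']}_{dx}_{i:04d}",
                    "site": row["cohort"],
                    "age": float(ages[i]),
                    "sex": "F" if female else "M",
                    "dx": dx,
                    "icv": float(max(icv, 8e5)),
                })
    return validate_roster(pd.DataFrame.from_records(records))


def enigma_like_sitespecs(n_total: int | None = None,
                          gamma_shift: float = DEFAULT_GAMMA_SHIFT,
                          delta_scale: float = DEFAULT_DELTA_SCALE,
                          n_scanner_groups: int = 10) -> list[SiteSpec]:
    """30 site specifications matching the cohort table.

    With n_total given, cohort sizes are scaled proportionally (minimum 12
    subjects per site so every cohort survives 10-fold splitting). Sites are
    assigned to scanner groups round-robin, so several cohorts share a
    scanner signature.
    """
    total = int(COHORT_TABLE["n_hc"].sum() + COHORT_TABLE["n_mdd"].sum())
    scale = 1.0 if n_total is None else n_total / total
    specs = []
    for i, row in COHORT_TABLE.iterrows():
        n_cohort = int(row["n_hc"] + row["n_mdd"])
        n = max(12, int(round(scale * n_cohort))) if n_total else n_cohort
        pct_mdd = row["n_mdd"] / n_cohort
        pct_female = (row["f_hc"] + row["f_mdd"]) / n_cohort
        # population age distribution: size-weighted mixture of the groups
        w_mdd = row["n_mdd"] / n_cohort
        m_hc, s_hc = _cohort_age(row, "hc")
        m_mdd, s_mdd = _cohort_age(row, "mdd")
        mean = (1 - w_mdd) * m_hc + w_mdd * m_mdd
        var = ((1 - w_mdd) * (s_hc ** 2 + m_hc ** 2)
               + w_mdd * (s_mdd ** 2 + m_mdd ** 2) - mean ** 2)
        specs.append(SiteSpec(
            name=str(row["cohort"]), n=n, age_mean=mean,
            age_sd=float(np.sqrt(max(var, 1.0))),
            pct_female=pct_female, pct_mdd=pct_mdd,
            gamma_shift=gamma_shift, delta_scale=delta_scale,
            scanner_group=f"scanner_{i % n_scanner_groups}"))
    return specs


def _equal_sites(n_total: int, n_sites: int, gamma_shift: float,
                 delta_scale: float, pct_mdd: float = 0.5) -> list[SiteSpec]:
    per = n_total // n_sites
    return [SiteSpec(name=f"site_{i:02d}", n=per, age_mean=40, age_sd=15,
                     pct_female=0.5, pct_mdd=pct_mdd,
                     gamma_shift=gamma_shift, delta_scale=delta_scale)
            for i in range(n_sites)]


def _signal_theta(d: float = 0.5, n_signal: int = 20) -> np.ndarray:
    """Diagnosis effect vector: d on a deterministic spread of features."""
    schema = canonical_schema()
    theta = np.zeros(len(schema))
    idx = np.linspace(0, len(schema) - 1, n_signal).round().astype(int)
    theta[idx] = d
    return theta


def scenario(name: str, n_total: int = 3000, seed: int = 0) -> ScenarioConfig:
    """Named scenario presets.

    - ``null``: 10 balanced sites, no diagnosis effect, no site effects.
    - ``site_confounded``: cohort-table site structure (heterogeneous MDD/HC
      ratios) with location/scale site effects but zero diagnosis effect —
      any classification signal is pure site confounding.
    - ``signal_only``: balanced sites, d = 0.5 on 20 features, no site
      effects.
    - ``full``: cohort-table structure, site effects, and a small diagnosis
      effect (d = 0.2 on 30 features).
    """
    if name == "null":
        return ScenarioConfig(sites=_equal_sites(n_total, 10, 0.0, 1.0),
                              seed=seed)
    if name == "site_confounded":
        return ScenarioConfig(sites=enigma_like_sitespecs(n_total), seed=seed)
    if name == "signal_only":
        return ScenarioConfig(sites=_equal_sites(n_total, 10, 0.0, 1.0),
                              theta=_signal_theta(0.5, 20), seed=seed)
    if name == "full":
        return ScenarioConfig(sites=enigma_like_sitespecs(n_total),
                              theta=_signal_theta(0.2, 30), seed=seed)
    raise ConfigError(f"unknown scenario {name!r}; expected one of "
                      "null, site_confounded, signal_only, full")
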