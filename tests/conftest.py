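import numpy as np
import pandas as pd
import pytest

import sitebench as sb
from sitebench.containers import Dataset
from sitebench.simulate import ScenarioConfig, SiteSpec, generate_features, generate_roster


@pytest.fixture(scope="session")
def schema():
    return sb.canonical_schema()


@pytest.fixture(scope="session")
def table1_roster():
    """Exact-count roster matching the published 30-cohort table."""
    return sb.cohort_roster(seed=0)


@pytest.fixture(scope="session")
def null_ds():
    """Small balanced multi-site dataset with no diagnosis or site effects."""
    return sb.generate_dataset(sb.scenario("null", n_total=400, seed=10))


@pytest.fixture(scope="session")
def confounded_small():
    """6 sites with location/scale effects, heterogeneous MDD/HC ratios,
    zero diagnosis effect: classification signal is pure site confound."""
    ratios = [0.2, 0.8, 0.5, 0.35, 0.65, 0.5]
    sites = [SiteSpec(f"s{i}", 120, pct_mdd=r, gamma_shift=0.6,
                      delta_scale=1.2) for i, r in enumerate(ratios)]
    cfg = ScenarioConfig(sites=sites, seed=11)
    return sb.generate_dataset(cfg)


def make_tiny_dataset(n_per_site=30, n_sites=2, seed=0, **site_kwargs):
    sites = [SiteSpec(f"t{i}", n_per_site, **site_kwargs)
             for i in range(n_sites)]
    cfg = ScenarioConfig(sites=sites, seed=seed)
    roster = generate_roster(sites, seed)
    return Dataset(roster, generate_features(roster, cfg))


@pytest.fixture()
def tiny_ds():
    return make_tiny_dataset(n_per_site=30, n_sites=2, seed=3)
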