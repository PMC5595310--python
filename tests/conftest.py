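import numpy as np
import pandas as pd
import pytest

from ctikit import CommunityTimeSeries, TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def three_species_traits():
    return TraitTable(
        pd.DataFrame({"species": ["a", "b", "c"], "temp_pref": [10.0, 20.0, 30.0]})
    )


@pytest.fixture
def small_community():
    rows = [
        ("a", 2001, 2.0), ("a", 2002, 4.0), ("a", 2003, 8.0),
        ("b", 2001, 3.0), ("b", 2002, 3.0), ("b", 2003, 3.0),
        ("c", 2001, 5.0), ("c", 2002, 5.0), ("c", 2003, 10.0),
    ]
    return CommunityTimeSeries(pd.DataFrame(rows, columns=["species", "year", "abundance"]))


def make_noiseless_panel(n_species=10, n_years=6, b=0.04, seed=3, b_habitat=0.0):
    """Community following log N = log(100) + t*(b*temp + b_habitat*habitat) exactly."""
    rng = np.random.default_rng(seed)
    temp = rng.standard_normal(n_species)
    hab = rng.standard_normal(n_species)
    rows = []
    for s in range(n_species):
        for t in range(n_years):
            logn = np.log(100.0) + t * (b * temp[s] + b_habitat * hab[s])
            rows.append((f"s{s:02d}", t + 1, float(np.exp(logn))))
    comm = CommunityTimeSeries(pd.DataFrame(rows, columns=["species", "year", "abundance"]))
    traits = TraitTable(
        pd.DataFrame(
            {
                "species": [f"s{s:02d}" for s in range(n_species)],
                "temp_pref": temp,
                "habitat_breadth": hab,
            }
        )
    )
    return comm, traits


def make_ar1_panel(n_species=60, n_years=25, rho=0.5, sigma=0.3, slope=0.03, seed=0):
    """Panel with a year x trait interaction and AR(1) residuals of known rho."""
    rng = np.random.default_rng(seed)
    temp = rng.standard_normal(n_species)
    rows = []
    for s in range(n_species):
        e = np.empty(n_years)
        e[0] = rng.normal(0.0, sigma / np.sqrt(1 - rho**2))
        for t in range(1, n_years):
            e[t] = rho * e[t - 1] + rng.normal(0.0, sigma)
        logn = np.log(100.0) + slope * temp[s] * np.arange(n_years) + e
        for t in range(n_years):
            rows.append((f"s{s:02d}", t + 1, float(np.exp(logn[t]))))
    comm = CommunityTimeSeries(pd.DataFrame(rows, columns=["species", "year", "abundance"]))
    traits = TraitTable(
        pd.DataFrame({"species": [f"s{s:02d}" for s in range(n_species)], "temp_pref": temp})
    )
    return comm, traits
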