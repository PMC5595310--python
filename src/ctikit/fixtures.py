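"""Seeded synthetic survey fixtures shaped like national monitoring datasets.

Two profiles emulate the structure (not the values) of the kinds of long-term
community surveys the CTI is applied to:

``birds_like``
    ~36 terrestrial breeding-bird species over 33 annual censuses, a
    categorical habitat attribute (farmland / forest / urban) whose classes
    differ in mean temperature preference (urban > farmland > forest), and a
    farmland decline confounding the temperature signal.

``fish_like``
    ~33 demersal fish species over 34 annual censuses, a 4-level commercial
    exploitation class negatively associated with temperature preference,
    plus continuous log maximum body length; exploited species decline.

Dynamics come from the same log-linear growth skeleton as the simulator, with
Poisson observation error, and abundances are standardized to 100 in year 1.
These are synthetic stand-ins: no real survey data are included or emulated
numerically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CommunityTimeSeries, TraitTable, standardize_to_index
from .errors import ValidationError

__all__ = ["PROFILES", "generate_fixture"]

PROFILES = ("birds_like", "fish_like")


def _simulate_counts(growth, n_years, rng, n0=100.0):
    logmu = np.log(n0) + np.outer(growth, np.arange(n_years))
    return rng.poisson(np.exp(logmu)).astype(float)


def _birds_like(rng):
    groups = [("urban", 7, 11.6), ("farmland", 13, 10.9), ("forest", 16, 9.9)]
    species, habitat, temp = [], [], []
    i = 0
    for name, n, mu in groups:
        for _ in range(n):
            i += 1
            species.append(f"bird{i:02d}")
            habitat.append(name)
            temp.append(mu + 0.8 * rng.standard_normal())
    traits = TraitTable(
        pd.DataFrame({"species": species, "temp_pref": temp, "habitat": habitat})
    )
    habitat_effect = {"urban": 0.0, "farmland": -0.012, "forest": 0.004}
    temp_arr = np.asarray(temp)
    growth = 0.010 * (temp_arr - temp_arr.mean()) + np.array(
        [habitat_effect[h] for h in habitat]
    )
    years = np.arange(1981, 2014)
    counts = _simulate_counts(growth, len(years), rng)
    comm = CommunityTimeSeries(
        pd.DataFrame(
            {
                "species": np.repeat(species, len(years)),
                "year": np.tile(years, len(species)),
                "abundance": counts.ravel(),
            }
        ),
        census_years=years,
    )
    return standardize_to_index(comm, zero_policy="floor"), traits


def _fish_like(rng):
    groups = [("none", 9, 10.6), ("minor", 7, 10.2), ("moderate", 9, 9.9), ("high", 8, 9.5)]
    exploit_effect = {"none": 0.0, "minor": -0.010, "moderate": -0.020, "high": -0.031}
    species, exploitation, temp, loglen = [], [], [], []
    i = 0
    for gi, (name, n, mu) in enumerate(groups):
        for _ in range(n):
            i += 1
            species.append(f"fish{i:02d}")
            exploitation.append(name)
            temp.append(mu + 0.7 * rng.standard_normal())
            loglen.append(2.5 + 0.4 * gi + 0.3 * rng.standard_normal())
    traits = TraitTable(
        pd.DataFrame(
            {
                "species": species,
                "temp_pref": temp,
                "exploitation": exploitation,
                "log_max_length": loglen,
            }
        )
    )
    temp_arr, len_arr = np.asarray(temp), np.asarray(loglen)
    growth = (
        0.0101 * (temp_arr - temp_arr.mean())
        + np.array([exploit_effect[e] for e in exploitation])
        - 0.004 * (len_arr - len_arr.mean())
    )
    years = np.arange(1980, 2014)
    counts = _simulate_counts(growth, len(years), rng)
    comm = CommunityTimeSeries(
        pd.DataFrame(
            {
                "species": np.repeat(species, len(years)),
                "year": np.tile(years, len(species)),
                "abundance": counts.ravel(),
            }
        ),
        census_years=years,
    )
    return standardize_to_index(comm, zero_policy="floor"), traits


def generate_fixture(profile: str, seed: int | None = None, out_dir=None):
    """Generate a (community index series, trait table) fixture pair.

    With ``out_dir`` given, also writes ``<profile>_community.csv`` and
    ``<profile>_traits.csv`` there (byte-identical for identical seeds) and
    returns the two paths alongside the objects.
    """
    if profile not in PROFILES:
        raise ValidationError(f"unknown fixture profile {profile!r}; choose from {PROFILES}")
    rng = np.random.default_rng(seed)
    community, traits = _birds_like(rng) if profile == "birds_like" else _fish_like(rng)
    if out_dir is None:
        return community, traits
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cpath = out_dir / f"{profile}_community.csv"
    tpath = out_dir / f"{profile}_traits.csv"
    community.to_csv(cpath)
    traits.to_csv(tpath)
    return community, traits, cpath, tpath
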