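"""Data containers and CSV I/O for community time series and species traits.

Two containers underpin every analysis in the package:

``TraitTable``
    one row per species with a temperature preference (degrees C) and any
    number of additional attributes, each declared continuous or categorical.

``CommunityTimeSeries``
    a long-format panel of (species, year, abundance) records over a declared
    census-year sequence.  ``AbundanceIndexSeries`` is the standardized form in
    which every species takes the value 100 in the base census year, so that
    initially dominant species do not drive the community index throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype

from .errors import AlignmentError, FormatError, ValidationError

__all__ = [
    "CONTINUOUS",
    "CATEGORICAL",
    "TraitTable",
    "CommunityTimeSeries",
    "AbundanceIndexSeries",
    "AlignmentReport",
    "read_community",
    "write_community",
    "read_traits",
    "standardize_to_index",
    "align",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class TraitTable:
    """Per-species temperature preference plus named confounder attributes.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by species id (or carrying a ``species`` column) with a
        ``temp_pref`` column (degrees C) and one column per attribute.
    kinds : mapping, optional
        ``attribute -> "continuous" | "categorical"``.  Attributes not listed
        are inferred from dtype: numeric columns are continuous, anything else
        categorical.
    temp_col : str
        Name of the temperature-preference column (default ``"temp_pref"``).

    Invariants: species ids unique, temperature preference finite for every
    species, and no missing cell in any declared attribute.
    """

    def __init__(self, data: pd.DataFrame, kinds=None, temp_col: str = "temp_pref"):
        df = data.copy()
        if "species" in df.columns:
            df = df.set_index("species")
        df.index = df.index.astype(str)
        df.index.name = "species"
        if temp_col not in df.columns:
            raise FormatError(f"trait table lacks a {temp_col!r} column")
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate species ids in trait table: {dups}")
        tp = pd.to_numeric(df[temp_col], errors="coerce").astype(float)
        if not np.isfinite(tp.to_numpy()).all():
            bad = sorted(df.index[~np.isfinite(tp.to_numpy())])
            raise ValidationError(f"non-finite temperature preference for species: {bad}")
        df[temp_col] = tp

        self.temp_col = temp_col
        self.kinds: dict[str, str] = {}
        requested = dict(kinds or {})
        for name in df.columns:
            if name == temp_col:
                continue
            kind = requested.pop(name, None)
            if kind is None:
                kind = CONTINUOUS if is_numeric_dtype(df[name]) else CATEGORICAL
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise FormatError(f"unknown attribute kind {kind!r} for {name!r}")
            if kind == CONTINUOUS:
                vals = pd.to_numeric(df[name], errors="coerce").astype(float)
                if not np.isfinite(vals.to_numpy()).all():
                    bad = sorted(df.index[~np.isfinite(vals.to_numpy())])
                    raise ValidationError(
                        f"attribute {name!r} missing or non-finite for species: {bad}"
                    )
                df[name] = vals
            else:
                if df[name].isna().any():
                    bad = sorted(df.index[df[name].isna()])
                    raise ValidationError(f"attribute {name!r} missing for species: {bad}")
                df[name] = df[name].astype(str)
            self.kinds[name] = kind
        if requested:
            raise FormatError(f"kinds given for unknown attributes: {sorted(requested)}")
        self.data = df

    # -- accessors ---------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def temp_pref(self) -> pd.Series:
        return self.data[self.temp_col]

    @property
    def attributes(self) -> list[str]:
        return list(self.kinds)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, species) -> "TraitTable":
        missing = sorted(set(species) - set(self.data.index))
        if missing:
            raise ValidationError(f"species absent from trait table: {missing}")
        return TraitTable(self.data.loc[list(species)], kinds=self.kinds, temp_col=self.temp_col)

    def with_attribute(self, name: str, values: pd.Series, kind: str = CONTINUOUS) -> "TraitTable":
        df = self.data.copy()
        df[name] = values.reindex(df.index)
        kinds = dict(self.kinds)
        kinds[name] = kind
        return TraitTable(df, kinds=kinds, temp_col=self.temp_col)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, kinds=None, temp_col: str = "temp_pref") -> "TraitTable":
        df = pd.read_csv(path)
        if "species" not in df.columns:
            raise FormatError(f"{path}: trait CSV requires a 'species' column")
        return cls(df, kinds=kinds, temp_col=temp_col)

    def to_csv(self, path) -> None:
        self.data.reset_index().to_csv(path, index=False, float_format="%.10g")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TraitTable({len(self)} species, attributes={self.attributes})"


class CommunityTimeSeries:
    """Species-by-year abundance panel in long format.

    At most one record per (species, year); abundances are finite and
    non-negative; record years are a subset of the declared census years
    (missing species-year cells are permitted and simply contribute no row).
    """

    def __init__(self, data: pd.DataFrame, census_years=None):
        required = {"species", "year", "abundance"}
        missing = required - set(data.columns)
        if missing:
            raise FormatError(f"community table lacks columns: {sorted(missing)}")
        df = data.loc[:, ["species", "year", "abundance"]].copy()
        df["species"] = df["species"].astype(str)
        try:
            df["year"] = df["year"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"year column is not integer-valued: {exc}") from None
        df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce").astype(float)
        if df["abundance"].isna().any():
            bad = df.loc[df["abundance"].isna(), ["species", "year"]]
            raise ValidationError(f"missing/NaN abundance rows:\n{bad.to_string(index=False)}")
        neg = df["abundance"] < 0
        if neg.any():
            bad = df.loc[neg, ["species", "year", "abundance"]]
            raise ValidationError(f"negative abundance rows:\n{bad.to_string(index=False)}")
        dup = df.duplicated(["species", "year"])
        if dup.any():
            bad = df.loc[dup, ["species", "year"]].drop_duplicates()
            raise FormatError(
                f"duplicated (species, year) records:\n{bad.to_string(index=False)}"
            )
        years_present = sorted(df["year"].unique())
        if census_years is None:
            census_years = years_present
        else:
            census_years = sorted(int(y) for y in census_years)
            extra = set(years_present) - set(census_years)
            if extra:
                raise ValidationError(f"records in years outside the census sequence: {sorted(extra)}")
        self.data = df.sort_values(["species", "year"]).reset_index(drop=True)
        self.census_years = list(census_years)

    # -- accessors ---------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def years(self) -> list[int]:
        return list(self.census_years)

    def __len__(self) -> int:
        return len(self.data)

    def to_matrix(self) -> pd.DataFrame:
        """Species x year wide table (NaN for missing cells)."""
        return self.data.pivot(index="species", columns="year", values="abundance")

    def year_slice(self, year: int) -> pd.Series:
        sl = self.data[self.data["year"] == int(year)]
        return sl.set_index("species")["abundance"]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}({len(self.species)} species, "
            f"years {self.census_years[0]}-{self.census_years[-1]})"
        )


class AbundanceIndexSeries(CommunityTimeSeries):
    """Community series standardized so every species is 100 at ``base_year``."""

    def __init__(self, data: pd.DataFrame, base_year: int, census_years=None):
        super().__init__(data, census_years=census_years)
        self.base_year = int(base_year)
        base = self.data[self.data["year"] == self.base_year]
        if not np.allclose(base["abundance"].to_numpy(), 100.0, atol=1e-8):
            raise ValidationError("index series is not 100 for every species at the base year")
        if (self.data["abundance"] <= 0).any():
            bad = self.data.loc[self.data["abundance"] <= 0, ["species", "year"]]
            raise ValidationError(
                f"index series must be strictly positive (log-safe):\n{bad.to_string(index=False)}"
            )


@dataclass
class AlignmentReport:
    """Species present in only one of community / trait inputs."""

    community_only: list[str] = field(default_factory=list)
    trait_only: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.community_only and not self.trait_only


def read_community(path, column_map=None, census_years=None) -> CommunityTimeSeries:
    """Read a community CSV with columns mappable to species/year/abundance.

    ``column_map`` maps file column names to the canonical names, e.g.
    ``{"art": "species", "aar": "year", "indeks": "abundance"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = {"species", "year", "abundance"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return CommunityTimeSeries(df, census_years=census_years)


def write_community(series: CommunityTimeSeries, path) -> None:
    series.to_csv(path)


def read_traits(path, kinds=None, temp_col: str = "temp_pref") -> TraitTable:
    return TraitTable.from_csv(path, kinds=kinds, temp_col=temp_col)


def _apply_zero_policy(df: pd.DataFrame, zero_policy: str) -> pd.DataFrame:
    """Resolve zero abundances before taking logs or ratios.

    ``strict`` raises; ``floor`` replaces zeros with half the smallest positive
    abundance of the same species (warning emitted).  A species observed only
    at zero cannot be floored and always raises.
    """
    if zero_policy not in ("strict", "floor"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    zero = df["abundance"] == 0
    if not zero.any():
        return df
    if zero_policy == "strict":
        bad = df.loc[zero, ["species", "year"]]
        raise ValidationError(
            "zero abundances under strict policy (use zero_policy='floor'):\n"
            + bad.to_string(index=False)
        )
    df = df.copy()
    floors = (
        df.loc[df["abundance"] > 0].groupby("species")["abundance"].min() / 2.0
    )
    allzero = sorted(set(df.loc[zero, "species"]) - set(floors.index))
    if allzero:
        raise ValidationError(f"species with no positive abundance at all: {allzero}")
    df.loc[zero, "abundance"] = floors.reindex(df.loc[zero, "species"]).to_numpy()
    warnings.warn(
        f"floored {int(zero.sum())} zero abundance(s) to half the species minimum",
        stacklevel=3,
    )
    return df


def standardize_to_index(
    series: CommunityTimeSeries,
    base_year: int | None = None,
    zero_policy: str = "strict",
) -> AbundanceIndexSeries:
    """Rescale each species so its abundance is 100 in the base census year.

    value(s, t) = 100 * N(s, t) / N(s, base).  Species absent at the base year
    raise; zeros elsewhere follow ``zero_policy`` ('strict' or 'floor').
    """
    if base_year is None:
        base_year = series.census_years[0]
    base_year = int(base_year)
    if base_year not in series.census_years:
        raise ValidationError(f"base year {base_year} not among census years")
    df = _apply_zero_policy(series.data, zero_policy)
    base = df[df["year"] == base_year].set_index("species")["abundance"]
    absent = sorted(set(df["species"].unique()) - set(base.index))
    if absent:
        raise ValidationError(f"species absent at base year {base_year}: {absent}")
    zero_base = sorted(base.index[base <= 0])
    if zero_base:
        raise ValidationError(f"species with zero abundance at base year {base_year}: {zero_base}")
    out = df.copy()
    out["abundance"] = 100.0 * out["abundance"].to_numpy() / base.reindex(out["species"]).to_numpy()
    return AbundanceIndexSeries(out, base_year=base_year, census_years=series.census_years)


def align(series: CommunityTimeSeries, traits: TraitTable):
    """Inner-join community records with traits on species id.

    Returns ``(panel, matched_traits, report)`` where ``panel`` is a long
    DataFrame of the community records restricted to matched species with the
    trait columns merged in, ``matched_traits`` is the trait table restricted
    the same way, and ``report`` lists species found in only one input.
    """
    comm_species = set(series.data["species"].unique())
    trait_species = set(traits.data.index)
    shared = comm_species & trait_species
    if not shared:
        raise AlignmentError("community and trait tables share no species")
    report = AlignmentReport(
        community_only=sorted(comm_species - trait_species),
        trait_only=sorted(trait_species - comm_species),
    )
    keep = series.data[series.data["species"].isin(shared)]
    panel = keep.merge(traits.data.reset_index(), on="species", how="left")
    matched = traits.subset(sorted(shared))
    return panel.sort_values(["species", "year"]).reset_index(drop=True), matched, report
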