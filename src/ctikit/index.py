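"""The community temperature index (CTI) and its weighting machinery.

The CTI is a community-weighted mean of species' temperature preferences:

    CTI_t = sum_s  temp_pref_s * w_{s,t}

where w_{s,t} is the relative abundance of species s in year t (its abundance
divided by the total community abundance that year), or an equal weight over
the present species in the presence/absence variant, which isolates species
turnover from abundance change.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import CommunityTimeSeries, TraitTable, align
from .errors import ValidationError

__all__ = [
    "VARIANTS",
    "CTISeries",
    "relative_abundance",
    "compute_cti",
    "compute_cti_presence",
    "cti_series",
]

VARIANTS = ("original", "modelled", "modelled_uncorrected", "presence_absence", "true")


@dataclass
class CTISeries:
    """Per-year CTI values (degrees C) tagged by calculation variant."""

    variant: str
    values: pd.Series  # index: year (int) -> CTI

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown CTI variant {self.variant!r}")
        self.values = pd.Series(self.values, dtype=float)
        self.values.index = self.values.index.astype(int)
        self.values.index.name = "year"
        self.values.name = "cti"

    @property
    def years(self) -> list[int]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.values.reset_index()
        df.insert(1, "variant", self.variant)
        return df


def relative_abundance(abundances: pd.Series) -> pd.Series:
    """Normalize one year's abundances to weights summing to 1.

    Raises if the year has no positive abundance (the CTI is then undefined).
    """
    a = pd.Series(abundances, dtype=float)
    if (a < 0).any():
        raise ValidationError("negative abundance in relative-abundance calculation")
    total = a.sum()
    if total <= 0:
        raise ValidationError("all-zero community: CTI undefined for this year")
    return a / total


def compute_cti(weights: pd.Series, traits: TraitTable | pd.Series) -> float:
    """Abundance-weighted mean temperature preference for one year."""
    prefs = traits.temp_pref if isinstance(traits, TraitTable) else pd.Series(traits, dtype=float)
    missing = sorted(set(weights.index) - set(prefs.index))
    if missing:
        raise ValidationError(f"weighted species missing from trait table: {missing}")
    aligned = prefs.reindex(weights.index)
    return float((aligned * weights).sum())


def compute_cti_presence(present, traits: TraitTable | pd.Series) -> float:
    """Unweighted mean temperature preference over the present species."""
    present = list(present)
    if not present:
        raise ValidationError("empty presence set: CTI undefined")
    prefs = traits.temp_pref if isinstance(traits, TraitTable) else pd.Series(traits, dtype=float)
    missing = sorted(set(present) - set(prefs.index))
    if missing:
        raise ValidationError(f"present species missing from trait table: {missing}")
    return float(prefs.reindex(present).mean())


def cti_series(
    series: CommunityTimeSeries,
    traits: TraitTable,
    variant: str = "original",
    presence_threshold: float = 0.0,
) -> CTISeries:
    """One CTI value per census year under the requested weighting.

    ``variant`` selects the weighting rule: any abundance-weighted variant tag
    ('original', 'modelled', 'modelled_uncorrected', 'true') uses relative
    abundances; 'presence_absence' weights species equally when their
    abundance exceeds ``presence_threshold``.
    """
    panel, matched, _ = align(series, traits)
    prefs = matched.temp_pref
    out: dict[int, float] = {}
    for year, grp in panel.groupby("year"):
        a = grp.set_index("species")["abundance"]
        if variant == "presence_absence":
            present = a.index[a > presence_threshold]
            out[int(year)] = compute_cti_presence(present, prefs)
        else:
            out[int(year)] = compute_cti(relative_abundance(a), prefs)
    values = pd.Series(out).sort_index()
    return CTISeries(variant=variant, values=values)
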