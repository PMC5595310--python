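"""Community simulator for validating the model-based CTI correction.

A hypothetical community of ``n_species`` species is tracked over ``n_years``
annual censuses.  Two standard-normal species traits -- temperature preference
and habitat breadth -- drive log-linear population growth:

    log N_{s,t} = log N_{s,t-1} + b_temp * temp_pref_s + b_habitat * habitat_breadth_s

so the expected trajectory is a deterministic exponential skeleton around
which observation error is drawn.  Four error models are supported: Poisson
counts (demographic stochasticity); Poisson plus log-normal overdispersion
with sd twice the trait effect; and Poisson with mis-measured traits handed to
the analyst (measured vs actual correlation ``measurement_r``), for the focal
trait only or for both traits.  Trait covariation is controlled by ``r``: the
diagnostic scenario sets r = -0.6 (habitat generalists are cool-adapted), in
which case the habitat effect on growth masks the temperature signal and the
original CTI is biased relative to the "true" CTI of a community driven by
temperature preference alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import CommunityTimeSeries, TraitTable, standardize_to_index
from .errors import CTIKitError, ScenarioError, ValidationError
from .index import CTISeries, cti_series
from .model import AttributeYearModel, modelled_cti

__all__ = [
    "ERROR_MODELS",
    "SimulationConfig",
    "SimulationResult",
    "simulate_traits",
    "simulate_community",
    "measured_traits",
    "true_cti",
    "run_scenario",
    "bias_grid",
    "robustness_suite",
]

ERROR_MODELS = ("none", "poisson", "overdispersion", "measure_temp", "measure_both")

_LOG_BOUND = np.log(1e12)  # overflow guard on expected log abundance


@dataclass
class SimulationConfig:
    """Study conditions for one simulation scenario.

    Defaults are the headline conditions: 50 species, 20 years, equal trait
    effects on log growth, 500 replicates, Poisson error, initial abundance
    100.  ``trait_correlation`` sets the temperature-habitat covariation
    (0 for the independent scenario, -0.6 for the confounded one).
    """

    n_species: int = 50
    n_years: int = 20
    b_temp: float = 0.05
    b_habitat: float = 0.05
    trait_correlation: float = 0.0
    error_model: str = "poisson"
    overdispersion_sd: float | None = None  # default 2*|b_temp|
    measurement_r: float = 0.7
    n_reps: int = 500
    N0: float = 100.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_species < 2 or self.n_years < 2 or self.n_reps < 1:
            raise ValidationError("need n_species >= 2, n_years >= 2, n_reps >= 1")
        if abs(self.trait_correlation) > 1:
            raise ValidationError("|trait_correlation| must be <= 1")
        if not (0 < self.measurement_r <= 1):
            raise ValidationError("measurement_r must be in (0, 1]")
        if self.error_model not in ERROR_MODELS:
            raise ValidationError(f"unknown error model {self.error_model!r}")

    @property
    def resolved_overdispersion_sd(self) -> float:
        if self.overdispersion_sd is not None:
            return self.overdispersion_sd
        return 2.0 * abs(self.b_temp)


@dataclass
class SimulationResult:
    """Replicate CTI trajectories plus per-year bias summaries against truth."""

    trajectories: pd.DataFrame  # columns: rep, year, variant, cti
    bias: pd.DataFrame  # columns: variant, year, mean, lo, hi (variant - true)
    n_reps: int
    n_failed: int
    config: SimulationConfig

    def final_year_bias(self, variant: str):
        """(mean, lo, hi) of variant - true in the last census year."""
        last = self.bias["year"].max()
        row = self.bias[(self.bias["variant"] == variant) & (self.bias["year"] == last)]
        if row.empty:
            raise KeyError(f"no bias summary for variant {variant!r}")
        r = row.iloc[0]
        return float(r["mean"]), float(r["lo"]), float(r["hi"])


def simulate_traits(n_species: int, r: float, rng) -> TraitTable:
    """Bivariate-normal traits with standard-normal marginals and correlation r."""
    if abs(r) > 1:
        raise ValidationError("|r| must be <= 1")
    rng = np.random.default_rng(rng)
    temp = rng.standard_normal(n_species)
    indep = rng.standard_normal(n_species)
    habitat = r * temp + np.sqrt(max(0.0, 1.0 - r * r)) * indep
    ids = [f"sp{i + 1:03d}" for i in range(n_species)]
    return TraitTable(
        pd.DataFrame({"species": ids, "temp_pref": temp, "habitat_breadth": habitat})
    )


def _expected_log_abundance(traits: TraitTable, config: SimulationConfig, b_habitat: float):
    growth = (
        config.b_temp * traits.temp_pref.to_numpy()
        + b_habitat * traits.data["habitat_breadth"].to_numpy()
    )
    steps = np.arange(config.n_years)
    logmu = np.log(config.N0) + np.outer(growth, steps)  # (S, T)
    if logmu.max() > _LOG_BOUND or logmu.min() < -_LOG_BOUND:
        raise ValidationError(
            "expected abundance out of range; reduce effect sizes or the time horizon"
        )
    return logmu


def simulate_community(
    traits: TraitTable,
    config: SimulationConfig,
    rng=None,
    b_habitat: float | None = None,
) -> CommunityTimeSeries:
    """Draw one community time series under the configured error model.

    ``b_habitat`` overrides the config value (the temperature-only reference
    community sets it to 0).  Measurement-error models affect only the trait
    table handed to the analyst (see ``measured_traits``); the dynamics here
    are Poisson.
    """
    rng = np.random.default_rng(rng)
    bh = config.b_habitat if b_habitat is None else b_habitat
    logmu = _expected_log_abundance(traits, config, bh)
    if config.error_model == "none":
        counts = np.exp(logmu)
    elif config.error_model == "overdispersion":
        noisy = logmu + rng.normal(0.0, config.resolved_overdispersion_sd, size=logmu.shape)
        counts = rng.poisson(np.exp(np.clip(noisy, -_LOG_BOUND, _LOG_BOUND))).astype(float)
    else:  # poisson, measure_temp, measure_both
        counts = rng.poisson(np.exp(logmu)).astype(float)
    years = np.arange(1, config.n_years + 1)
    df = pd.DataFrame(
        {
            "species": np.repeat(traits.species, config.n_years),
            "year": np.tile(years, len(traits)),
            "abundance": counts.ravel(),
        }
    )
    return CommunityTimeSeries(df, census_years=years)


def measured_traits(traits: TraitTable, config: SimulationConfig, rng) -> TraitTable:
    """The analyst's trait table: mis-measured under the measurement-error models.

    Measured = actual + N(0, sigma_e) with sigma_e = sigma * sqrt(1/r^2 - 1),
    which gives cor(measured, actual) = r for standard-normal traits.  Applied
    once per replicate and held fixed across years; the generator always uses
    the actual traits.
    """
    if config.error_model not in ("measure_temp", "measure_both"):
        return traits
    rng = np.random.default_rng(rng)
    r = config.measurement_r
    sd = np.sqrt(max(1.0 / (r * r) - 1.0, 0.0))
    df = traits.data.copy()
    df["temp_pref"] = df["temp_pref"] + rng.normal(0.0, sd, len(df))
    if config.error_model == "measure_both":
        df["habitat_breadth"] = df["habitat_breadth"] + rng.normal(0.0, sd, len(df))
    return TraitTable(df, kinds=traits.kinds)


def true_cti(traits: TraitTable, config: SimulationConfig, rng=None) -> CTISeries:
    """CTI of the reference community driven by temperature preference alone.

    Simulated with the habitat effect forced to zero; stochasticity is Poisson
    unless the config disables error entirely.  Uses the actual (not
    mis-measured) temperature preferences.
    """
    cfg = config if config.error_model == "none" else replace(config, error_model="poisson")
    community = simulate_community(traits, cfg, rng=rng, b_habitat=0.0)
    idx = standardize_to_index(community, zero_policy="floor")
    series = cti_series(idx, traits, variant="original")
    return CTISeries(variant="true", values=series.values)


def _replicate(
    config: SimulationConfig,
    seeds,
    include_modelled: bool,
    model_attribute_interaction: str,
    extra_random_predictor: bool,
):
    rng_traits, rng_obs, rng_true, rng_meas, rng_extra = (
        np.random.default_rng(s) for s in seeds
    )
    traits = simulate_traits(config.n_species, config.trait_correlation, rng_traits)
    observed = simulate_community(traits, config, rng=rng_obs)
    obs_idx = standardize_to_index(observed, zero_policy="floor")
    analyst = measured_traits(traits, config, rng_meas)

    out = {
        "true": true_cti(traits, config, rng=rng_true),
        "original": cti_series(obs_idx, analyst, variant="original"),
    }
    if include_modelled:
        confounders = ["habitat_breadth"]
        if extra_random_predictor:
            noise = pd.Series(rng_extra.standard_normal(len(analyst)), index=analyst.data.index)
            analyst = analyst.with_attribute("noise_predictor", noise)
            confounders.append("noise_predictor")
        model = AttributeYearModel(
            confounders=confounders,
            attribute_interaction=model_attribute_interaction,
            allow_collinear=True,  # the guard is a real-data rail, not a study condition
            zero_policy="floor",
        ).fit(obs_idx, analyst)
        out["modelled"] = modelled_cti(model)
    return out


def run_scenario(
    config: SimulationConfig,
    include_modelled: bool = True,
    model_attribute_interaction: str = "none",
    extra_random_predictor: bool = False,
    max_failure_fraction: float = 0.2,
) -> SimulationResult:
    """Replicate the scenario and summarise CTI bias against the true CTI.

    Each replicate draws fresh traits, simulates the observed and the
    temperature-only reference community, computes the original CTI and (when
    ``include_modelled``) fits the attribute-year model on the analyst's data
    to compute the modelled CTI.  Bias summaries are per-year percentile
    (2.5/97.5) intervals of (variant - true) across replicates.  Replicate
    fits that fail are excluded and counted; more than
    ``max_failure_fraction`` failures aborts the scenario.
    """
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.n_reps)
    rows = []
    n_failed = 0
    failures: list[str] = []
    for rep, rs in enumerate(rep_seeds):
        seeds = rs.spawn(5)
        try:
            series = _replicate(
                config, seeds, include_modelled, model_attribute_interaction,
                extra_random_predictor,
            )
        except (CTIKitError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            failures.append(f"rep {rep}: {type(exc).__name__}: {exc}")
            continue
        for variant, s in series.items():
            for year, val in s.values.items():
                rows.append((rep, int(year), variant, float(val)))
    if n_failed > max_failure_fraction * config.n_reps:
        detail = "\n".join(failures[:5])
        raise ScenarioError(
            f"{n_failed}/{config.n_reps} replicates failed (> {max_failure_fraction:.0%}):\n{detail}"
        )
    traj = pd.DataFrame(rows, columns=["rep", "year", "variant", "cti"])
    bias = _bias_summary(traj)
    return SimulationResult(
        trajectories=traj,
        bias=bias,
        n_reps=config.n_reps - n_failed,
        n_failed=n_failed,
        config=config,
    )


def _bias_summary(traj: pd.DataFrame) -> pd.DataFrame:
    wide = traj.pivot_table(index=["rep", "year"], columns="variant", values="cti")
    rows = []
    for variant in wide.columns:
        if variant == "true":
            continue
        diff = (wide[variant] - wide["true"]).dropna()
        grp = diff.groupby(level="year")
        summary = pd.DataFrame(
            {
                "mean": grp.mean(),
                "lo": grp.quantile(0.025),
                "hi": grp.quantile(0.975),
            }
        ).reset_index()
        summary.insert(0, "variant", variant)
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)


def bias_grid(
    config: SimulationConfig,
    r_values=(0.0, 0.3, 0.6),
    effect_values=None,
    n_species_values=None,
) -> pd.DataFrame:
    """Final-year bias of the original CTI over a scenario grid.

    Bias is (true - original) in the last census year, summarised by its mean
    and percentile interval across replicates.  The grid varies the
    trait correlation, the (common) trait effect size, and the community size;
    no model fitting is involved.
    """
    cells = []
    for r in r_values:
        cells.append({"trait_correlation": r})
    for b in effect_values or ():
        cells.append({"b_temp": b, "b_habitat": b})
    for n in n_species_values or ():
        cells.append({"n_species": n})
    if not cells:
        raise ValidationError("empty bias grid")
    rows = []
    for cell in cells:
        cfg = replace(config, **cell)
        result = run_scenario(cfg, include_modelled=False)
        mean, lo, hi = result.final_year_bias("original")
        rows.append(
            {
                "trait_correlation": cfg.trait_correlation,
                "b_temp": cfg.b_temp,
                "n_species": cfg.n_species,
                "bias_mean": -mean,  # true - original
                "bias_lo": -hi,
                "bias_hi": -lo,
                "n_reps": result.n_reps,
            }
        )
    return pd.DataFrame(rows)


def robustness_suite(config: SimulationConfig) -> dict:
    """Bias summaries under deliberately mis-specified analyst models.

    Re-runs the scenario with (a) the baseline analyst model, (b) a
    superfluous 3-way year x focal x confounder interaction, and (c) an extra
    random-noise predictor, none of which exist in the generating dynamics.
    """
    return {
        "baseline": run_scenario(config),
        "three_way_interaction": run_scenario(config, model_attribute_interaction="with_year"),
        "superfluous_predictor": run_scenario(config, extra_random_predictor=True),
    }
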