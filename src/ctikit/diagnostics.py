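"""Supporting analyses around the CTI: covariation and trend tests, the
warm/cool quartile mechanism, and loess trend smoothing.

These are the checks recommended before applying the model-based correction:
first test which attributes are linked with species' long-term population
trends (year-by-attribute interactions on logged abundances with AR(1)
errors), then examine covariation between temperature preference and those
attributes, and finally ask whether a CTI trend is driven by gains of
warm-adapted or losses of cool-adapted species (quartile geometric means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CATEGORICAL, CommunityTimeSeries, TraitTable, _apply_zero_policy, align
from .errors import RankDeficiencyError, ValidationError
from .index import CTISeries

__all__ = [
    "CovariationTest",
    "TrendTestResult",
    "QuartileTrend",
    "covariation_test",
    "trend_test",
    "quartile_mechanism",
    "loess_trend",
]


@dataclass
class CovariationTest:
    """Linear-model test of focal trait ~ other attribute."""

    focal: str
    other: str
    statistic: float  # F
    df: tuple
    pvalue: float
    pearson_r: float | None  # continuous-continuous pairs only
    group_summary: pd.DataFrame | None  # categorical attributes only
    largest_contrast: tuple | None  # (level_a, level_b, difference)


def covariation_test(traits: TraitTable, focal: str = "temp_pref", other: str = "") -> CovariationTest:
    """Test covariation between the focal trait and another attribute.

    Categorical attributes give a one-way ANOVA F test plus per-level
    summaries with the largest pairwise mean difference flagged; continuous
    attributes give the regression F test and the Pearson correlation.
    """
    if not other:
        raise ValidationError("name the attribute to test against")
    y = traits.temp_pref if focal == traits.temp_col else traits.data[focal].astype(float)
    if float(np.var(y)) == 0.0:
        raise ValidationError(f"{focal!r} has zero variance; covariation test undefined")
    if other not in traits.kinds and other != traits.temp_col:
        raise ValidationError(f"unknown attribute {other!r}")

    kind = traits.kinds.get(other, "continuous")
    if kind == CATEGORICAL:
        groups = {lvl: y[traits.data[other] == lvl].to_numpy() for lvl in sorted(traits.data[other].unique())}
        small = [lvl for lvl, v in groups.items() if len(v) < 2]
        if small:
            warnings.warn(f"levels with fewer than 2 species: {small}", stacklevel=2)
        if len(groups) < 2:
            raise ValidationError(f"attribute {other!r} has a single level")
        F, p = stats.f_oneway(*groups.values())
        k, n = len(groups), len(y)
        means = {lvl: float(np.mean(v)) for lvl, v in groups.items()}
        summary = pd.DataFrame(
            {
                "level": list(groups),
                "n": [len(v) for v in groups.values()],
                "mean": [means[lvl] for lvl in groups],
                "sd": [float(np.std(v, ddof=1)) if len(v) > 1 else np.nan for v in groups.values()],
            }
        )
        contrasts = [
            (a, b, means[a] - means[b])
            for i, a in enumerate(groups)
            for b in list(groups)[i + 1 :]
        ]
        largest = max(contrasts, key=lambda c: abs(c[2]))
        return CovariationTest(focal, other, float(F), (k - 1, n - k), float(p), None, summary, largest)

    x = traits.data[other].astype(float)
    if float(np.var(x)) == 0.0:
        raise ValidationError(f"{other!r} has zero variance; covariation test undefined")
    res = stats.linregress(x, y)
    n = len(y)
    F = float(res.rvalue**2 * (n - 2) / max(1e-300, 1.0 - res.rvalue**2))
    return CovariationTest(
        focal, other, F, (1, n - 2), float(res.pvalue), float(res.rvalue), None, None
    )


@dataclass
class TrendTestResult:
    """Year x attribute interaction effects on log abundance with AR(1) errors."""

    table: pd.DataFrame  # term, estimate, se, lo, hi
    rho: float
    sigma2: float
    n_obs: int
    n_iter: int

    @property
    def interactions(self) -> pd.DataFrame:
        return self.table[self.table["term"].str.contains(":cyear")].reset_index(drop=True)


def _attribute_columns(traits: TraitTable, attributes):
    """Centred continuous / reference-dummy-coded attribute columns."""
    cols = {}
    for name in attributes:
        if name == traits.temp_col:
            cols[name] = traits.temp_pref - traits.temp_pref.mean()
        elif traits.kinds.get(name) == CATEGORICAL:
            levels = sorted(traits.data[name].unique())
            for lvl in levels[1:]:
                cols[f"{name}[{lvl}]"] = (traits.data[name] == lvl).astype(float)
        elif name in traits.kinds:
            v = traits.data[name].astype(float)
            cols[name] = v - v.mean()
        else:
            raise ValidationError(f"unknown attribute {name!r}")
    return pd.DataFrame(cols)


def trend_test(
    community: CommunityTimeSeries,
    traits: TraitTable,
    attributes=None,
    zero_policy: str = "strict",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> TrendTestResult:
    """Joint test of attribute effects on species' long-term abundance trends.

    One multiple regression of log abundance on continuous year, all attribute
    main effects and their year interactions, with AR(1) errors within species
    across consecutive census years, fitted by iterated Prais-Winsten GLS
    (rho re-estimated from lag-1 residuals until stable).  95% CIs are the
    normal-approximation estimate +/- 1.96 SE convention.
    """
    if attributes is None:
        attributes = [traits.temp_col] + traits.attributes
    panel, matched, _ = align(community, traits)
    if panel["year"].nunique() < 3:
        raise ValidationError("trend test needs at least 3 census years")
    panel = _apply_zero_policy(panel, zero_policy)
    y = np.log(panel["abundance"].to_numpy())

    years = np.asarray(sorted(panel["year"].unique()), float)
    cyear = (panel["year"].to_numpy() - years.mean()) / (years.std() or 1.0)
    A = _attribute_columns(matched, attributes)
    Arow = A.reindex(panel["species"]).to_numpy()

    labels = ["Intercept", "cyear"] + list(A.columns) + [f"{c}:cyear" for c in A.columns]
    X = np.column_stack([np.ones(len(y)), cyear, Arow, Arow * cyear[:, None]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("trend-test design matrix is rank deficient")

    pos_of_year = {int(yr): i for i, yr in enumerate(sorted(panel["year"].unique()))}
    pos = panel["year"].map(pos_of_year).to_numpy()
    species = panel["species"].to_numpy()
    # lag-1 pairs: consecutive census positions within the same species
    same_sp = species[1:] == species[:-1]
    consec = (np.diff(pos) == 1) & same_sp
    first_of_run = np.concatenate([[True], ~consec])

    rho = 0.0
    for it in range(max_iter):
        # Prais-Winsten whitening given rho
        w = np.where(first_of_run, np.sqrt(1.0 - rho * rho), 1.0)
        Xt = X * w[:, None]
        yt = y * w
        lagged = np.concatenate([[False], consec])
        Xt[lagged] = X[lagged] - rho * X[np.flatnonzero(lagged) - 1]
        yt[lagged] = y[lagged] - rho * y[np.flatnonzero(lagged) - 1]
        beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = y - X @ beta
        a, b = resid[:-1][consec], resid[1:][consec]
        denom = float(a @ a)
        rho_new = float(np.clip(a @ b / denom, -0.99, 0.99)) if denom > 0 else 0.0
        if abs(rho_new - rho) < tol:
            rho = rho_new
            break
        rho = rho_new
    # final whitened fit at converged rho for the covariance of beta
    w = np.where(first_of_run, np.sqrt(1.0 - rho * rho), 1.0)
    Xt = X * w[:, None]
    yt = y * w
    lagged = np.concatenate([[False], consec])
    Xt[lagged] = X[lagged] - rho * X[np.flatnonzero(lagged) - 1]
    yt[lagged] = y[lagged] - rho * y[np.flatnonzero(lagged) - 1]
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    rt = yt - Xt @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(rt @ rt) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(Xt.T @ Xt)
    se = np.sqrt(np.diag(cov))

    # report on the original per-calendar-year scale
    scale = years.std() or 1.0
    est = beta.copy()
    se_out = se.copy()
    for i, lab in enumerate(labels):
        if lab == "cyear" or lab.endswith(":cyear"):
            est[i] /= scale
            se_out[i] /= scale
    table = pd.DataFrame(
        {
            "term": labels,
            "estimate": est,
            "se": se_out,
            "lo": est - 1.96 * se_out,
            "hi": est + 1.96 * se_out,
        }
    )
    return TrendTestResult(table=table, rho=rho, sigma2=sigma2, n_obs=len(y), n_iter=it + 1)


@dataclass
class QuartileTrend:
    """Geometric-mean abundance trajectories of the warm and cool quartiles."""

    upper: pd.Series  # year -> geometric mean, warm-adapted quartile
    lower: pd.Series
    upper_species: list
    lower_species: list


def quartile_mechanism(
    community: CommunityTimeSeries,
    traits: TraitTable,
    zero_policy: str = "strict",
) -> QuartileTrend:
    """Per-year geometric-mean abundance of the warmest and coolest quartiles.

    Species are ranked by temperature preference (ties broken by species id);
    the upper and lower groups hold ceil(n/4) species each.  Positive
    abundances are required for the geometric mean (zero policy as in the
    data layer).
    """
    panel, matched, _ = align(community, traits)
    n = len(matched)
    if n < 4:
        raise ValidationError("quartile analysis needs at least 4 species")
    panel = _apply_zero_policy(panel, zero_policy)
    order = matched.data.sort_values(
        [matched.temp_col], kind="mergesort"
    ).index.tolist()  # mergesort: stable, so ties fall back to species-id order
    k = int(np.ceil(n / 4))
    lower_sp, upper_sp = order[:k], order[-k:]

    def gmeans(species_list):
        sub = panel[panel["species"].isin(species_list)]
        return sub.groupby("year")["abundance"].apply(lambda v: float(stats.gmean(v)))

    return QuartileTrend(
        upper=gmeans(upper_sp),
        lower=gmeans(lower_sp),
        upper_species=upper_sp,
        lower_species=lower_sp,
    )


def loess_trend(
    series: CTISeries | pd.Series,
    span: float = 0.75,
    degree: int = 2,
) -> pd.DataFrame:
    """Locally weighted polynomial (loess) smooth with pointwise 95% band.

    Tricube weights over the nearest floor(span*n) points, local polynomial of
    the given degree evaluated at each census year.  The band is the
    conventional fit +/- 1.96 * SE with the residual variance estimated on
    the smoother's residual degrees of freedom.  Returns a DataFrame with
    columns year, fit, se, lo, hi.
    """
    values = series.values if isinstance(series, CTISeries) else pd.Series(series, dtype=float)
    x = np.asarray(values.index, float)
    y = values.to_numpy(dtype=float)
    n = len(y)
    if n < max(4, degree + 2):
        raise ValidationError(f"loess needs at least {max(4, degree + 2)} points")
    if not (0 < span <= 1):
        raise ValidationError("span must be in (0, 1]")
    q = int(np.floor(span * n))
    if q < degree + 1:
        raise ValidationError("span too small for the requested polynomial degree")

    L = np.zeros((n, n))
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if h <= 0:
            h = np.finfo(float).tiny
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        B = np.vander(x - x0, degree + 1, increasing=True)  # row of interest: e_0
        WB = B * w[:, None]
        G = B.T @ WB
        # l_i' = e_0' (B'WB)^-1 B'W
        li = np.linalg.solve(G, WB.T)[0]
        L[i] = li
    fit = L @ y
    resid = y - fit
    nu1 = float(np.trace(L))
    nu2 = float(np.sum(L * L))
    dof = max(n - 2 * nu1 + nu2, 1.0)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.sum(L * L, axis=1))
    return pd.DataFrame(
        {"year": x.astype(int), "fit": fit, "se": se, "lo": fit - 1.96 * se, "hi": fit + 1.96 * se}
    )
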