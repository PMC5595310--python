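"""Attribute-by-year regression behind the model-based CTI.

The confounding problem: species' temperature preferences covary with other
attributes (habitat preference, body size, exploitation), and those attributes
respond to non-climate drivers.  A trend in the plain abundance-weighted CTI
can therefore reflect land-use change or fishing as much as warming.  The
correction fits, on species' log abundance indices,

    log N_{s,t} = a + b_t + c x_s + d z_s + e_t x_s + f_t z_s
                  + Sp_s + u_s cyear_t + eps_{s,t}

with year as a factor (b_t; first census year as reference), focal trait x
(temperature preference) and confounders z entering both as main effects and
in year interactions, species random intercepts Sp_s and random slopes u_s on
continuous year (each constrained to sum to zero), and residuals following an
AR(1) process with coefficient rho within species across consecutive census
years.  Abundances are then *predicted* from the fitted fixed effects -- with
the year x confounder interactions dropped, so that year-to-year variation in
the predictions is attributable to temperature preference alone -- plus the
species random intercepts, and the CTI is computed on those predictions
("modelled CTI").  Keeping every year interaction instead gives the
"modelled-uncorrected CTI", a model-adequacy check against the original CTI.

Estimation is deterministic profile maximum likelihood: beta and the BLUPs
have closed forms given the covariance parameters, and the profiled deviance
is minimised over (atanh rho, log variance ratios) with bounded Nelder-Mead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .data import CATEGORICAL, CommunityTimeSeries, TraitTable, _apply_zero_policy, align
from .errors import (
    CollinearityError,
    ConvergenceError,
    RankDeficiencyError,
    ValidationError,
)
from .index import CTISeries, cti_series

__all__ = [
    "AttributeYearModel",
    "modelled_cti",
    "modelled_uncorrected_cti",
    "randomized_attribute_cti",
    "compare_interaction_models",
]

# design-column roles; temp_only prediction zeroes every year interaction
# that involves a confounder
_ROLE_INTERCEPT = "intercept"
_ROLE_YEAR = "year"
_ROLE_FOCAL = "focal_main"
_ROLE_CONF = "conf_main"
_ROLE_ATTR_INTER = "attr_inter"
_ROLE_YEAR_FOCAL = "year_focal"
_ROLE_YEAR_CONF = "year_conf"
_ROLE_YEAR_ATTR = "year_attr_inter"
_CONFOUNDER_ROLES = frozenset({_ROLE_YEAR_CONF, _ROLE_YEAR_ATTR})

_JITTER = 1e-8  # ridge on the within-species correlation matrix


@dataclass
class _Coding:
    """Frozen covariate coding so permuted trait values reuse fit-time centring."""

    focal: str
    focal_mean: float
    confounders: tuple[str, ...]
    conf_kinds: dict
    conf_means: dict  # continuous confounder -> centring mean
    conf_levels: dict  # categorical confounder -> sorted level list


def _species_covariates(traits_df: pd.DataFrame, coding: _Coding) -> pd.DataFrame:
    """Species-level design columns (centred focal, centred/dummy confounders)."""
    out = pd.DataFrame(index=traits_df.index)
    out[coding.focal] = traits_df[coding.focal].astype(float) - coding.focal_mean
    for name in coding.confounders:
        if coding.conf_kinds[name] == CATEGORICAL:
            levels = coding.conf_levels[name]
            vals = traits_df[name].astype(str)
            unknown = sorted(set(vals) - set(levels))
            if unknown:
                raise ValidationError(f"unknown level(s) for {name!r}: {unknown}")
            for lvl in levels[1:]:  # first (alphabetical) level is the reference
                out[f"{name}[{lvl}]"] = (vals == lvl).astype(float)
        else:
            out[name] = traits_df[name].astype(float) - coding.conf_means[name]
    return out


def _make_coding(traits: TraitTable, focal: str, confounders) -> _Coding:
    kinds, means, levels = {}, {}, {}
    for name in confounders:
        if name not in traits.kinds and name != traits.temp_col:
            raise ValidationError(f"confounder {name!r} not in trait table")
        kind = traits.kinds.get(name, CATEGORICAL)
        kinds[name] = kind
        if kind == CATEGORICAL:
            lv = sorted(traits.data[name].astype(str).unique())
            if len(lv) < 2:
                raise ValidationError(f"categorical confounder {name!r} has a single level")
            levels[name] = lv
        else:
            means[name] = float(traits.data[name].mean())
    if focal == traits.temp_col:
        fmean = float(traits.temp_pref.mean())
    else:
        if focal not in traits.kinds or traits.kinds[focal] != "continuous":
            raise ValidationError(f"focal trait {focal!r} must be a continuous attribute")
        fmean = float(traits.data[focal].mean())
    return _Coding(
        focal=focal,
        focal_mean=fmean,
        confounders=tuple(confounders),
        conf_kinds=kinds,
        conf_means=means,
        conf_levels=levels,
    )


def _build_design(panel, years, coding, species_cov, attribute_interaction):
    """Row-level fixed-effects design matrix for a (species, year) panel.

    Returns (X, column labels, roles) with the year factor reference-coded on
    the first census year, so the model intercept is the year-1 level and every
    interaction coefficient vanishes in year 1.
    """
    species_row = panel["species"].to_numpy()
    year_row = panel["year"].to_numpy()
    n = len(panel)
    later_years = [y for y in years if y != years[0]]
    D = np.equal.outer(year_row, np.asarray(later_years)).astype(float)  # (n, T-1)

    C = species_cov.reindex(species_row)
    focal_col = C[coding.focal].to_numpy()
    conf_labels = [c for c in species_cov.columns if c != coding.focal]
    Cc = C[conf_labels].to_numpy() if conf_labels else np.empty((n, 0))

    cols: list[np.ndarray] = [np.ones((n, 1))]
    labels: list[str] = ["Intercept"]
    roles: list[str] = [_ROLE_INTERCEPT]

    cols.append(D)
    labels += [f"year[{y}]" for y in later_years]
    roles += [_ROLE_YEAR] * len(later_years)

    cols.append(focal_col[:, None])
    labels.append(coding.focal)
    roles.append(_ROLE_FOCAL)

    if conf_labels:
        cols.append(Cc)
        labels += conf_labels
        roles += [_ROLE_CONF] * len(conf_labels)

    inter_cols = []
    if attribute_interaction in ("main", "with_year") and conf_labels:
        inter_cols = [(lab, focal_col * Cc[:, j]) for j, lab in enumerate(conf_labels)]
        cols.append(np.column_stack([v for _, v in inter_cols]))
        labels += [f"{coding.focal}:{lab}" for lab, _ in inter_cols]
        roles += [_ROLE_ATTR_INTER] * len(inter_cols)

    cols.append(D * focal_col[:, None])
    labels += [f"year[{y}]:{coding.focal}" for y in later_years]
    roles += [_ROLE_YEAR_FOCAL] * len(later_years)

    for j, lab in enumerate(conf_labels):
        cols.append(D * Cc[:, j][:, None])
        labels += [f"year[{y}]:{lab}" for y in later_years]
        roles += [_ROLE_YEAR_CONF] * len(later_years)

    if attribute_interaction == "with_year":
        for lab, v in inter_cols:
            cols.append(D * v[:, None])
            labels += [f"year[{y}]:{coding.focal}:{lab}" for y in later_years]
            roles += [_ROLE_YEAR_ATTR] * len(later_years)

    return np.hstack(cols), labels, roles


def _ar1_corr(pos: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) correlation over census positions; non-consecutive gaps break runs."""
    run = np.concatenate([[0], np.cumsum(np.diff(pos) != 1)])
    lag = np.abs(np.subtract.outer(pos, pos)).astype(int)
    same = np.equal.outer(run, run)
    R = np.where(same, np.power(float(rho), lag), 0.0)
    np.fill_diagonal(R, 1.0)
    return R


class AttributeYearModel:
    """Mixed-effects attribute-by-year regression for model-based CTI.

    Parameters
    ----------
    confounders : sequence of str
        Attribute names (from the trait table) whose year interactions are to
        be removed from the corrected predictions.
    focal_trait : str
        Continuous trait defining the index (default the temperature-
        preference column).
    attribute_interaction : {"none", "main", "with_year"}
        Optionally add focal x confounder interactions, either as main effects
        only or additionally interacted with the year factor (3-way).
    collinearity_threshold : float
        Refuse to fit when |r| between the focal trait and a continuous
        confounder exceeds this (default 0.7) unless ``allow_collinear``.
    zero_policy : {"strict", "floor"}
        How zero abundances are resolved before taking logs.
    max_iter, tol : int, float
        Nelder-Mead budget and simplex tolerance for the covariance
        parameters.

    Fitted attributes (trailing underscore) include ``coef_``, ``rho_``,
    ``sigma2_``, ``sigma2_species_``, ``sigma2_slope_``, ``species_effects_``
    (sum-to-zero random intercept BLUPs), ``species_slopes_``, ``loglik_``,
    ``aic_``, ``converged_`` and ``n_iter_``.
    """

    def __init__(
        self,
        confounders=(),
        focal_trait: str = "temp_pref",
        attribute_interaction: str = "none",
        collinearity_threshold: float = 0.7,
        allow_collinear: bool = False,
        zero_policy: str = "strict",
        max_iter: int = 500,
        tol: float = 1e-6,
    ):
        self.confounders = tuple(confounders)
        self.focal_trait = focal_trait
        self.attribute_interaction = attribute_interaction
        self.collinearity_threshold = collinearity_threshold
        self.allow_collinear = allow_collinear
        self.zero_policy = zero_policy
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn-style parameter plumbing ---------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "confounders": self.confounders,
            "focal_trait": self.focal_trait,
            "attribute_interaction": self.attribute_interaction,
            "collinearity_threshold": self.collinearity_threshold,
            "allow_collinear": self.allow_collinear,
            "zero_policy": self.zero_policy,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "AttributeYearModel":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for AttributeYearModel")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, community: CommunityTimeSeries, traits: TraitTable) -> "AttributeYearModel":
        if self.focal_trait in self.confounders:
            raise ValidationError("focal trait cannot also be a confounder")
        if self.attribute_interaction not in ("none", "main", "with_year"):
            raise ValueError(f"unknown attribute_interaction {self.attribute_interaction!r}")

        panel, matched, report = align(community, traits)
        if len(matched) < 2 or panel["year"].nunique() < 2:
            raise ValidationError("model needs at least 2 species and 2 census years")
        self._check_collinearity(matched)

        panel = _apply_zero_policy(panel, self.zero_policy)
        y = np.log(panel["abundance"].to_numpy())
        years = [yr for yr in community.census_years if yr in set(panel["year"])]

        coding = _make_coding(matched, self.focal_trait, self.confounders)
        species_cov = _species_covariates(matched.data, coding)
        X, labels, roles = _build_design(
            panel, years, coding, species_cov, self.attribute_interaction
        )
        self._check_rank(X, labels)

        groups = self._group_panel(panel, years, X, y)
        n, p = X.shape

        beta_ols, rss, ss_tot = self._ols(X, y)
        if rss <= 1e-12 * max(1.0, ss_tot):
            # saturated / noiseless fit: covariance parameters are not
            # identified and all BLUPs vanish
            beta, rho, gsp, gcy, sig2 = beta_ols, 0.0, 0.0, 0.0, max(rss / n, 1e-300)
            f_min = n * np.log(sig2)
            n_iter, converged = 0, True
        else:
            theta0 = self._initial_theta(groups, X, y, beta_ols)
            res = minimize(
                self._neg_profile_ll,
                theta0,
                args=(groups, n, p),
                method="Nelder-Mead",
                bounds=[(-5.0, 5.0), (-12.0, 6.0), (-12.0, 6.0)],
                options={
                    "maxiter": self.max_iter,
                    "xatol": self.tol,
                    "fatol": 1e-9,
                    "maxfev": 4 * self.max_iter,
                },
            )
            if not res.success:
                raise ConvergenceError(
                    f"covariance optimisation did not converge in {res.nit} iterations "
                    f"({res.nfev} evaluations; message: {res.message}; "
                    f"last theta={np.round(res.x, 6)})"
                )
            rho = float(np.tanh(res.x[0]))
            gsp = float(np.exp(res.x[1]))
            gcy = float(np.exp(res.x[2]))
            beta, sig2, _ = self._gls_beta(groups, rho, gsp, gcy, n)
            f_min = float(res.fun)
            n_iter, converged = int(res.nit), True

        u_sp, u_cy = self._blups(groups, beta, rho, gsp, gcy)
        # recentre to sum to zero; the intercept absorbs the intercept shift
        sp_mean = float(np.mean(list(u_sp.values())))
        u_sp = {s: v - sp_mean for s, v in u_sp.items()}
        beta = beta.copy()
        beta[0] += sp_mean
        cy_mean = float(np.mean(list(u_cy.values())))
        u_cy = {s: v - cy_mean for s, v in u_cy.items()}

        self.panel_ = panel
        self.traits_ = matched
        self.alignment_report_ = report
        self.coding_ = coding
        self.years_ = years
        self.species_ = list(matched.species)
        self.X_ = X
        self.y_ = y
        self.columns_ = labels
        self.roles_ = roles
        self.coef_ = pd.Series(beta, index=labels, name="coef")
        self.rho_ = rho
        self.sigma2_ = float(sig2)
        self.sigma2_species_ = float(gsp * sig2)
        self.sigma2_slope_ = float(gcy * sig2)
        self.species_effects_ = pd.Series(u_sp, name="Sp").reindex(self.species_)
        self.species_slopes_ = pd.Series(u_cy, name="cYear").reindex(self.species_)
        self.n_obs_ = n
        self.loglik_ = float(-0.5 * (f_min + n * np.log(2 * np.pi) + n))
        self.aic_ = float(-2 * self.loglik_ + 2 * (p + 4))
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    # -- prediction and CTI wrappers --------------------------------------
    def predict(self, mode: str = "full") -> CommunityTimeSeries:
        """Predicted abundances (natural scale) on the training panel.

        ``mode="full"`` uses every fixed effect; ``mode="temp_only"`` zeroes
        the year x confounder interaction coefficients so year-to-year change
        in the predictions is driven by temperature preference alone.  Species
        random intercepts are always added; random year slopes never are.
        """
        self._check_fitted()
        coef = self._mode_coef(mode)
        return self._predict_from(self.X_, self.panel_, coef)

    def _mode_coef(self, mode: str) -> np.ndarray:
        if mode not in ("full", "temp_only"):
            raise ValueError(f"unknown prediction mode {mode!r}")
        coef = self.coef_.to_numpy().copy()
        if mode == "temp_only":
            drop = np.array([r in _CONFOUNDER_ROLES for r in self.roles_])
            coef[drop] = 0.0
        return coef

    def _predict_from(self, X, panel, coef) -> CommunityTimeSeries:
        sp = self.species_effects_.reindex(panel["species"]).to_numpy()
        pred = np.exp(X @ coef + sp)
        out = panel.loc[:, ["species", "year"]].copy()
        out["abundance"] = pred
        return CommunityTimeSeries(out, census_years=self.years_)

    def cti(self, variant: str = "modelled") -> CTISeries:
        """CTI on model predictions: 'modelled' or 'modelled_uncorrected'."""
        mode = {"modelled": "temp_only", "modelled_uncorrected": "full"}.get(variant)
        if mode is None:
            raise ValueError(f"model produces 'modelled'/'modelled_uncorrected', not {variant!r}")
        series = cti_series(self.predict(mode), self.traits_, variant="original")
        return CTISeries(variant=variant, values=series.values)

    def randomized_attribute_cti(self, n_draws: int = 100, seed=None, return_draws=False):
        """Modelled CTI via randomized-attribute averaging.

        Instead of dropping the year x confounder coefficients, the confounder
        values entering the year-interaction terms are permuted among species
        ``n_draws`` times, full-model predictions computed for each draw and
        averaged before the CTI is calculated, which averages out any
        covariation between the confounders' year effects and the focal trait.
        Confounder *main* effects keep each species' observed value -- the
        correction deliberately retains them so the year-1 index matches the
        original CTI -- which makes this estimator agree with coefficient
        dropping up to Monte-Carlo error.
        """
        self._check_fitted()
        if n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        if not self.confounders:
            series = self.cti("modelled")
            draws = pd.DataFrame({0: series.values})
            return (series, draws) if return_draws else series

        coef = self._mode_coef("full")
        traits_df = self.traits_.data
        total = None
        draw_ctis = {}
        for d in range(int(n_draws)):
            perm = rng.permutation(len(traits_df))
            shuffled = traits_df.copy()
            shuffled[list(self.confounders)] = traits_df[list(self.confounders)].iloc[perm].to_numpy()
            species_cov = _species_covariates(shuffled, self.coding_)
            X, _, roles = _build_design(
                self.panel_, self.years_, self.coding_, species_cov, self.attribute_interaction
            )
            # species' observed confounder values stay in the retained
            # main-effect (and focal x confounder) columns
            keep = np.array([r in (_ROLE_CONF, _ROLE_ATTR_INTER) for r in roles])
            X[:, keep] = self.X_[:, keep]
            pred = self._predict_from(X, self.panel_, coef)
            draw_ctis[d] = cti_series(pred, self.traits_, variant="original").values
            mat = pred.data["abundance"].to_numpy()
            total = mat if total is None else total + mat

        avg = self.panel_.loc[:, ["species", "year"]].copy()
        avg["abundance"] = total / n_draws
        series = cti_series(
            CommunityTimeSeries(avg, census_years=self.years_), self.traits_, variant="original"
        )
        series = CTISeries(variant="modelled", values=series.values)
        if return_draws:
            return series, pd.DataFrame(draw_ctis)
        return series

    # -- internals ---------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ValidationError("model is not fitted; call fit() first")

    def _check_collinearity(self, traits: TraitTable):
        focal = (
            traits.temp_pref
            if self.focal_trait == traits.temp_col
            else traits.data[self.focal_trait]
        )
        for name in self.confounders:
            if traits.kinds.get(name) != "continuous":
                continue
            r = float(np.corrcoef(focal, traits.data[name])[0, 1])
            if abs(r) > self.collinearity_threshold and not self.allow_collinear:
                raise CollinearityError(
                    f"|r|={abs(r):.3f} between {self.focal_trait!r} and {name!r} exceeds "
                    f"{self.collinearity_threshold}; their year effects cannot be separated "
                    "(set allow_collinear=True to override)"
                )

    @staticmethod
    def _check_rank(X: np.ndarray, labels: list[str]):
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag[0] * max(X.shape) * np.finfo(float).eps
        bad = diag < tol
        if bad.any():
            aliased = [labels[piv[i]] for i in np.where(bad)[0]]
            raise RankDeficiencyError(f"design matrix rank deficient; aliased terms: {aliased}")

    @staticmethod
    def _ols(X, y):
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return beta, float(resid @ resid), float(np.sum((y - y.mean()) ** 2))

    def _group_panel(self, panel, years, X, y):
        """Group species by identical census-year pattern for batched algebra."""
        pos_of_year = {yr: i for i, yr in enumerate(years)}
        year_mid = float(np.mean(years))
        year_scale = float(np.std(years)) or 1.0
        idx = panel.reset_index(drop=True)
        groups: dict[tuple, dict] = {}
        for sp, grp in idx.groupby("species", sort=True):
            yrs = tuple(grp["year"])
            g = groups.setdefault(
                yrs,
                {
                    "pos": np.array([pos_of_year[yr] for yr in yrs]),
                    "cyear": (np.array(yrs, float) - year_mid) / year_scale,
                    "rows": [],
                    "species": [],
                },
            )
            g["rows"].append(grp.index.to_numpy())
            g["species"].append(sp)
        out = []
        for g in groups.values():
            rows = np.array(g["rows"])  # (S_g, n_g)
            out.append(
                {
                    "pos": g["pos"],
                    "cyear": g["cyear"],
                    "species": g["species"],
                    "X": X[rows],  # (S_g, n_g, p)
                    "y": y[rows],  # (S_g, n_g)
                }
            )
        return out

    @staticmethod
    def _group_W(g, rho, gsp, gcy):
        c = g["cyear"]
        W = _ar1_corr(g["pos"], rho) + gsp + gcy * np.outer(c, c)
        W[np.diag_indices_from(W)] += _JITTER
        return W

    def _gls_beta(self, groups, rho, gsp, gcy, n):
        p = groups[0]["X"].shape[2]
        A = np.zeros((p, p))
        rhs = np.zeros(p)
        yWy = 0.0
        logdet = 0.0
        Wis = []
        for g in groups:
            W = self._group_W(g, rho, gsp, gcy)
            cho = cho_factor(W, lower=True)
            Wi = cho_solve(cho, np.eye(len(W)))
            Wis.append(Wi)
            logdet += 2.0 * np.sum(np.log(np.diag(cho[0]))) * len(g["species"])
            Xg, yg = g["X"], g["y"]
            WiX = np.matmul(Wi, Xg)  # (S_g, n_g, p) batched
            A += np.tensordot(Xg, WiX, axes=([0, 1], [0, 1]))
            Wiy = yg @ Wi  # (S_g, n_g)
            rhs += np.tensordot(WiX, yg, axes=([0, 1], [0, 1]))
            yWy += float(np.sum(Wiy * yg))
        beta = np.linalg.solve(A, rhs)
        quad = max(yWy - rhs @ beta, 0.0)
        sig2 = max(quad / n, 1e-300)
        return beta, sig2, (logdet, A, Wis)

    def _neg_profile_ll(self, theta, groups, n, p):
        rho = float(np.tanh(theta[0]))
        gsp = float(np.exp(theta[1]))
        gcy = float(np.exp(theta[2]))
        try:
            _, sig2, (logdet, _, _) = self._gls_beta(groups, rho, gsp, gcy, n)
        except np.linalg.LinAlgError:
            return 1e12
        return n * np.log(sig2) + logdet

    def _initial_theta(self, groups, X, y, beta_ols):
        resid = y - X @ beta_ols
        num = den = 0.0
        means: list[float] = []
        for g in groups:
            r = g["y"] - g["X"] @ beta_ols  # (S_g, n_g)
            pos = g["pos"]
            consec = np.diff(pos) == 1
            if consec.any():
                a = r[:, :-1][:, consec]
                b = r[:, 1:][:, consec]
                num += float(np.sum(a * b))
                den += float(np.sum(a * a))
            means.extend(np.mean(r, axis=1))
        rho0 = np.clip(num / den if den > 0 else 0.0, -0.9, 0.9)
        v_within = max(float(np.var(resid)), 1e-12)
        gsp0 = np.clip(float(np.var(means)) / v_within, 1e-3, 1e3)
        return np.array([np.arctanh(rho0), np.log(gsp0), np.log(1e-3)])

    def _blups(self, groups, beta, rho, gsp, gcy):
        u_sp: dict[str, float] = {}
        u_cy: dict[str, float] = {}
        for g in groups:
            W = self._group_W(g, rho, gsp, gcy)
            Wi = np.linalg.inv(W)
            r = g["y"] - g["X"] @ beta  # (S_g, n_g)
            Wir = r @ Wi
            sp_vals = gsp * Wir.sum(axis=1)
            cy_vals = gcy * (Wir @ g["cyear"])
            for s, a, b in zip(g["species"], sp_vals, cy_vals):
                u_sp[s] = float(a)
                u_cy[s] = float(b)
        return u_sp, u_cy


# -- module-level wrappers over the estimator ------------------------------


def modelled_cti(model: AttributeYearModel) -> CTISeries:
    """CTI on temperature-only predictions (the corrected index)."""
    return model.cti("modelled")


def modelled_uncorrected_cti(model: AttributeYearModel) -> CTISeries:
    """CTI on full fixed-effect predictions (model-adequacy check)."""
    return model.cti("modelled_uncorrected")


def randomized_attribute_cti(
    model: AttributeYearModel, n_draws: int = 100, seed=None, return_draws: bool = False
):
    return model.randomized_attribute_cti(n_draws=n_draws, seed=seed, return_draws=return_draws)


def compare_interaction_models(
    community: CommunityTimeSeries, traits: TraitTable, confounders, **model_kwargs
) -> dict:
    """Screen the focal x confounder interaction by information criterion.

    Fits the attribute-year model with and without the interaction between the
    focal trait and the confounders and reports marginal-likelihood AIC for
    each, preferring the smaller (a difference below 1e-6 is reported a tie).
    """
    base = AttributeYearModel(confounders=confounders, attribute_interaction="none", **model_kwargs)
    inter = AttributeYearModel(confounders=confounders, attribute_interaction="main", **model_kwargs)
    base.fit(community, traits)
    inter.fit(community, traits)
    delta = base.aic_ - inter.aic_
    if abs(delta) < 1e-6:
        preferred = "tie"
    else:
        preferred = "interaction" if delta > 0 else "no_interaction"
    return {
        "aic_no_interaction": base.aic_,
        "aic_interaction": inter.aic_,
        "delta_aic": delta,
        "preferred": preferred,
        "models": {"no_interaction": base, "interaction": inter},
    }
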