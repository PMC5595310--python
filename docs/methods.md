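# Methods

## The index

The community temperature index (CTI) for year *t* is the community-weighted
mean of species' temperature preferences,

    CTI_t = Σ_s Temp.pref_s · w_{s,t},      w_{s,t} = N_{s,t} / Σ_s' N_{s',t},

with the presence/absence variant replacing the weights by equal weights over
the species whose abundance exceeds a presence threshold (default: any
positive abundance).  Temperature preference is treated as a fixed continuous
species trait in °C; how it was derived (range maps, climate normals) is
outside this package's scope.  Abundances are standardized so every species
has index value 100 in the base census year before any CTI is computed; this
stops initially dominant species from dominating the index and makes the
year-1 CTI equal to the unweighted mean preference for every variant.

Zero abundances: the log-scale model cannot accept zeros.  Policy is
configurable — `strict` (error, the default) or `floor` (replace zeros by
half the species' smallest positive value, with a warning).  The simulation
harness uses `floor`.

## The attribute-by-year model

On log standardized indices we fit

    log N_{s,t} = a + b_t + c·x_s + d·z_s + e_t·x_s + f_t·z_s
                  + Sp_s + u_s·cyear_t + ε_{s,t}

* year enters as a factor (`b_t`), reference-coded on the first census year,
  so the intercept is the year-1 level and every interaction coefficient is
  exactly zero in year 1 — which is what makes the modelled CTI match the
  original CTI at the base year;
* the focal trait *x* (temperature preference) and each confounder *z* enter
  as main effects and in year interactions (`e_t`, `f_t`).  Continuous
  covariates are mean-centred for conditioning; categorical confounders are
  reference-coded with the alphabetically first level as reference;
* `Sp_s` are species random intercepts and `u_s` random slopes on continuous
  (standardized) year, each recentred to sum to zero after estimation (the
  intercept absorbs the recentring shift);
* ε follows an AR(1) process with coefficient ρ within species across
  *consecutive* census years; a missing census year breaks the run and
  observations across the gap are treated as independent.

**Estimation.**  Deterministic profile maximum likelihood.  Given
θ = (atanh ρ, log γ_sp, log γ_cy), where γ are variance ratios against the
residual variance, the GLS fixed effects, the profiled residual variance and
the deviance have closed forms via the species-block covariance
W = R(ρ) + γ_sp·J + γ_cy·cc′ (+10⁻⁸·I for conditioning); species sharing a
census pattern share one Cholesky factorisation, so a 50×20 panel evaluates
in well under a millisecond.  θ is minimised with bounded Nelder–Mead
(bounds ±5 on atanh ρ, [−12, 6] on the log ratios; defaults `tol=1e-6`,
`max_iter=500`; non-convergence raises with the iteration trace).  BLUPs are
u = γ Z′W⁻¹r.  We chose direct likelihood optimisation over an alternating
fixed-point scheme (fit effects given ρ, re-estimate ρ from lag-1 residuals)
because it is guaranteed-descent, equally deterministic, and converges on
panels where the fixed point oscillates.  When the fit is saturated and
noiseless (residual SS ≤ 10⁻¹² of total SS) the covariance parameters are
unidentified; we short-circuit to the OLS solution with ρ = 0 and zero BLUPs,
which keeps noiseless coefficient recovery exact to solver precision.

A collinearity guard refuses to fit when |r| between the focal trait and a
continuous confounder exceeds 0.7 (configurable, over-ridable): beyond that,
the year effects of the two traits cannot be meaningfully separated.  The
simulation harness overrides the guard, since at r = −0.6 and 50 species the
*sample* correlation exceeds 0.7 by chance in roughly one replicate in eight
and the guard is a real-data safety rail, not part of the study conditions.

**Prediction and the corrected index.**  Predictions are fixed effects plus
species random intercepts, exponentiated to the natural scale (plain
exponential, no smearing correction — both modelled and modelled-uncorrected
CTIs back-transform identically, so retransformation bias cancels in the
comparison).  Random year slopes are excluded from every prediction: they
carry trend variation not attributed to any trait, and including them would
reintroduce exactly what the correction removes.  `temp_only` mode zeroes the
year×confounder (and any year×focal×confounder) coefficients while keeping
all main effects; the modelled CTI is the CTI of those predictions.  Main
effects are retained so the year-1 prediction, and hence the year-1 CTI,
matches the original index; their removal would only shift species' constant
levels.

**Randomized-attribute estimator.**  As a cross-check, the modelled CTI can
be computed by averaging full-model predictions over permutations of the
confounder values among species (permutation preserves the attributes' joint
marginal distribution; 100 draws by default, seeded).  The permutation is
applied to the values entering the *year-interaction* columns only: each
species keeps its observed confounder value in the retained main-effect
columns, mirroring the coefficient-dropping definition above.  With that
convention the two estimators target the same quantity and agree within
Monte-Carlo error; permuting the main effects too would introduce a
systematic offset through the species-specific constant factors that the
correction deliberately retains.

**Interaction screening.**  `compare_interaction_models` fits the model with
and without focal×confounder interaction terms and compares marginal
maximum-likelihood AIC (k = p fixed effects + 4 covariance parameters),
preferring the smaller value.  An information criterion on the marginal
likelihood is the natural frequentist analogue of posterior-predictive
criteria used for the same screening task in Bayesian fits.

## The simulator

`simulate_traits` draws temperature preference and habitat breadth from a
bivariate normal with standard-normal marginals and correlation r (Cholesky
construction, so r = ±1 degenerates exactly).  Trait effects are therefore in
units of trait standard deviations.

`simulate_community` builds the deterministic skeleton

    log N_{s,t} = log N0 + t·(b_temp·temp_s + b_hab·habitat_s),   t = 0..T−1,

(N0 = 100) and draws observations around it: `poisson` — Poisson counts with
the skeleton mean (so zeros are possible but not absorbing, and the sample
mean of repeated draws equals the deterministic expectation);
`overdispersion` — a normal deviate with sd = 2·|b_temp| added on the log
scale before the Poisson draw; `measure_temp` / `measure_both` — Poisson
dynamics, but the *analyst's* trait table is perturbed once per replicate by
additive normal error with σ_e = σ·sqrt(1/r_m² − 1), giving
cor(measured, actual) = r_m = 0.7 by default.  The generator always uses the
actual traits.  Expected log abundances beyond ±log 10¹² raise an error
advising smaller effects or a shorter horizon.

Defaults are the headline study conditions: 50 species, 20 years,
b_temp = b_habitat = 0.05 per year per trait SD, 500 replicates.  The 0.05
effect is our own calibration — over 19 years it multiplies a +2 SD species'
expected abundance by e^1.9 ≈ 6.7, a realistic range for multi-decade
monitoring series — and the bias grid sweeps it.  The "true CTI" is the
original CTI of a companion community simulated from the same traits with
the habitat effect forced to zero (Poisson error), i.e. the index that
results when temperature alone drives the dynamics.

`run_scenario` repeats: draw traits → simulate observed and true communities
→ standardize → original and true CTI → fit the analyst model on the
(possibly mis-measured) traits → modelled CTI.  Bias summaries are per-year
means and percentile (2.5/97.5%) intervals of (variant − true) across
replicates.  Replicate-level fit failures are excluded and counted; more
than 20% aborts the scenario.  All randomness flows from one seed through
spawned child sequences, so every operation is a pure function of
(config, seed).  `bias_grid` sweeps trait correlation, effect size and
community size using original-vs-true bias only (no model fits);
`robustness_suite` re-runs the confounded scenario with a superfluous 3-way
year×temperature×habitat interaction and with an extra pure-noise predictor
in the analyst's model.

What the simulator does *not* emulate: density dependence, species
interactions, observation effort variation, immigration/extinction dynamics,
and non-stationary trait effects.  Passing tests therefore show that the
correction removes confounder-driven bias under log-linear trait-driven
dynamics with the stated error structures — not that it is robust to every
failure mode of real survey data.

## Diagnostics

* `covariation_test` — one-way ANOVA of the focal trait across the levels of
  a categorical attribute (all pairwise mean contrasts are computed and the
  largest flagged), or the regression F test plus Pearson r for a continuous
  attribute.
* `trend_test` — one joint regression of log abundance on continuous year,
  all attribute main effects and attribute×year interactions, with AR(1)
  errors fitted by iterated Prais–Winsten GLS (ρ from lag-1 residuals of
  consecutive census years within species, iterated to 10⁻⁸).  Estimates and
  SEs are reported per calendar year; 95% CIs use the ±1.96·SE convention.
* `quartile_mechanism` — species ranked by temperature preference (ties
  broken by species id; stable sort), upper and lower groups of ⌈n/4⌉
  species, per-year geometric-mean abundance per group.  Standardized
  indices are the intended input (they guarantee positivity).
* `loess_trend` — local polynomial regression with tricube weights over the
  nearest ⌊span·n⌋ points (defaults span 0.75, degree 2, no robustness
  iterations, matching R's `loess` with `surface="direct"`, against which
  the implementation is cross-checked to 10⁻⁶).  The pointwise band is
  fit ± 1.96·SE with the residual variance estimated on the smoother's
  residual degrees of freedom (n − 2ν₁ + ν₂); a degree-d fit reproduces any
  polynomial of degree ≤ d exactly.  Bands are pointwise, not simultaneous.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run the study at 100 replicates
for the scenario comparisons, 200 for the bias grid and the calibration
experiments, and single replicates for the oracle-equivalence and exactness
checks — sizes at which every qualitative conclusion of the full 500-replicate
design is already stable, chosen so a complete validation run finishes in a
few minutes on one CPU.

## Known limitations

* The fit is marginal ML, not REML; variance components are mildly biased
  downward in small panels (the package's contracts are on predictions,
  which are insensitive to this).
* AR(1) correlation is not propagated across census gaps (no ρ^gap).
* No uncertainty intervals on the modelled CTI itself (a bootstrap is an
  extension point, not implemented).
* The heteroscedasticity of Poisson counts on the log scale is approximated
  by a homoscedastic residual; at index values near zero the floor policy
  interacts with this approximation.
* Other community-weighted means (specialization, nutrient preference) share
  the same mathematics and could reuse the machinery, but only the
  temperature index is exposed.
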