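import numpy as np
import pandas as pd
import pytest

from ctikit import (
    AttributeYearModel,
    CollinearityError,
    RankDeficiencyError,
    SimulationConfig,
    TraitTable,
    ValidationError,
    compare_interaction_models,
    cti_series,
    modelled_cti,
    modelled_uncorrected_cti,
    simulate_community,
    simulate_traits,
    standardize_to_index,
)

from conftest import make_ar1_panel, make_noiseless_panel


@pytest.fixture(scope="module")
def noiseless_fit():
    comm, traits = make_noiseless_panel(b=0.04)
    model = AttributeYearModel(confounders=["habitat_breadth"]).fit(comm, traits)
    return comm, traits, model


@pytest.fixture(scope="module")
def covaried_fit():
    """One replicate of the confounded scenario with a fitted analyst model."""
    cfg = SimulationConfig(n_reps=1, seed=5, trait_correlation=-0.6)
    rng = np.random.default_rng(11)
    traits = simulate_traits(50, -0.6, rng)
    idx = standardize_to_index(simulate_community(traits, cfg, rng=rng), zero_policy="floor")
    model = AttributeYearModel(
        confounders=["habitat_breadth"], zero_policy="floor", allow_collinear=True
    ).fit(idx, traits)
    return idx, traits, model


class TestFit:
    def test_noiseless_recovery_of_year_interactions(self, noiseless_fit):
        _, _, model = noiseless_fit
        cols = [c for c in model.columns_ if c.startswith("year[") and c.endswith(":temp_pref")]
        fitted = model.coef_[cols].to_numpy()
        assert np.allclose(fitted, 0.04 * np.arange(1, 6), atol=1e-6)

    def test_random_effects_sum_to_zero(self, covaried_fit):
        _, _, model = covaried_fit
        assert model.species_effects_.sum() == pytest.approx(0.0, abs=1e-9)
        assert model.species_slopes_.sum() == pytest.approx(0.0, abs=1e-9)

    def test_rho_strictly_inside_unit_interval(self, covaried_fit):
        _, _, model = covaried_fit
        assert -1 < model.rho_ < 1

    def test_ar1_rho_recovery(self):
        comm, traits = make_ar1_panel(rho=0.5, seed=0)
        model = AttributeYearModel().fit(comm, traits)
        assert model.rho_ == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_data(self, covaried_fit):
        idx, traits, model = covaried_fit
        again = AttributeYearModel(
            confounders=["habitat_breadth"], zero_policy="floor", allow_collinear=True
        ).fit(idx, traits)
        assert np.array_equal(again.coef_.to_numpy(), model.coef_.to_numpy())
        assert again.rho_ == model.rho_

    def test_collinearity_guard(self, rng):
        temp = rng.standard_normal(30)
        traits = TraitTable(
            pd.DataFrame(
                {
                    "species": [f"s{i:02d}" for i in range(30)],
                    "temp_pref": temp,
                    "habitat_breadth": 0.95 * temp + 0.05 * rng.standard_normal(30),
                }
            )
        )
        cfg = SimulationConfig(n_species=30, n_years=5, n_reps=1)
        comm = simulate_community(traits, cfg, rng=rng)
        idx = standardize_to_index(comm, zero_policy="floor")
        with pytest.raises(CollinearityError, match=r"\|r\|"):
            AttributeYearModel(confounders=["habitat_breadth"]).fit(idx, traits)
        # override fits fine
        AttributeYearModel(confounders=["habitat_breadth"], allow_collinear=True).fit(idx, traits)

    def test_rank_deficiency_names_aliased_terms(self):
        comm, traits = make_noiseless_panel(n_species=8, n_years=4)
        dup = TraitTable(
            traits.data.assign(habitat_breadth=traits.data["temp_pref"]),
            kinds=traits.kinds,
        )
        with pytest.raises(RankDeficiencyError, match="aliased"):
            AttributeYearModel(confounders=["habitat_breadth"], allow_collinear=True).fit(
                comm, dup
            )

    def test_focal_cannot_be_confounder(self, noiseless_fit):
        comm, traits, _ = noiseless_fit
        with pytest.raises(ValidationError):
            AttributeYearModel(confounders=["temp_pref"]).fit(comm, traits)

    def test_get_set_params_roundtrip(self):
        model = AttributeYearModel(confounders=["x"], tol=1e-7)
        params = model.get_params()
        clone = AttributeYearModel().set_params(**params)
        assert clone.get_params() == params


class TestPredict:
    def test_full_mode_reproduces_noiseless_data(self, noiseless_fit):
        comm, _, model = noiseless_fit
        pred = model.predict("full")
        merged = comm.data.merge(pred.data, on=["species", "year"], suffixes=("", "_hat"))
        assert np.allclose(merged["abundance"], merged["abundance_hat"], rtol=1e-8)

    def test_modes_identical_when_confounder_interactions_zero(self, noiseless_fit):
        # generating process has no habitat effect, so the fitted confounder
        # year-interaction coefficients vanish and the modes coincide
        _, _, model = noiseless_fit
        full = model.predict("full").data["abundance"].to_numpy()
        temp_only = model.predict("temp_only").data["abundance"].to_numpy()
        assert np.allclose(full, temp_only, rtol=1e-8)

    def test_temp_only_within_species_ratios_unchanged_by_confounders(self, covaried_fit):
        # confounder main effects shift species levels; year-to-year ratios
        # within a species must depend only on year and temperature terms
        _, traits, model = covaried_fit
        pred = model.predict("temp_only").to_matrix()
        ratios = np.log(pred.to_numpy()[:, 1:] / pred.to_numpy()[:, :-1])
        temp = traits.temp_pref.reindex(pred.index).to_numpy()
        temp_c = temp - model.coding_.focal_mean
        for j in range(ratios.shape[1]):
            design = np.column_stack([np.ones_like(temp_c), temp_c])
            resid = ratios[:, j] - design @ np.linalg.lstsq(design, ratios[:, j], rcond=None)[0]
            assert np.abs(resid).max() < 1e-10


class TestModelledCTI:
    def test_uncorrected_equals_original_for_saturated_noiseless_fit(self, noiseless_fit):
        comm, traits, model = noiseless_fit
        orig = cti_series(comm, traits).values
        uncorr = modelled_uncorrected_cti(model).values
        assert np.allclose(orig, uncorr, atol=1e-8)

    def test_modelled_equals_uncorrected_when_no_confounder_effect(self, noiseless_fit):
        _, _, model = noiseless_fit
        assert np.allclose(
            modelled_cti(model).values, modelled_uncorrected_cti(model).values, atol=1e-10
        )

    def test_base_year_matches_original(self, covaried_fit):
        idx, traits, model = covaried_fit
        orig = cti_series(idx, traits).values
        assert modelled_cti(model).values.iloc[0] == pytest.approx(orig.iloc[0], abs=0.05)

    def test_uncorrected_tracks_original_better_than_shuffled(self, covaried_fit):
        idx, traits, model = covaried_fit
        orig = cti_series(idx, traits).values.to_numpy()
        uncorr = modelled_uncorrected_cti(model).values.to_numpy()
        r = np.corrcoef(orig, uncorr)[0, 1]
        shuffled = np.corrcoef(orig, np.roll(uncorr, len(uncorr) // 2))[0, 1]
        assert r > shuffled

    def test_variant_tags(self, covaried_fit):
        _, _, model = covaried_fit
        assert modelled_cti(model).variant == "modelled"
        assert modelled_uncorrected_cti(model).variant == "modelled_uncorrected"


class TestRandomizedAttributeCTI:
    def test_reproducible_given_seed(self, covaried_fit):
        _, _, model = covaried_fit
        a = model.randomized_attribute_cti(n_draws=5, seed=42).values
        b = model.randomized_attribute_cti(n_draws=5, seed=42).values
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_equals_modelled_when_no_confounders(self):
        comm, traits = make_noiseless_panel()
        only_temp = TraitTable(traits.data.drop(columns=["habitat_breadth"]))
        model = AttributeYearModel().fit(comm, only_temp)
        rand = model.randomized_attribute_cti(n_draws=3, seed=0).values
        assert np.allclose(rand, modelled_cti(model).values)

    def test_draw_variance_shrinks_with_draws(self, covaried_fit):
        _, _, model = covaried_fit
        drop = modelled_cti(model).values
        few = model.randomized_attribute_cti(n_draws=2, seed=3).values
        many = model.randomized_attribute_cti(n_draws=50, seed=3).values
        assert np.abs(many - drop).mean() < np.abs(few - drop).mean()

    def test_n_draws_validated(self, covaried_fit):
        _, _, model = covaried_fit
        with pytest.raises(ValidationError):
            model.randomized_attribute_cti(n_draws=0)


class TestModelComparison:
    def test_identical_models_tie(self):
        # no confounders: the interaction adds no columns, models coincide
        comm, traits = make_noiseless_panel()
        only_temp = TraitTable(traits.data.drop(columns=["habitat_breadth"]))
        report = compare_interaction_models(comm, only_temp, confounders=[])
        assert report["preferred"] == "tie"

    def test_strong_true_interaction_preferred(self, rng):
        n_species, n_years = 40, 12
        temp = rng.standard_normal(n_species)
        hab = rng.standard_normal(n_species)
        rows = []
        for s in range(n_species):
            for t in range(n_years):
                logn = (
                    np.log(100.0)
                    + 0.02 * t * temp[s]
                    + 0.3 * temp[s] * hab[s]
                    + rng.normal(0, 0.05)
                )
                rows.append((f"s{s:02d}", t + 1, float(np.exp(logn))))
        comm = pd.DataFrame(rows, columns=["species", "year", "abundance"])
        from ctikit import CommunityTimeSeries

        comm = CommunityTimeSeries(comm)
        traits = TraitTable(
            pd.DataFrame(
                {
                    "species": [f"s{s:02d}" for s in range(n_species)],
                    "temp_pref": temp,
                    "habitat_breadth": hab,
                }
            )
        )
        report = compare_interaction_models(comm, traits, confounders=["habitat_breadth"])
        assert report["preferred"] == "interaction"

    def test_no_interaction_preferred_without_one(self):
        cfg = SimulationConfig(n_reps=1, seed=9, trait_correlation=0.0)
        rng = np.random.default_rng(9)
        traits = simulate_traits(40, 0.0, rng)
        idx = standardize_to_index(simulate_community(traits, cfg, rng=rng), zero_policy="floor")
        report = compare_interaction_models(
            idx, traits, confounders=["habitat_breadth"], zero_policy="floor"
        )
        assert report["preferred"] == "no_interaction"
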