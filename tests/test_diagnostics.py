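import subprocess

import numpy as np
import pandas as pd
import pytest

from ctikit import (
    CommunityTimeSeries,
    TraitTable,
    ValidationError,
    covariation_test,
    loess_trend,
    quartile_mechanism,
    trend_test,
)

from conftest import make_ar1_panel, make_noiseless_panel


def traits_with_groups(values, groups, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return TraitTable(
        pd.DataFrame({"species": ids, "temp_pref": values, "group": groups})
    )


class TestCovariationTest:
    def test_null_case_equal_group_means(self):
        tt = traits_with_groups([4.0, 5.0, 6.0, 4.0, 5.0, 6.0], ["x"] * 3 + ["y"] * 3)
        res = covariation_test(tt, other="group")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_anova(self):
        # groups {1,2,3} and {4,5,6}: SSB=13.5 on 1 df, MSW=1 on 4 df -> F=13.5
        tt = traits_with_groups([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], ["x"] * 3 + ["y"] * 3)
        res = covariation_test(tt, other="group")
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_largest_contrast_flagged(self):
        tt = traits_with_groups(
            [1.0, 1.0, 3.0, 3.0, 9.0, 9.0], ["a", "a", "b", "b", "c", "c"]
        )
        res = covariation_test(tt, other="group")
        assert set(res.largest_contrast[:2]) == {"a", "c"}
        assert abs(res.largest_contrast[2]) == pytest.approx(8.0)

    def test_continuous_self_correlation_is_one(self):
        tt = TraitTable(
            pd.DataFrame({"species": ["a", "b", "c"], "temp_pref": [1.0, 2.0, 4.0],
                          "size": [1.0, 2.0, 4.0]})
        )
        res = covariation_test(tt, other="size")
        assert res.pearson_r == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        tt = traits_with_groups([2.0, 2.0, 2.0, 2.0], ["x", "x", "y", "y"])
        with pytest.raises(ValidationError, match="zero variance"):
            covariation_test(tt, other="group")

    def test_small_level_warns(self):
        tt = traits_with_groups([1.0, 2.0, 3.0], ["x", "x", "y"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            covariation_test(tt, other="group")


class TestTrendTest:
    def test_noiseless_interaction_recovery(self):
        comm, traits = make_noiseless_panel(n_species=12, n_years=8, b=0.01)
        res = trend_test(comm, traits, attributes=["temp_pref"])
        row = res.table[res.table["term"] == "temp_pref:cyear"].iloc[0]
        assert row["estimate"] == pytest.approx(0.01, abs=1e-8)
        assert row["se"] == pytest.approx(0.0, abs=1e-8)

    def test_ar1_rho_estimated(self):
        comm, traits = make_ar1_panel(rho=0.5, seed=1)
        res = trend_test(comm, traits, attributes=["temp_pref"])
        assert res.rho == pytest.approx(0.5, abs=0.15)

    def test_permuted_years_centre_interaction_on_zero(self):
        comm, traits = make_ar1_panel(n_species=30, n_years=15, rho=0.3, slope=0.02, seed=2)
        ests = []
        rng = np.random.default_rng(3)
        for _ in range(30):
            df = comm.data.copy()
            year_map = dict(zip(comm.years, rng.permutation(comm.years)))
            df["year"] = df["year"].map(year_map)
            permuted = CommunityTimeSeries(df)
            res = trend_test(permuted, traits, attributes=["temp_pref"])
            ests.append(res.table.set_index("term").loc["temp_pref:cyear", "estimate"])
        assert abs(np.mean(ests)) < 3 * np.std(ests) / np.sqrt(len(ests)) + 0.002

    def test_ci_convention(self):
        comm, traits = make_ar1_panel(n_species=20, n_years=10, seed=4)
        res = trend_test(comm, traits)
        assert np.allclose(res.table["lo"], res.table["estimate"] - 1.96 * res.table["se"])
        assert (res.table["lo"] <= res.table["hi"]).all()


class TestQuartileMechanism:
    @staticmethod
    def _community(values_by_species, years):
        rows = [
            (sp, yr, v)
            for sp, vals in values_by_species.items()
            for yr, v in zip(years, vals)
        ]
        return CommunityTimeSeries(pd.DataFrame(rows, columns=["species", "year", "abundance"]))

    def test_four_species_single_member_groups(self):
        comm = self._community(
            {"a": [1.0, 2.0], "b": [3.0, 3.0], "c": [5.0, 5.0], "d": [7.0, 8.0]}, [1, 2]
        )
        tt = TraitTable(
            pd.DataFrame({"species": list("abcd"), "temp_pref": [1.0, 2.0, 3.0, 4.0]})
        )
        qt = quartile_mechanism(comm, tt)
        assert qt.lower_species == ["a"] and qt.upper_species == ["d"]
        assert list(qt.upper) == pytest.approx([7.0, 8.0])

    def test_geometric_mean_of_4_and_9_is_6(self):
        comm = self._community(
            {"a": [4.0], "b": [9.0], "c": [1.0], "d": [1.0], "e": [1.0], "f": [1.0],
             "g": [1.0], "h": [1.0]}, [1]
        )
        tt = TraitTable(
            pd.DataFrame({"species": list("abcdefgh"),
                          "temp_pref": [9.0, 8.0, 5.0, 5.0, 5.0, 5.0, 1.0, 2.0]})
        )
        qt = quartile_mechanism(comm, tt)
        assert sorted(qt.upper_species) == ["a", "b"]
        assert qt.upper.iloc[0] == pytest.approx(6.0)

    def test_constant_series_flat_and_am_gm(self, rng):
        years = list(range(1, 6))
        vals = {f"s{i}": [float(v)] * 5 for i, v in enumerate(rng.uniform(1, 10, 8))}
        comm = self._community(vals, years)
        tt = TraitTable(
            pd.DataFrame({"species": list(vals), "temp_pref": rng.normal(size=8)})
        )
        qt = quartile_mechanism(comm, tt)
        assert qt.upper.nunique() == 1 and qt.lower.nunique() == 1
        # AM-GM: geometric mean never exceeds the arithmetic mean
        sub = comm.data[comm.data["species"].isin(qt.upper_species)]
        am = sub.groupby("year")["abundance"].mean()
        assert ((qt.upper - am) <= 1e-9).all()

    def test_too_few_species(self):
        comm = self._community({"a": [1.0], "b": [1.0], "c": [1.0]}, [1])
        tt = TraitTable(pd.DataFrame({"species": list("abc"), "temp_pref": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValidationError, match="at least 4"):
            quartile_mechanism(comm, tt)


class TestLoess:
    def test_reproduces_polynomials_up_to_degree(self):
        x = np.arange(2000, 2020)
        for degree in (1, 2):
            coefs = [1.0, -0.3, 0.01][: degree + 1]
            y = sum(c * (x - 2010.0) ** k for k, c in enumerate(coefs))
            out = loess_trend(pd.Series(y, index=x), span=0.6, degree=degree)
            assert np.abs(out["fit"].to_numpy() - y).max() < 1e-8

    def test_constant_series_zero_width_band(self):
        x = np.arange(1, 11)
        out = loess_trend(pd.Series(5.0, index=x), span=0.75, degree=2)
        assert np.allclose(out["fit"], 5.0)
        assert np.allclose(out["se"], 0.0, atol=1e-8)

    def test_matches_r_loess_on_noisy_quadratic(self):
        rng = np.random.default_rng(7)
        x = np.arange(1990, 2015)
        y = 0.002 * (x - 2000.0) ** 2 + 0.01 * (x - 2000.0) + rng.normal(0, 0.3, len(x))
        ours = loess_trend(pd.Series(y, index=x), span=0.75, degree=2)["fit"].to_numpy()
        rcode = (
            "x <- c(%s); y <- c(%s); "
            "fit <- loess(y ~ x, span=0.75, degree=2, surface='direct', family='gaussian'); "
            "cat(sprintf('%%.12f\\n', predict(fit)))"
            % (",".join(map(str, x)), ",".join("%.17g" % v for v in y))
        )
        proc = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        theirs = np.array([float(v) for v in proc.stdout.split()])
        assert np.abs(ours - theirs).max() < 1e-6

    def test_too_few_points_and_bad_span(self):
        with pytest.raises(ValidationError):
            loess_trend(pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3]))
        x = np.arange(10)
        with pytest.raises(ValidationError):
            loess_trend(pd.Series(x, index=x, dtype=float), span=1.5)
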