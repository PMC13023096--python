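"""Tornado analysis, probabilistic stress testing, key-driver regression."""

import numpy as np
import pandas as pd
import pytest

from stemboost import (
    DsaGrid,
    ParameterError,
    PsaRanges,
    key_driver_regression,
    run_dsa,
    run_psa,
)


@pytest.fixture(scope="module")
def results(noboost_params, boost_params, costs):
    return run_dsa(noboost_params, boost_params, costs)


class TestDsa:
    def test_reserve_cost_range_is_exact(self, results):
        """Incremental cost is linear in the reserve cost: range $4,000."""
        r = next(x for x in results if x.parameter == "reserve_collection_cost_usd")
        assert r.absolute_range == pytest.approx(4_000.0)

    def test_hospitalization_cost_range_is_exact(self, results):
        """(390 / 10,000) x $8,000 = $312."""
        r = next(x for x in results if x.parameter == "hospitalization_cost_usd")
        assert r.absolute_range == pytest.approx(312.0)

    def test_split_ranges(self, results):
        """Each infection-split arm swings 0.26 x 0.10 x $64,012 = $1,664.31."""
        for name in ("noboost_neutropenia_split", "boost_neutropenia_split"):
            r = next(x for x in results if x.parameter == name)
            assert r.absolute_range == pytest.approx(0.26 * 0.10 * 64_012)

    def test_boost_costlier_across_entire_grid(self, results):
        assert all(r.positive_throughout for r in results)

    def test_tornado_sorted_descending_with_alphabetical_ties(self, results):
        ranges = [r.absolute_range for r in results]
        assert ranges == sorted(ranges, reverse=True)
        # the two split groups tie exactly; alphabetical order breaks the tie
        tied = [r.parameter for r in results if r.absolute_range == pytest.approx(
            0.26 * 0.10 * 64_012)]
        assert tied == sorted(tied)

    def test_degenerate_grid_gives_zero_ranges(
        self, noboost_params, boost_params, costs
    ):
        grid = DsaGrid(
            noboost_splits=((0.75, 0.25),),
            boost_splits=((0.90, 0.10),),
            hospitalization_costs=(64_012.0,),
            reserve_costs=(17_918.0,),
        )
        results = run_dsa(noboost_params, boost_params, costs, grid=grid)
        assert all(r.absolute_range == 0.0 for r in results)

    def test_non_complementary_split_rejected(self):
        with pytest.raises(ParameterError, match="not complementary"):
            DsaGrid(noboost_splits=((0.70, 0.25),))


class TestPsa:
    def test_base_case_conclusion_holds_in_over_95_percent_of_draws(self):
        """500 uniform draws over the stress ranges: boosting costs more in
        >95% of scenarios."""
        res = run_psa(n_draws=500, seed=101)
        assert res.fraction_positive_incremental > 0.95

    def test_draws_respect_declared_ranges(self):
        res = run_psa(n_draws=200, seed=5)
        ranges = PsaRanges()
        for name in (
            "noboost_recovery", "noboost_infection", "boost_recovery",
            "boost_infection", "hospitalization_cost", "reserve_cost",
        ):
            lo, hi = getattr(ranges, name)
            col = res.draws[name]
            assert (col >= lo).all() and (col <= hi).all()

    def test_collapsed_ranges_reproduce_base_case(self):
        """Zero-width ranges at base-case values give the base incremental."""
        point = PsaRanges(
            noboost_recovery=(0.75, 0.75),
            noboost_infection=(0.25, 0.25),
            boost_recovery=(0.90, 0.90),
            boost_infection=(0.10, 0.10),
            hospitalization_cost=(64_012.0, 64_012.0),
            reserve_cost=(17_918.0, 17_918.0),
        )
        res = run_psa(ranges=point, n_draws=20, seed=3)
        assert np.allclose(res.draws["incremental_cost"], 15_421.532)

    def test_seeded_reproducibility(self):
        a = run_psa(n_draws=50, seed=17)
        b = run_psa(n_draws=50, seed=17)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_fraction_positive_stable_across_seeds(self):
        fracs = [run_psa(n_draws=500, seed=s).fraction_positive_incremental
                 for s in (1, 2)]
        assert max(fracs) - min(fracs) <= 2 / 500

    def test_degenerate_range_rejected(self):
        with pytest.raises(ParameterError, match="degenerate range"):
            PsaRanges(reserve_cost=(22_000.0, 14_000.0))


class TestKeyDriverRegression:
    @staticmethod
    def _draws_varying(param, values):
        """Targeted draw set: one parameter varies, the rest sit at base."""
        base = {
            "noboost_recovery": 0.75,
            "noboost_infection": 0.25,
            "boost_recovery": 0.90,
            "boost_infection": 0.10,
            "hospitalization_cost": 64_012.0,
            "reserve_cost": 17_918.0,
        }
        rows = []
        for v in values:
            d = dict(base)
            d[param] = v
            # savings (no-boost minus boost) at base-case structure
            infections_nb = 0.26 * d["noboost_infection"]
            infections_b = 0.26 * d["boost_infection"]
            savings = (
                (infections_nb - infections_b) * d["hospitalization_cost"]
                - d["reserve_cost"]
            )
            rows.append({**d, "cost_savings": savings})
        return pd.DataFrame(rows)

    def test_hospitalization_cost_slope_is_averted_fraction(self):
        """Savings rise by (650-260)/10,000 = 0.039 per hospitalization dollar."""
        draws = self._draws_varying(
            "hospitalization_cost", np.linspace(50_000, 70_000, 12)
        )
        table = key_driver_regression(draws)
        coef = table.set_index("parameter").loc["hospitalization_cost", "coefficient"]
        assert coef == pytest.approx(0.039, abs=1e-9)

    def test_reserve_cost_slope_is_minus_one(self):
        draws = self._draws_varying("reserve_cost", np.linspace(14_000, 22_000, 12))
        table = key_driver_regression(draws)
        coef = table.set_index("parameter").loc["reserve_cost", "coefficient"]
        assert coef == pytest.approx(-1.0, abs=1e-9)

    def test_signs_on_real_psa_draws(self):
        res = run_psa(n_draws=300, seed=23)
        table = key_driver_regression(res.draws).set_index("parameter")
        assert table.loc["hospitalization_cost", "coefficient"] > 0
        assert table.loc["reserve_cost", "coefficient"] < 0
        assert table.loc["noboost_infection", "coefficient"] > 0
        assert (table["rank"].sort_values().values == np.arange(1, 7)).all()

    def test_constant_parameters_dropped_with_warning(self, caplog):
        draws = self._draws_varying("reserve_cost", np.linspace(14_000, 22_000, 12))
        with caplog.at_level("WARNING"):
            table = key_driver_regression(draws)
        assert "constant parameter" in caplog.text
        assert list(table["parameter"]) == ["reserve_cost"]

    def test_fully_constant_design_refused(self):
        draws = self._draws_varying("reserve_cost", [17_918.0] * 10)
        with pytest.raises(ValueError, match="at least one varying parameter"):
            key_driver_regression(draws)


def test_figures_render(tmp_path, noboost_params, boost_params, costs):
    from stemboost.sensitivity import psa_histogram, tornado_figure

    results = run_dsa(noboost_params, boost_params, costs)
    tornado_figure(results, tmp_path / "tornado.png")
    psa = run_psa(n_draws=20, seed=1)
    psa_histogram(psa, tmp_path / "hist.png")
    assert (tmp_path / "tornado.png").stat().st_size > 0
    assert (tmp_path / "hist.png").stat().st_size > 0
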