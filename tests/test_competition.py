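"""Growth-advantage inference and assay calculators."""

import numpy as np
import pandas as pd
import pytest

import airwaycomp as aw


def analytic_obs(td_a, td_b, x_days, orientation="color1", feeder=0.0, n0_ratio=1.0,
                 **kwargs):
    par = aw.CoculturePar(
        td_a=td_a, td_b=td_b, n0_ratio=n0_ratio, feeder_fraction=feeder,
        duration_days=x_days, events=None,
    )
    return aw.simulate_coculture(par, orientation=orientation, **kwargs)


class TestRatioChange:
    def test_unchanged_ratio_gives_unity(self):
        obs = aw.CocultureObservation(
            "w", "color1", 0, 7, 50, 50, 0, 50, 50, 0
        )
        assert aw.ratio_change(obs) == pytest.approx(1.0)

    def test_feeder_events_excluded(self):
        obs = aw.CocultureObservation(
            "w", "color1", 0, 7, 50, 50, 0, 80, 10, 10
        )
        assert aw.ratio_change(obs) == pytest.approx(8.0)

    def test_varying_feeder_fraction_is_invisible(self):
        # true labeled ratio constant, feeder 10% at t0 vs 60% at tX
        obs = aw.CocultureObservation(
            "w", "color1", 0, 7, 45, 45, 10, 20, 20, 60
        )
        assert aw.ratio_change(obs) == pytest.approx(1.0)

    def test_extinct_color_rejected(self):
        obs = aw.CocultureObservation(
            "w", "color1", 0, 7, 50, 50, 0, 90, 0, 10
        )
        with pytest.raises(ValueError, match="extinct or unlabeled"):
            aw.ratio_change(obs)

    def test_fraction_scale_input_rejected_without_flag(self):
        obs = aw.CocultureObservation(
            "w", "color1", 0, 7, 0.5, 0.5, 0, 0.8, 0.1, 0.1
        )
        with pytest.raises(ValueError, match="fraction"):
            aw.ratio_change(obs)
        assert aw.ratio_change(obs, allow_fraction_scale=True) == pytest.approx(8.0)


class TestDoublingTime:
    def test_single_passage(self):
        curve = aw.DoublingCurve(
            pd.DataFrame({"passage": [1], "days": [3.0], "seeded": [1e5], "harvested": [8e5]})
        )
        assert aw.doubling_time(curve) == pytest.approx(1.0, abs=1e-12)

    def test_two_identical_passages_same_td(self):
        one = aw.DoublingCurve(
            pd.DataFrame({"passage": [1], "days": [3.0], "seeded": [1e5], "harvested": [8e5]})
        )
        two = aw.DoublingCurve(
            pd.DataFrame(
                {"passage": [1, 2], "days": [3.0, 6.0], "seeded": [1e5] * 2,
                 "harvested": [8e5] * 2}
            )
        )
        assert aw.doubling_time(two) == pytest.approx(aw.doubling_time(one), abs=1e-12)

    def test_endpoint_mode_matches_on_noiseless_data(self):
        curve = aw.simulate_doubling_curve(2.2, 5, 3.0, 1e5)
        assert aw.doubling_time(curve, mode="endpoint") == pytest.approx(
            aw.doubling_time(curve, mode="regression"), abs=1e-9
        )

    def test_shrinking_culture_rejected(self):
        curve = aw.DoublingCurve(
            pd.DataFrame({"passage": [1], "days": [3.0], "seeded": [1e5], "harvested": [5e4]})
        )
        with pytest.raises(ValueError, match="positive"):
            aw.doubling_time(curve)


class TestGrowthAdvantage:
    @pytest.mark.parametrize(
        "Y, X, td_ref, expected",
        [
            (1.0, 7.0, 2.0, 0.0),
            (8.0, 6.0, 2.0, -50.0),   # implied focal td = 1 d
            (0.5, 6.0, 2.0, +50.0),   # implied focal td = 3 d
        ],
    )
    def test_printed_formula_values(self, Y, X, td_ref, expected):
        assert aw.growth_advantage(Y, X, td_ref) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="non-positive doubling time"):
            aw.growth_advantage(Y=2.0 ** -10, X=3.0, td_ref=2.0)

    def test_monotone_decreasing_in_Y(self):
        ys = np.linspace(0.2, 4.0, 50)
        gas = [aw.growth_advantage(y, 7.0, 2.0) for y in ys]
        assert np.all(np.diff(gas) < 0)

    def test_forward_inverse_identity(self):
        """Analytic simulation -> estimator returns (td_a-td_b)/td_b*100."""
        for td_a in np.linspace(0.8, 4.0, 9):
            for td_b in np.linspace(0.8, 4.0, 9):
                for x in (3.0, 7.0):
                    obs = analytic_obs(td_a, td_b, x, n0_ratio=1.7, feeder=0.2)
                    ga = aw.growth_advantage(aw.ratio_change(obs), x, td_b)
                    assert ga == pytest.approx(
                        (td_a - td_b) / td_b * 100, abs=1e-9
                    )

    def test_reciprocity(self):
        obs = analytic_obs(1.3, 2.6, 5.0)
        y = aw.ratio_change(obs)
        g_ab = aw.growth_advantage(y, 5.0, 2.6)
        g_ba = aw.growth_advantage(1 / y, 5.0, 1.3)
        assert (1 + g_ab / 100) * (1 + g_ba / 100) == pytest.approx(1.0, abs=1e-12)

    def test_feeder_invariance_across_fractions(self):
        ref = aw.growth_advantage(aw.ratio_change(analytic_obs(1.5, 2.0, 6.0)), 6.0, 2.0)
        for feeder in (0.1, 0.5, 0.89):
            ga = aw.growth_advantage(
                aw.ratio_change(analytic_obs(1.5, 2.0, 6.0, feeder=feeder)), 6.0, 2.0
            )
            assert ga == pytest.approx(ref, abs=1e-9)

    def test_stochastic_median_close_to_analytic(self):
        """Multinomial flow sampling: median estimate near truth."""
        td_b, x = 2.0, 6.0
        truth = +30.0
        td_a = td_b * (1 + truth / 100)
        gas = []
        for s in range(200):
            par = aw.CoculturePar(
                td_a=td_a, td_b=td_b, duration_days=x,
                feeder_fraction=0.3, events=10_000, seed=s,
            )
            obs = aw.simulate_coculture(par)
            gas.append(aw.growth_advantage(aw.ratio_change(obs), x, td_b))
        assert abs(np.median(gas) - truth) < 2.0


class TestSummarizePair:
    def make_wells(self, td_ped, td_adult, x=6.0, reps=3):
        wells = []
        for orientation in ("color1", "color2"):
            for rep in range(1, reps + 1):
                wells.append(
                    analytic_obs(
                        td_ped, td_adult, x, orientation=orientation,
                        well=f"{orientation}_r{rep}", replicate=rep,
                        pair="P1:A1", focal_donor="P1", ref_donor="A1",
                    )
                )
        return wells

    def test_identical_replicates_mean_equals_single_value(self):
        wells = self.make_wells(1.5, 2.0)
        res = aw.summarize_pair(wells, td_ref=2.0)
        single = aw.growth_advantage(aw.ratio_change(wells[0]), 6.0, 2.0)
        assert res.per_orientation["color1"] == pytest.approx(single, abs=1e-9)

    def test_both_orientations_agree_in_analytic_mode(self):
        res = aw.summarize_pair(self.make_wells(1.5, 2.0), td_ref=2.0)
        expected = (1.5 - 2.0) / 2.0 * 100
        assert res.per_orientation["color1"] == pytest.approx(expected, abs=1e-9)
        assert res.per_orientation["color2"] == pytest.approx(expected, abs=1e-9)
        assert res.ga_percent == pytest.approx(expected, abs=1e-9)

    def test_equal_doubling_times_give_zero(self):
        res = aw.summarize_pair(self.make_wells(2.0, 2.0), td_ref=2.0)
        assert res.ga_percent == pytest.approx(0.0, abs=1e-9)

    def test_extinct_wells_excluded_and_counted(self):
        wells = self.make_wells(1.5, 2.0)
        dead = aw.CocultureObservation(
            "dead", "color1", 0, 6, 50, 50, 0, 95, 0, 5,
            pair="P1:A1", focal_donor="P1", ref_donor="A1",
        )
        res = aw.summarize_pair(wells + [dead], td_ref=2.0)
        assert res.excluded_wells == ["dead"]
        assert res.n_wells == len(wells)

    def test_orientation_with_no_usable_well_rejected(self):
        dead = aw.CocultureObservation(
            "dead", "color2", 0, 6, 50, 50, 0, 95, 0, 5,
        )
        wells = [w for w in self.make_wells(1.5, 2.0) if w.orientation == "color1"]
        with pytest.raises(ValueError, match="orientation"):
            aw.summarize_pair(wells + [dead], td_ref=2.0)

    def test_missing_reference_td_rejected(self):
        with pytest.raises(ValueError, match="doubling time"):
            aw.summarize_pair(self.make_wells(1.5, 2.0), td_ref=0.0)


class TestAssayCalculators:
    @pytest.mark.parametrize(
        "pct, vol, expected",
        [(20.0, 0.5, 20_000.0), (0.0, 1.0, 0.0), (100.0, 1.0, 50_000.0)],
    )
    def test_viral_titre(self, pct, vol, expected):
        assert aw.viral_titre(pct, vol) == pytest.approx(expected)

    def test_viral_titre_rejects_bad_volume(self):
        with pytest.raises(ValueError, match="volume"):
            aw.viral_titre(10.0, 0.0)

    @pytest.mark.parametrize(
        "colonies, seeded, expected",
        [(50, 2000, 2.5), (0, 2000, 0.0), (2000, 2000, 100.0)],
    )
    def test_colony_forming_efficiency(self, colonies, seeded, expected):
        assert aw.colony_forming_efficiency(colonies, seeded) == pytest.approx(expected)

    def test_colonies_cannot_exceed_seeded(self):
        with pytest.raises(ValueError, match="exceed"):
            aw.colony_forming_efficiency(2001, 2000)
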