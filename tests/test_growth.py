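"""Competition index, growth function and growth-model fitting."""

import math

import numpy as np
import pytest

import woodprod as wp
from woodprod.growth import GrowthFitError
from woodprod.inventory import ValidationError, fitting_subset
from conftest import make_plot, make_tree


class TestCompetitionIndex:
    def _plot(self, diams, strata=None):
        strata = strata or ["outer"] * len(diams)
        trees = [make_tree(f"t{i}", D1=d, D2=d + 1, stratum=s)
                 for i, (d, s) in enumerate(zip(diams, strata))]
        return trees, make_plot()

    def test_hand_evaluated_sum(self):
        # neighbours larger than 40 cm: one 50 cm outer stem at 8/ha
        trees, plot = self._plot([50.0, 40.0, 30.0])
        bl = wp.competition_index(trees[1], trees, plot)
        assert bl == pytest.approx(math.pi / 4 * 0.5 ** 2 * 8, abs=1e-9)
        assert bl == pytest.approx(1.5708, abs=1e-4)

    def test_largest_tree_has_zero(self):
        trees, plot = self._plot([50.0, 40.0, 30.0])
        assert wp.competition_index(trees[0], trees, plot) == 0.0

    def test_equal_diameters_excluded(self):
        trees, plot = self._plot([40.0, 40.0])
        assert wp.competition_index(trees[0], trees, plot) == 0.0

    def test_inner_stratum_expansion(self):
        trees, plot = self._plot([20.0, 12.0], strata=["inner", "inner"])
        bl = wp.competition_index(trees[1], trees, plot)
        assert bl == pytest.approx(math.pi / 4 * 0.2 ** 2 * 80, abs=1e-9)

    def test_raw_convention(self):
        trees, plot = self._plot([50.0, 40.0])
        bl = wp.competition_index(trees[1], trees, plot,
                                  expansion_scaled=False)
        assert bl == pytest.approx(math.pi / 4 * 0.5 ** 2, abs=1e-12)

    def test_focal_must_belong_to_plot(self):
        trees, plot = self._plot([50.0, 40.0])
        stranger = make_tree("x", D1=45.0)
        with pytest.raises(ValidationError):
            wp.competition_index(stranger, trees, plot)


class TestGrowthFunction:
    def test_no_competition_when_rho3_zero(self):
        p = wp.GrowthParams(rho0=0.3, rho1=0.5, rho2=-0.01, rho3=0.0,
                            rho4=0.07)
        expected = 0.3 * 25 ** 0.5 * math.exp(-0.25)
        assert expected == pytest.approx(1.1683, abs=1e-4)
        for bl in (0.0, 10.0, 50.0):
            assert wp.growth_function(25.0, bl, p) == pytest.approx(expected)

    def test_competition_denominator(self):
        p = wp.GrowthParams(rho0=0.3, rho1=0.5, rho2=-0.01, rho3=1.0,
                            rho4=0.05)
        expected = (0.3 * 25 ** 0.5 * math.exp(-0.25)) / (1 + math.e)
        assert wp.growth_function(25.0, 20.0, p) == pytest.approx(expected)
        assert expected == pytest.approx(0.3142, abs=1e-4)

    def test_growth_declines_with_competition(self):
        p = wp.GrowthParams(rho0=0.35, rho1=0.4, rho2=-0.008, rho3=1.2,
                            rho4=0.04)
        bl = np.linspace(0, 60, 200)
        for d in (12.0, 30.0, 80.0):
            g = wp.growth_function(d, bl, p)
            assert np.all(np.diff(g) < 0)

    def test_genus_deviation_multiplies(self):
        p = wp.GrowthParams(rho0=0.3, rho1=0.5, rho2=-0.01, rho3=0.0,
                            rho4=0.0, genus_effects={"Cola": 1.5})
        base = wp.growth_function(25.0, 0.0, p)
        assert wp.growth_function(25.0, 0.0, p, genus="Cola") \
            == pytest.approx(1.5 * base)
        assert wp.growth_function(25.0, 0.0, p, genus="Unknown") \
            == pytest.approx(base)


class TestPredictDiameter:
    def test_one_year_projection(self):
        p = wp.GrowthParams(rho0=0.5, rho1=0.0, rho2=0.0, rho3=0.0, rho4=0.0)
        t = make_tree(D1=30.0, D2=None, status="died")
        # growth imputed even for stems that died between censuses
        assert wp.predict_diameter_t1(t, 0.0, p) == pytest.approx(30.5)

    def test_recruit_uses_second_census_diameter(self):
        p = wp.GrowthParams(rho0=0.5, rho1=0.0, rho2=0.0, rho3=0.0, rho4=0.0)
        t = make_tree(D1=None, D2=12.0, status="recruit", stratum="inner")
        assert wp.predict_diameter_t1(t, 0.0, p) == pytest.approx(12.5)

    def test_vanishing_growth_rate_is_identity(self):
        p = wp.GrowthParams(rho0=1e-12, rho1=0.4, rho2=-0.008, rho3=1.2,
                            rho4=0.04)
        t = make_tree(D1=30.0)
        assert wp.predict_diameter_t1(t, 5.0, p) == pytest.approx(30.0,
                                                                  abs=1e-9)

    def test_missing_reference_diameter(self):
        p = wp.GrowthParams(rho0=0.5, rho1=0.0, rho2=0.0, rho3=0.0, rho4=0.0)
        t = make_tree(D1=None, D2=None, status="recruit")
        with pytest.raises(ValidationError):
            wp.predict_diameter_t1(t, 0.0, p)


class TestFitGrowthModel:
    def test_noiseless_single_genus_recovery(self, clean_network):
        trees, plots, truth = clean_network
        sub = [t for t in trees if t.status == "alive"]
        fit = wp.fit_growth_model(sub, plots, method="fixed")
        tg = truth.growth
        for name in ("rho0", "rho1", "rho2", "rho3", "rho4"):
            assert getattr(fit, name) == pytest.approx(
                getattr(tg, name), rel=1e-6), name

    def test_too_few_trees_rejected(self):
        trees = [make_tree(f"t{i}", D1=30.0 + i, D2=32.0 + i)
                 for i in range(20)]
        with pytest.raises(GrowthFitError, match="minimum"):
            wp.fit_growth_model(trees, [make_plot()])

    def test_degenerate_identical_growth_fails_loudly(self):
        trees = [make_tree(f"t{i}", D1=40.0, D2=43.0) for i in range(300)]
        with pytest.raises(GrowthFitError, match="degenerate"):
            wp.fit_growth_model(trees, [make_plot()])

    def test_two_stage_genus_effects_centred(self, small_network):
        trees, plots, _ = small_network
        rt, rp = wp.screen_trees(trees), wp.screen_plots(trees, plots)
        sub = fitting_subset(trees, rt, rp)
        fit = wp.fit_growth_model(sub, plots, method="two_stage",
                                  min_trees=100)
        logs = np.log(list(fit.genus_effects.values()))
        assert abs(logs.sum()) < 1e-8  # geometric mean 1

    def test_serialization_round_trip(self, tmp_path, clean_network):
        trees, plots, _ = clean_network
        sub = [t for t in trees if t.status == "alive"]
        fit = wp.fit_growth_model(sub, plots, method="fixed")
        path = tmp_path / "m.json"
        fit.to_json(path)
        back = wp.GrowthParams.from_json(path)
        assert back.rho0 == pytest.approx(fit.rho0)
        assert back.genus_effects == fit.genus_effects


def test_refit_on_self_simulated_data_is_consistent():
    """Data simulated from a fitted model refits to nearly the same
    parameters (self-consistency within Monte Carlo error)."""
    from woodprod.synth import recovery_config
    cfg = recovery_config(99, n_plots=150)
    trees, plots, truth = wp.generate(cfg)
    sub = [t for t in trees if t.status == "alive"]
    fit1 = wp.fit_growth_model(sub, plots)
    # regenerate with the fitted parameters as truth
    cfg2 = recovery_config(100, n_plots=150)
    cfg2.growth = wp.GrowthParams(
        rho0=fit1.rho0, rho1=fit1.rho1, rho2=fit1.rho2, rho3=fit1.rho3,
        rho4=fit1.rho4, sigma_genus=fit1.sigma_genus,
        sigma_resid=fit1.sigma_resid)
    trees2, plots2, _ = wp.generate(cfg2)
    fit2 = wp.fit_growth_model([t for t in trees2 if t.status == "alive"],
                               plots2)
    assert fit2.rho0 == pytest.approx(fit1.rho0, rel=0.25)
    assert fit2.rho1 == pytest.approx(fit1.rho1, rel=0.25)
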