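"""Cost, AIC, simulated-annealing calibration and model comparison."""

import numpy as np
import pytest

import phenoproc as pp
from phenoproc.datatypes import NO_TRANSITION
from phenoproc.fitting import SSE_EPSILON
from phenoproc.stack import DriverError


class TestCost:
    def test_rmse_basic(self):
        assert pp.cost_rmse([100, 110], [103, 106]) == pytest.approx(np.sqrt(12.5))

    def test_sentinel_replaced_by_penalty(self):
        with_penalty = pp.cost_rmse([100.0], [NO_TRANSITION], penalty=9999.0)
        assert with_penalty == pytest.approx(9999.0 - 100.0)

    def test_empty_and_mismatched_inputs_raise(self):
        with pytest.raises(ValueError):
            pp.cost_rmse([], [])
        with pytest.raises(ValueError):
            pp.cost_rmse([1, 2], [1])


class TestAic:
    def test_formula_matches_reference_to_1e10(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            k = int(rng.integers(1, 11))
            obs = rng.normal(150, 20, n)
            pred = obs + rng.normal(0, 3, n)
            sse = float(np.sum((obs - pred) ** 2))
            expected = 2 * k + n * np.log(sse / n)
            assert abs(pp.compute_aic(obs, pred, k) - expected) < 1e-10

    def test_zero_sse_floored_with_warning(self):
        obs = np.array([100.0, 120.0])
        with pytest.warns(UserWarning, match="SSE"):
            aic = pp.compute_aic(obs, obs, 3)
        assert aic == pytest.approx(6 + 2 * np.log(SSE_EPSILON / 2))

    def test_delta_classes_on_constructed_list(self):
        aics = [100.0, 101.9, 102.0, 109.9, 110.0, 200.0]
        deltas = [a - aics[0] for a in aics]
        classes = [pp.support_class(d) for d in deltas]
        assert classes == ["equivalent", "equivalent", "little", "little", "none", "none"]


class TestDefaultBounds:
    def test_every_model_has_complete_bounds(self):
        for registry in (pp.SPRING_MODELS, pp.AUTUMN_MODELS):
            for model in registry.values():
                bounds = pp.default_bounds(model)
                assert set(bounds) == set(model.parameter_names)
                for lo, hi in bounds.values():
                    assert lo < hi

    def test_example_truths_inside_bounds(self):
        for name, truth in pp.EXAMPLE_TRUTHS.items():
            model = (pp.SPRING_MODELS.get(name) or pp.AUTUMN_MODELS[name])
            bounds = pp.default_bounds(model)
            for pname, value in truth.items():
                lo, hi = bounds[pname]
                assert lo <= value <= hi, f"{name}.{pname}={value} outside [{lo}, {hi}]"


@pytest.fixture(scope="module")
def tt_fit_setup(small_experiment):
    series, _ = small_experiment
    model = pp.get_spring_model("TT")
    obs = pp.generate_transitions_process(
        series, model, pp.EXAMPLE_TRUTHS["TT"], "DN", noise_sd=0.0, seed=3
    )
    return model, obs, series


class TestFitModel:
    def test_noise_free_self_recovery(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        cfg = pp.FitConfig(n_chains=5, n_iterations=2000, seed=1)
        fit = pp.fit_model(model, obs, series, cfg)
        # rounding of generated dates alone allows RMSE up to 0.5
        assert fit.rmse <= 0.5
        assert fit.n_obs == len(obs)
        assert set(fit.parameters) == set(model.parameter_names)

    def test_deterministic_given_seed(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        cfg = pp.FitConfig(n_chains=2, n_iterations=500, seed=9)
        a = pp.fit_model(model, obs, series, cfg)
        b = pp.fit_model(model, obs, series, cfg)
        assert a.aic == b.aic
        assert a.parameters == b.parameters

    def test_different_seeds_explore_differently(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        a = pp.fit_model(model, obs, series, pp.FitConfig(2, 300, seed=1))
        b = pp.fit_model(model, obs, series, pp.FitConfig(2, 300, seed=2))
        assert a.chain_costs != b.chain_costs

    def test_chain_costs_recorded_per_chain(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        fit = pp.fit_model(model, obs, series, pp.FitConfig(3, 300, seed=1))
        assert len(fit.chain_costs) == 3

    def test_bounds_override_respected(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        cfg = pp.FitConfig(2, 300, seed=1, bounds={"T_base": (4.9, 5.1)})
        fit = pp.fit_model(model, obs, series, cfg)
        assert 4.9 <= fit.parameters["T_base"] <= 5.1

    def test_observation_without_driver_raises(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        bad = obs + [pp.TransitionObservation("E99", 1999, "DN", "spring", 100.0)]
        with pytest.raises(ValueError, match="E99"):
            pp.fit_model(model, bad, series, pp.FitConfig(1, 100, seed=1))


class TestRankModels:
    def test_orders_by_aic_and_classifies(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        cfg = pp.FitConfig(3, 800, seed=4)
        fits = [pp.fit_model(pp.get_spring_model(n), obs, series, cfg)
                for n in ("TT", "LIN")]
        table = pp.rank_models(fits)
        assert table.delta_aic[0] == 0.0
        assert table.aic == sorted(table.aic)
        assert table.support[0] == "equivalent"
        frame = table.to_frame()
        assert list(frame.columns) == [
            "model", "k_params", "rmse", "aic", "delta_aic", "support"
        ]

    def test_rejects_mismatched_observation_sets(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        cfg = pp.FitConfig(1, 200, seed=4)
        f1 = pp.fit_model(model, obs, series, cfg)
        f2 = pp.fit_model(model, obs[:-2], series, cfg)
        with pytest.raises(ValueError, match="different observation sets"):
            pp.rank_models([f1, f2])


class TestApplyFitted:
    def test_forward_application_no_refit(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        rmse, pred = pp.apply_fitted(model, pp.EXAMPLE_TRUTHS["TT"], obs, series)
        assert rmse <= 0.5
        assert pred.size == len(obs)

    def test_missing_channel_raises_driver_error(self, tt_fit_setup):
        model, obs, series = tt_fit_setup
        stripped = [
            pp.DriverSeries(s.enclosure_id, s.focal_year, s.doy, s.t_air)
            for s in series
        ]
        ptt = pp.get_spring_model("PTT")
        with pytest.raises(DriverError, match="daylength"):
            pp.apply_fitted(ptt, {"t0": 1, "T_base": 0, "F_star": 50}, obs, stripped)


def test_compare_driver_depths_flags_missing_channels(tt_fit_setup):
    model, obs, series = tt_fit_setup
    stripped = [
        pp.DriverSeries(
            s.enclosure_id, s.focal_year, s.doy, s.t_air,
            t_soil={10: s.t_soil[10]}, daylength=s.daylength,
        )
        for s in series
    ]
    cfg = pp.FitConfig(1, 200, seed=2)
    table = pp.compare_driver_depths(model, obs, stripped, ["air", 10, 200], cfg)
    avail = dict(zip(table.channel, table.available))
    assert avail == {"air": True, "10": True, "200": False}
    assert np.isnan(table.loc[table.channel == "200", "aic"]).all()
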