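import numpy as np
import pandas as pd
import pytest

from basilight.dose_response import fit_linear
from basilight.synthetic_data import (
    GradientConfig,
    SimulationConfig,
    lamp_spectrum,
    ppfd800_factor,
    read_experiment,
    simulate_environment,
    simulate_gradient,
    simulate_plants,
    write_experiment,
)


class TestConfig:
    def test_defaults_encode_study_design(self):
        cfg = SimulationConfig()
        assert cfg.gradient.max_ppfd == 230.0
        assert cfg.gradient.n_positions == 120
        assert cfg.photoperiod_h == 18.0
        assert set(cfg.seasons) == {
            "late_winter",
            "mid_spring",
            "early_summer",
            "late_summer",
        }
        assert cfg.seasons["late_winter"].mean_natural_dli_700 == 7.1
        assert cfg.treatments["red"].mu == 0.63

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_positions"):
            SimulationConfig(gradient=GradientConfig(n_positions=2))
        with pytest.raises(ValueError, match="min_ppfd"):
            SimulationConfig(gradient=GradientConfig(max_ppfd=1.0, min_ppfd=2.0))
        with pytest.raises(ValueError, match="mode"):
            SimulationConfig(mode="hybrid")

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=7)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.to_dict() == cfg.to_dict()


class TestEnvironment:
    def test_zero_variability_gives_constant_days(self):
        cfg = SimulationConfig()
        cfg.seasons["late_winter"].temp_sd_C = 0.0
        cfg.seasons["late_winter"].dli_cv = 0.0
        env = simulate_environment(cfg, "late_winter", np.random.default_rng(0))
        assert (env["mean_temp_C"] == 19.3).all()
        assert (env["natural_dli_700"] == 7.1).all()
        assert len(env) == 32

    def test_realized_mean_dli_matches_seasonal_target(self):
        cfg = SimulationConfig()
        env = simulate_environment(cfg, "late_winter", np.random.default_rng(3))
        assert env["natural_dli_700"].mean() == pytest.approx(7.1, rel=1e-9)
        assert (
            env["natural_dli_800"] / env["natural_dli_700"]
        ).mean() == pytest.approx(cfg.natural_800_factor)

    def test_same_seed_identical(self):
        cfg = SimulationConfig()
        a = simulate_environment(cfg, "mid_spring", np.random.default_rng(5))
        b = simulate_environment(cfg, "mid_spring", np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)


class TestGradient:
    def test_endpoints_match_design(self):
        doses = simulate_gradient(SimulationConfig())
        assert doses[0] == pytest.approx(230.0)
        assert doses[-1] == pytest.approx(0.5)

    @pytest.mark.parametrize("shape", ["exponential", "linear", "inverse_square"])
    def test_strictly_decreasing_all_shapes(self, shape):
        cfg = SimulationConfig(gradient=GradientConfig(shape=shape))
        doses = simulate_gradient(cfg)
        assert np.all(np.diff(doses) < 0)
        assert len(np.unique(doses)) == len(doses)

    def test_unknown_shape_errors(self):
        cfg = SimulationConfig()
        cfg.gradient.shape = "parabolic"
        with pytest.raises(ValueError, match="shape"):
            simulate_gradient(cfg)


class TestSpectra:
    def test_normalised_to_unit_ppfd(self):
        from basilight.photometry import integrate_band

        for color in ("blue", "red", "white_fr"):
            s = lamp_spectrum(color)
            assert integrate_band(s, 400, 700).value == pytest.approx(1.0)

    def test_farred_lamp_carries_extra_photons_beyond_700(self):
        assert ppfd800_factor(lamp_spectrum("white_fr")) > 1.5
        assert ppfd800_factor(lamp_spectrum("red")) == pytest.approx(1.0, abs=1e-3)

    def test_unknown_color_errors(self):
        with pytest.raises(ValueError, match="color"):
            lamp_spectrum("green")


class TestSimulatePlants:
    def test_design_arithmetic(self, small_experiment, small_config):
        obs = small_experiment.observations
        n_expected = 3 * 4 * 2 * 2 * small_config.gradient.n_positions
        assert len(obs) == n_expected
        cells = obs.groupby(["treatment", "season", "replication", "harvest"]).size()
        assert (cells == small_config.gradient.n_positions).all()

    def test_observation_invariants(self, small_experiment):
        obs = small_experiment.observations
        np.testing.assert_allclose(
            obs["plant_height_mm"],
            obs["hypocotyl_mm"] + obs["epicotyl_mm"] + obs["internode_mm"],
        )
        np.testing.assert_allclose(
            obs["lma_g_m2"], obs["leaf_dw_g"] / obs["leaf_area_m2"]
        )
        np.testing.assert_allclose(
            obs["stem_leaf_ratio"], obs["stem_dw_g"] / obs["leaf_dw_g"]
        )
        np.testing.assert_allclose(
            obs["shoot_dw_g"], obs["leaf_dw_g"] + obs["stem_dw_g"]
        )
        assert (obs[["leaf_fw_g", "stem_fw_g", "leaf_area_m2"]] > 0).all().all()

    def test_determinism_byte_identical(self, small_config):
        a = simulate_plants(small_config)
        b = simulate_plants(small_config)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        for s in a.environments:
            pd.testing.assert_frame_equal(a.environments[s], b.environments[s])

    def test_noiseless_mode_recovers_parameters_exactly(self):
        cfg = SimulationConfig(seed=9, gradient=GradientConfig(n_positions=24), sigma_rep=0.0)
        for tp in cfg.traits.values():
            tp.sigma = 0.0
        cfg.dmc_sigma = 0.0
        exp = simulate_plants(cfg)
        cell = exp.observations.query(
            "treatment == 'red' and season == 'late_winter' "
            "and replication == 1 and harvest == 'intermediate'"
        )
        tp = cfg.traits["leaf_dw_g"]
        fit = fit_linear(cell, "leaf_dw_g")
        assert fit.slope == pytest.approx(tp.slope("red", "late_winter"), abs=1e-10)
        assert fit.intercept == pytest.approx(
            tp.level("late_winter", "intermediate"), abs=1e-9
        )
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_ground_truth_recorded(self, small_experiment):
        gt = small_experiment.ground_truth
        assert gt["mode"] == "phenomenological"
        assert len(gt["gradient_doses"]) == 16
        assert "leaf_dw_g" in gt["traits"]


class TestRoundTrip:
    def test_write_read_lossless(self, small_experiment, tmp_path):
        write_experiment(small_experiment, tmp_path / "exp")
        back = read_experiment(tmp_path / "exp")
        pd.testing.assert_frame_equal(
            back.observations, small_experiment.observations
        )
        assert set(back.environments) == set(small_experiment.environments)
        assert back.ground_truth["mode"] == "phenomenological"
        assert back.config.to_dict() == small_experiment.config.to_dict()

    def test_readable_without_ground_truth(self, small_experiment, tmp_path):
        d = tmp_path / "exp"
        write_experiment(small_experiment, d)
        (d / "ground_truth.json").unlink()
        (d / "config.yaml").unlink()
        back = read_experiment(d)
        assert back.config is None
        assert back.ground_truth == {}
        assert len(back.observations) == len(small_experiment.observations)

    def test_corrupted_column_raises_validation_error(self, small_experiment, tmp_path):
        d = tmp_path / "exp"
        write_experiment(small_experiment, d)
        obs = pd.read_csv(d / "observations.csv").rename(
            columns={"dose_ppfd700": "dose"}
        )
        obs.to_csv(d / "observations.csv", index=False)
        with pytest.raises(ValueError, match="dose_ppfd700"):
            read_experiment(d)
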