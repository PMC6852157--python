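import math

import numpy as np
import pytest

from benthic_encounters.abm import (ArenaConfig, analytic_encounter_rate,
                                    make_world, mean_relative_speed,
                                    run_replicate, run_world, step,
                                    sweep_consumer_mass)


def _static_world(radius=0.05, extent=1.0, n=10, seed=0, **kw):
    cfg = ArenaConfig(extent=extent, n_steps=10, **kw)
    rng = np.random.default_rng(seed)
    return make_world(radius=radius, region="discoid", consumer_speed=0.0,
                      n_resources=n, resource_speed=0.0, planktonic=False,
                      density=n / extent ** 2, config=cfg, rng=rng)


class TestStep:
    def test_still_world_never_encounters(self):
        w = _static_world()
        # push all resources well away from the central region
        w.res_pos[:] = [[0.05, 0.05]] * w.res_pos.shape[0]
        for _ in range(50):
            step(w)
        assert w.encounters == 0

    def test_resource_inside_region_hit_on_first_step(self):
        w = _static_world()
        w.res_pos[:] = [[0.05, 0.05]] * w.res_pos.shape[0]
        w.res_pos[0] = [0.51, 0.5]  # inside the radius-0.05 disc at centre
        step(w)
        assert w.encounters == 1

    def test_resource_count_conserved(self):
        cfg = ArenaConfig(extent=0.5, height=0.5, n_steps=10)
        rng = np.random.default_rng(1)
        w = make_world(radius=0.08, region="hemispheric", consumer_speed=0.0,
                       n_resources=200, resource_speed=0.005, planktonic=True,
                       density=3200, config=cfg, rng=rng)
        for _ in range(200):
            step(w)
        assert w.res_pos.shape[0] == 200
        assert w.encounters > 0  # flow drives flux through the hemisphere

    def test_hemisphere_keeps_resources_above_seabed(self):
        cfg = ArenaConfig(extent=0.5, height=0.2, n_steps=10)
        rng = np.random.default_rng(2)
        w = make_world(radius=0.05, region="hemispheric", consumer_speed=0.0,
                       n_resources=100, resource_speed=0.02, planktonic=True,
                       density=2000, config=cfg, rng=rng)
        for _ in range(100):
            step(w)
            assert np.all(w.res_pos[:, 2] >= 0.0)
            assert np.all(w.res_pos[:, 2] <= w.height + 1e-12)

    def test_aliasing_config_rejected(self):
        cfg = ArenaConfig(extent=0.1, dt=10.0, n_steps=10)
        with pytest.raises(ValueError, match="aliasing|extent"):
            make_world(radius=0.01, region="discoid", consumer_speed=0.05,
                       n_resources=5, resource_speed=0.0, planktonic=False,
                       density=500, config=cfg,
                       rng=np.random.default_rng(0))


class TestRunReplicate:
    def test_zero_duration_zero_rates(self):
        cfg = ArenaConfig(n_steps=0)
        log = run_replicate(cfg, 1.0, "filter", 0)
        assert log.unitary_rate == 0.0 and log.biomass_rate == 0.0

    def test_deterministic_under_seed(self):
        cfg = ArenaConfig(n_steps=200, max_resources=100)
        a = run_replicate(cfg, 1.0, "filter", 7)
        b = run_replicate(cfg, 1.0, "filter", 7)
        assert a.encounters == b.encounters
        assert a.unitary_rate == b.unitary_rate

    def test_biomass_identity(self):
        cfg = ArenaConfig(n_steps=300, max_resources=200)
        for strategy in ("filter", "active-static", "active-mobile"):
            log = run_replicate(cfg, 1.0, strategy, 3)
            if log.unitary_rate > 0:
                assert log.biomass_rate / log.unitary_rate == pytest.approx(
                    log.resource_mass)

    def test_filter_uses_hemisphere_and_no_self_motion(self):
        cfg = ArenaConfig(n_steps=10, max_resources=50)
        log = run_replicate(cfg, 1.0, "filter", 0)
        assert log.config["consumer_speed"] == 0.0

    def test_clearance_radius_mode(self):
        cfg = ArenaConfig(n_steps=50, max_resources=50)
        log = run_replicate(cfg, 1.0, "filter", 0, use_clearance=True,
                            clearance_rate=1e-5)
        expected_r = math.sqrt(2 * 1e-5 / (math.pi * 0.1))
        assert log.config["radius"] == pytest.approx(expected_r)


class TestSweep:
    def test_single_replicate_bands_collapse(self):
        cfg = ArenaConfig(n_steps=100, max_resources=50)
        out = sweep_consumer_mass("filter", [1.0], 1, cfg, seed=1)
        row = out.iloc[0]
        assert row["unitary_q025"] == row["unitary_q975"] == row[
            "unitary_median"]
        assert row["quantiles_unstable"]

    def test_bands_reproducible_under_seed(self):
        cfg = ArenaConfig(n_steps=100, max_resources=50)
        a = sweep_consumer_mass("filter", [0.5, 5.0], 5, cfg, seed=4)
        b = sweep_consumer_mass("filter", [0.5, 5.0], 5, cfg, seed=4)
        assert a.equals(b)

    def test_band_width_narrows_with_replicates(self):
        cfg = ArenaConfig(n_steps=150, max_resources=100)
        narrow = sweep_consumer_mass("filter", [1.0], 60, cfg, seed=2)
        wide = sweep_consumer_mass("filter", [1.0], 6, cfg, seed=2)
        w_narrow = (narrow["unitary_q975"] - narrow["unitary_q025"]).iloc[0]
        w_wide = (wide["unitary_q975"] - wide["unitary_q025"]).iloc[0]
        # central quantiles from 6 draws are the sample extremes; with 60
        # replicates they move inside the tails
        assert w_narrow <= w_wide * 1.5


class TestAnalyticRates:
    def test_active_static_formula(self):
        assert analytic_encounter_rate("2d_active_static", r=0.1, n=10,
                                       V=0.05) == pytest.approx(0.1)

    def test_advective_flux_formula(self):
        rate = analytic_encounter_rate("3d_advective_filter", r=0.05, n=1000,
                                       U=0.1)
        assert rate == pytest.approx(1000 * 0.1 * math.pi * 0.0025 / 2)

    def test_zero_density(self):
        assert analytic_encounter_rate("2d_active_static", r=0.1, n=0,
                                       V=1.0) == 0.0

    def test_unsupported_scenario_signalled(self):
        with pytest.raises(ValueError):
            analytic_encounter_rate("sit_and_wait", r=0.1, n=1)

    def test_relative_speed_reduces_to_single_mover(self):
        assert mean_relative_speed(0.3, 0.0) == pytest.approx(0.3)

    def test_relative_speed_equal_movers(self):
        # equal speeds v: mean relative speed is 4v/pi
        assert mean_relative_speed(0.2, 0.2) == pytest.approx(0.8 / math.pi)


class TestCurrentCalibration:
    def test_realised_current_matches_configuration(self):
        cfg = ArenaConfig(n_steps=500, max_resources=100)
        log = run_replicate(cfg, 1.0, "filter", 11)
        # ~100 resources x 500 steps of N(0.1, 0.01) draws
        assert log.mean_current == pytest.approx(0.1, abs=0.005)
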