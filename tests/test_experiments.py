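"""Initialization, the swarm engine, ensembles, sweeps, and diagnostics."""

import json
from dataclasses import replace

import numpy as np
import pytest

from swarmtaxis.dynamics import AgentState, MotionParams, advance
from swarmtaxis.experiments import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    default_config,
    init_swarm,
    load_config,
    mechanism_comparison,
    run_ensemble,
    run_simulation,
    save_config,
    sweep,
    validate_config,
)
from swarmtaxis.metrics import arrival_times
from swarmtaxis.terrain import ConfigurationError, TerrainParams, concentration


class TestInitSwarm:
    def test_positions_within_init_radius(self):
        cfg = replace(default_config(), n_agents=10_000)
        agents = init_swarm(cfg, np.random.default_rng(0))
        pos = np.array([a.position for a in agents])
        d = np.linalg.norm(pos - np.asarray(cfg.start_position), axis=1)
        assert np.all(d <= cfg.init_radius)

    def test_disc_uniform_mean_at_start(self):
        cfg = replace(default_config(), n_agents=10_000)
        agents = init_swarm(cfg, np.random.default_rng(1))
        pos = np.array([a.position for a in agents])
        # per-axis variance of the uniform disc is R^2/4
        se = cfg.init_radius / 2 / np.sqrt(cfg.n_agents)
        for k in range(2):
            assert abs(pos[:, k].mean() - cfg.start_position[k]) < 3 * se

    def test_headings_cover_all_directions(self):
        cfg = replace(default_config(), n_agents=10_000)
        agents = init_swarm(cfg, np.random.default_rng(2))
        th = np.array([a.heading for a in agents])
        assert np.all((th > -np.pi) & (th <= np.pi))
        assert abs(np.mean(np.cos(th))) < 0.05 and abs(np.mean(np.sin(th))) < 0.05

    def test_tumble_phases_staggered_and_tau_heterogeneous(self):
        cfg = replace(default_config(), n_agents=2000, tau_range=(2, 9))
        agents = init_swarm(cfg, np.random.default_rng(3))
        taus = np.array([a.run_length for a in agents])
        phases = np.array([a.steps_since_tumble for a in agents])
        assert set(np.unique(taus)) == set(range(2, 10))
        assert np.all(phases < taus) and np.all(phases >= 0)

    def test_fixed_seed_reproducible(self):
        cfg = replace(default_config(), n_agents=50)
        a = init_swarm(cfg, np.random.default_rng(7))
        b = init_swarm(cfg, np.random.default_rng(7))
        assert all(
            np.array_equal(x.position, y.position) and x.heading == y.heading
            for x, y in zip(a, b)
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            replace(default_config(), n_agents=0)
        with pytest.raises(ConfigurationError):
            replace(default_config(), init_radius=-1.0)
        with pytest.raises(ConfigurationError):
            # start inside the init disc of the target
            replace(default_config(), start_position=(0.1, 0.0), init_radius=1.0)
        with pytest.raises(ConfigurationError):
            replace(default_config(), tau_range=(0, 5))


class TestRunSimulation:
    def test_single_agent_reduces_to_reference_walk(self, small_config):
        """The vectorized engine at N=1 without interactions reproduces the
        per-agent reference implementation draw for draw."""
        cfg = replace(
            small_config,
            n_agents=1,
            max_steps=200,
            policy=replace(small_config.policy, mode="independent"),
            seed=17,
        )
        traj = run_simulation(cfg)

        rng = np.random.default_rng(17)
        agents = init_swarm(cfg, rng)
        agent = agents[0]
        ref_pos = [agent.position.copy()]
        ref_theta = [agent.heading]
        goal = cfg.resolved_goal_radius
        for _ in range(cfg.max_steps):
            if agent.arrived:
                break
            advance(agent, None, cfg.terrain, cfg.motion, rng)
            if np.linalg.norm(agent.position - np.asarray(cfg.terrain.target_position)) <= goal:
                agent.arrived = True
            ref_pos.append(agent.position.copy())
            ref_theta.append(agent.heading)

        n = min(len(ref_pos), traj.positions.shape[0])
        assert np.array_equal(traj.positions[:n, 0, :], np.array(ref_pos)[:n])
        assert np.array_equal(traj.headings[:n, 0], np.array(ref_theta)[:n])

    def test_identical_seeds_identical_trajectories(self, small_config):
        t1 = run_simulation(small_config)
        t2 = run_simulation(small_config)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.headings, t2.headings)
        assert np.array_equal(t1.weights, t2.weights)
        assert np.array_equal(t1.arrived, t2.arrived)

    def test_fixed_w1_with_inert_zones_equals_independent(self, small_config):
        """With w = 1 and interaction radii too small to ever trigger, the
        fixed mechanism reproduces the independent trajectories exactly."""
        from swarmtaxis.interactions import InteractionZones

        inert = InteractionZones(repulsion=1e-9, orientation=2e-9, attraction=3e-9)
        fixed = replace(
            small_config,
            zones=inert,
            policy=replace(small_config.policy, mode="fixed", fixed_w=1.0),
        )
        indep = replace(
            small_config,
            zones=inert,
            policy=replace(small_config.policy, mode="independent"),
        )
        t1, t2 = run_simulation(fixed), run_simulation(indep)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.headings, t2.headings)

    def test_bowl_descent_always_arrives(self):
        """A lone tumbling agent on a pure bowl reaches the target from any
        start: Monte-Carlo over 100 seeds, no censoring."""
        terrain = TerrainParams(periodic_amplitude=0.0)
        base = SimulationConfig(
            terrain=terrain,
            motion=MotionParams(internal_noise_sd=0.0, run_length=1),
            n_agents=1,
            start_position=(-2.5, 1.0),
            max_steps=3000,
            goal_radius=0.2,
        )
        base = replace(base, policy=replace(base.policy, mode="independent"))
        for seed in range(100):
            traj = run_simulation(replace(base, seed=seed))
            assert np.isfinite(arrival_times(traj)).all(), f"censored at seed {seed}"

    def test_displacement_magnitude_for_active_agents(self, small_config):
        traj = run_simulation(replace(small_config, max_steps=120))
        step = small_config.motion.step_length
        for t in range(1, traj.positions.shape[0]):
            active = ~traj.arrived[t - 1]
            d = np.linalg.norm(traj.positions[t] - traj.positions[t - 1], axis=1)
            assert np.allclose(d[active], step)
            assert np.allclose(d[~active], 0.0)

    def test_arrived_flags_monotone(self, small_config):
        traj = run_simulation(small_config)
        assert np.all(traj.arrived[1:] >= traj.arrived[:-1])


class TestEnsembles:
    def test_single_round_matches_single_run(self, small_config):
        from swarmtaxis.metrics import summarize

        res = run_ensemble(small_config, 1, base_seed=5)
        traj = run_simulation(replace(small_config, seed=5))
        stats = summarize(traj, small_config.policy.mode, 5, small_config.zones.attraction)
        rec = res.records.iloc[0].to_dict()
        for key, val in stats.as_dict().items():
            assert rec[key] == val or (
                isinstance(val, float) and np.isclose(rec[key], val)
            )

    def test_doubling_rounds_reproduces_first_half(self, small_config):
        r1 = run_ensemble(small_config, 4, base_seed=100)
        r2 = run_ensemble(small_config, 8, base_seed=100)
        assert r1.records.equals(r2.records.iloc[:4].reset_index(drop=True))

    def test_aggregate_standard_error_definition(self, small_config):
        res = run_ensemble(small_config, 6, base_seed=0)
        agg = res.aggregate()
        unc = res.records[~res.records["censored"]]["median_path_length"]
        assert agg["se_median_path_length"] == pytest.approx(
            unc.std(ddof=1) / np.sqrt(len(unc))
        )
        assert agg["n_rounds"] == 6
        assert agg["n_censored"] + len(unc) == 6


class TestSweep:
    def test_single_value_equals_ensemble(self, small_config):
        table = sweep(small_config, "fixed_w", [0.6], 3, base_seed=9)
        res = run_ensemble(
            replace(small_config, policy=replace(small_config.policy, fixed_w=0.6)),
            3,
            base_seed=9,
        )
        assert table.drop(columns=["parameter", "value"]).equals(res.records)

    def test_long_format_shape(self, small_config):
        table = sweep(small_config, "n_agents", [2, 4], 3, base_seed=0)
        assert len(table) == 6
        assert set(table["value"]) == {2, 4}
        assert (table.groupby("value").size() == 3).all()

    def test_invalid_radii_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            sweep(small_config, "radii", [(2.5, 2.0)], 1, base_seed=0)

    def test_unknown_parameter_lists_options(self, small_config):
        with pytest.raises(ValueError, match="fixed_w"):
            sweep(small_config, "bogus", [1], 1, base_seed=0)


class TestMechanismComparison:
    def test_record_count_and_columns(self, small_config):
        res = mechanism_comparison(small_config, 4, base_seed=0)
        assert len(res.records) == 12
        assert set(res.records["mechanism"]) == {"independent", "fixed", "adaptive"}
        assert set(res.rank_tests) == {
            "adaptive<fixed",
            "fixed<independent",
            "adaptive<independent",
        }

    def test_degenerate_equality_with_interactions_disabled(self, small_config):
        from swarmtaxis.interactions import InteractionZones

        inert = InteractionZones(repulsion=1e-9, orientation=2e-9, attraction=3e-9)
        cfg = replace(
            small_config,
            zones=inert,
            policy=replace(small_config.policy, fixed_w=1.0),
        )
        res = mechanism_comparison(cfg, 10, base_seed=0)
        by_mech = {
            m: res.path_lengths(m) for m in ("independent", "fixed", "adaptive")
        }
        assert np.array_equal(by_mech["independent"], by_mech["fixed"])
        assert np.array_equal(by_mech["independent"], by_mech["adaptive"])
        assert all(v["p"] > 0.01 for v in res.rank_tests.values())


class TestValidateConfig:
    def test_default_config_clean(self):
        diag = validate_config(default_config())
        assert diag.ok
        assert diag.terrain_wavelength == pytest.approx(0.5)

    def test_overlong_runs_warned(self):
        cfg = default_config()
        cfg = replace(cfg, motion=replace(cfg.motion, run_length=30))
        diag = validate_config(cfg)
        assert any("too long" in w for w in diag.warnings)

    def test_too_short_runs_warned(self):
        cfg = default_config()
        cfg = replace(cfg, motion=replace(cfg.motion, dt=0.001, run_length=1))
        diag = validate_config(cfg)
        assert any("too short" in w for w in diag.warnings)

    def test_oversized_repulsion_radius_warned(self):
        cfg = default_config()
        cfg = replace(
            cfg,
            zones=replace(cfg.zones, repulsion=0.5, orientation=0.9),
            goal_radius=0.35,
        )
        diag = validate_config(cfg)
        assert any("repulsion" in w.lower() for w in diag.warnings)


class TestConfigIO:
    def test_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.json"
        save_config(small_config, path)
        loaded = load_config(path)
        assert loaded == small_config

    def test_unknown_section_rejected(self):
        data = config_to_dict(default_config())
        data["extra_section"] = {}
        with pytest.raises(ConfigurationError, match="unknown config section"):
            config_from_dict(data)

    def test_unknown_key_rejected(self):
        data = config_to_dict(default_config())
        data["motion"]["warp_speed"] = 9
        with pytest.raises(ConfigurationError, match="warp_speed"):
            config_from_dict(data)
        data = config_to_dict(default_config())
        data["run"]["bogus"] = 1
        with pytest.raises(ConfigurationError, match="bogus"):
            config_from_dict(data)

    def test_json_is_plain_types(self):
        text = json.dumps(config_to_dict(default_config()))
        assert "Infinity" not in text
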