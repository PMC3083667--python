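"""Simulation orchestration: stepping, replicates, output, CLI."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from tiedsim import (
    AgeClass,
    AgeDistribution,
    AgentType,
    ClimateGenConfig,
    CommunityConfig,
    ConfigError,
    SimulationConfig,
    SimulationState,
    VariableGenConfig,
    ClimateVariable,
    community_perception,
    individual_perception,
    knowledge_transfer_weight,
    apply_knowledge_transfer,
    load_climate_table,
    load_config,
    perception_weight,
    read_results,
    recorded_change,
    run_replicates,
    run_simulation,
    select_lk_provider,
    write_results,
)
from tiedsim.cli import main as cli_main
from tiedsim.simulation import _resolve_series


def small_config(**overrides):
    defaults = dict(
        community=CommunityConfig(population_size=15),
        scenario="B",
        lk_enabled=False,
        replicates=1,
        base_seed=7,
        sim_start_year=2010,
        sim_end_year=2020,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def all_old_community(size=10, mortality_enabled=False):
    """Every agent old enough for its adult lifetime to span the full record."""
    dist = AgeDistribution(
        class_proportions={AgeClass.YOUNG: 0.0, AgeClass.MIDDLE: 0.0,
                           AgeClass.OLD: 1.0},
        class_ranges={AgeClass.YOUNG: (18, 39), AgeClass.MIDDLE: (40, 59),
                      AgeClass.OLD: (68, 80)},
    )
    return CommunityConfig(population_size=size, age_distribution=dist,
                           mortality_enabled=mortality_enabled)


class TestRunShape:
    def test_default_window_emits_2916_records(self):
        cfg = small_config(sim_end_year=2090,
                           community=CommunityConfig(population_size=10))
        result = run_simulation(cfg, seed=1)
        assert len(result.frame) == 81 * 12 * 3
        by_var = result.frame.groupby("variable").size()
        assert set(by_var) == {81 * 12}

    def test_one_year_window_is_twelve_steps(self):
        cfg = small_config(sim_end_year=2011)
        result = run_simulation(cfg, seed=1)
        assert len(result.frame) == 24 * 3  # 2010 and 2011 inclusive

    def test_records_are_dense_and_consistent(self):
        result = run_simulation(small_config(), seed=3)
        f = result.frame
        assert not f[["year", "month", "variable"]].duplicated().any()
        assert np.allclose(f.v, f.q - f.P_c)
        assert np.allclose(f.v_abs, f.v.abs())

    def test_series_must_cover_window(self):
        clim = ClimateGenConfig(start_year=2000, end_year=2095)
        with pytest.raises(ValueError, match="cover"):
            run_simulation(small_config(climate=clim), seed=1)


class TestDeterminism:
    def test_same_seed_same_output(self):
        cfg = small_config(lk_enabled=True)
        a = run_simulation(cfg, seed=11).frame
        b = run_simulation(cfg, seed=11).frame
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        cfg = small_config(scenario="C")
        a = run_simulation(cfg, seed=11).frame
        b = run_simulation(cfg, seed=12).frame
        assert not np.allclose(a.v, b.v)

    def test_frozen_climate_shared_across_replicates(self):
        cfg = small_config()
        a = run_simulation(cfg, seed=1).frame
        b = run_simulation(cfg, seed=2).frame
        # identical recorded change: the climate realization is shared
        assert np.allclose(a.q, b.q)
        unfrozen = dataclasses.replace(cfg, freeze_climate=False)
        c = run_simulation(unfrozen, seed=1).frame
        d = run_simulation(unfrozen, seed=2).frame
        assert not np.allclose(c.q, d.q)


class TestReplicates:
    def test_single_replicate_equals_single_run(self):
        cfg = small_config(replicates=1)
        avg = run_replicates(cfg)
        single = run_simulation(cfg, seed=cfg.base_seed)
        assert np.allclose(avg.frame.v, single.frame.v)
        assert np.allclose(avg.frame.sd_v, 0.0)

    def test_mean_lies_within_replicate_envelope(self):
        cfg = small_config(replicates=3, scenario="C")
        avg = run_replicates(cfg)
        singles = [run_simulation(cfg, seed=cfg.base_seed + i).frame.v.to_numpy()
                   for i in range(3)]
        stack = np.stack(singles)
        assert np.all(avg.frame.v.to_numpy() <= stack.max(axis=0) + 1e-12)
        assert np.all(avg.frame.v.to_numpy() >= stack.min(axis=0) - 1e-12)


class TestPerfectKnowledgeLimit:
    def test_full_history_community_has_zero_vulnerability(self):
        for lk in (False, True):
            cfg = small_config(
                scenario="A",
                lk_enabled=lk,
                community=all_old_community(),
                sim_end_year=2030,
            )
            result = run_simulation(cfg, seed=5)
            assert result.frame.v_abs.max() <= 1e-9

    def test_all_gamma_population_makes_lk_inert(self):
        comm = CommunityConfig(
            population_size=12,
            type_proportions={AgentType.ALPHA: 0.0, AgentType.BETA: 0.0,
                              AgentType.GAMMA: 1.0},
        )
        on = run_simulation(small_config(lk_enabled=True, community=comm), seed=4)
        off = run_simulation(small_config(lk_enabled=False, community=comm), seed=4)
        pd.testing.assert_frame_equal(on.frame, off.frame)


class TestEngineMatchesScalarOperations:
    def test_monthly_records_match_composed_scalar_pipeline(self):
        """The vectorized yearly caches must reproduce, step by step, the
        composition of the scalar operations: individual perception, provider
        selection, transfer, weighted consensus, recorded change."""
        clim = ClimateGenConfig(start_year=2000, end_year=2015, seed=2)
        cfg = SimulationConfig(
            climate=clim,
            community=CommunityConfig(population_size=8),
            scenario="E",
            lk_enabled=True,
            sim_start_year=2010,
            sim_end_year=2013,
            history_start_year=2000,
            replicates=1,
            base_seed=21,
        )
        series = _resolve_series(cfg, 21)
        state = SimulationState(cfg, series, 21)
        tables = cfg.weight_tables
        for _ in range(48):
            year, month = state.year, state.month
            records = state.step()
            pop = state.population  # unchanged since this year's January
            providers = {
                a.id: select_lk_provider(a, pop, eligibility=cfg.lk_eligibility)
                for a in pop
            }
            for rec in records:
                var = rec.variable
                own = {
                    a.id: individual_perception(a, series, var, month, year)
                    for a in pop
                }
                final = []
                weights = []
                for a in pop:
                    r = own[a.id]
                    prov = providers[a.id]
                    if prov is not None:
                        w_k = knowledge_transfer_weight(a.type, prov.type, tables)
                        r = apply_knowledge_transfer(r, own[prov.id], w_k)
                    final.append(r)
                    weights.append(perception_weight(a, tables))
                expected_pc = community_perception(final, weights)
                expected_q = recorded_change(
                    series, var, month, year,
                    range(cfg.history_start_year, year),
                )
                assert rec.p_c == pytest.approx(expected_pc, abs=1e-9)
                assert rec.q == pytest.approx(expected_q, abs=1e-9)
                assert rec.v == pytest.approx(expected_q - expected_pc, abs=1e-9)


class TestOutput:
    def test_csv_round_trip_and_sidecar(self, tmp_path):
        cfg = small_config(replicates=2, sim_end_year=2011)
        avg = run_replicates(cfg)
        path = tmp_path / "out.csv"
        write_results(avg, path)
        back = read_results(path)
        assert len(back) == len(avg.frame)
        assert np.allclose(back.v, avg.frame.v, atol=1e-9)
        assert list(back.scenario.unique()) == ["B"]
        meta = json.loads((tmp_path / "out.csv.meta.json").read_text())
        assert meta["seeds"] == [7, 8]
        assert meta["version"]
        assert meta["config"]["community"]["population_size"] == 15

    def test_one_year_run_rows(self, tmp_path):
        cfg = small_config(sim_start_year=2010, sim_end_year=2011)
        run = run_simulation(cfg, seed=1)
        first_year = run.frame[run.frame.year == 2010]
        assert len(first_year) == 36


class TestConfigFile:
    def _write(self, tmp_path, payload):
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(payload))
        return path

    def test_yaml_round_trip(self, tmp_path):
        path = self._write(tmp_path, {
            "community": {"population_size": 33,
                          "type_proportions": {"alpha": 0.5, "beta": 0.25,
                                               "gamma": 0.25}},
            "simulation": {"scenario": "D", "lk_enabled": True,
                           "replicates": 4, "base_seed": 9},
            "weights": {"w_p": {"O.alpha": 0.9}},
        })
        cfg = load_config(path)
        assert cfg.community.population_size == 33
        assert cfg.scenario == "D" and cfg.lk_enabled
        assert cfg.weight_tables.w_p[(AgeClass.OLD, AgentType.ALPHA)] == 0.9
        # untouched entries keep their defaults
        assert cfg.weight_tables.w_p[(AgeClass.YOUNG, AgentType.BETA)] == 0.3

    def test_invalid_population_rejected(self, tmp_path):
        path = self._write(tmp_path, {"community": {"population_size": 0}})
        with pytest.raises(ConfigError):
            load_config(path)

    def test_unknown_scenario_rejected(self, tmp_path):
        path = self._write(tmp_path, {"simulation": {"scenario": "Z"}})
        with pytest.raises(ConfigError):
            load_config(path)


class TestCli:
    def test_generate_climate_writes_loadable_table(self, tmp_path):
        out = tmp_path / "climate.csv"
        result = CliRunner().invoke(cli_main, [
            "generate-climate", "--out", str(out),
            "--seed", "3", "--start-year", "1990", "--end-year", "2005",
        ])
        assert result.exit_code == 0, result.output
        series = load_climate_table(out)
        assert (series.start_year, series.end_year) == (1990, 2005)

    def test_run_smoke(self, tmp_path):
        config = tmp_path / "cfg.yaml"
        config.write_text(yaml.safe_dump({
            "community": {"population_size": 10},
            "simulation": {"sim_start_year": 2010, "sim_end_year": 2012,
                           "replicates": 1},
        }))
        out = tmp_path / "run.csv"
        result = CliRunner().invoke(cli_main, [
            "run", "--config", str(config), "--scenario", "A",
            "--no-lk", "--seed", "1", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert len(read_results(out)) == 3 * 12 * 3

    def test_sweep_produces_twelve_files(self, tmp_path):
        config = tmp_path / "cfg.yaml"
        config.write_text(yaml.safe_dump({
            "community": {"population_size": 8},
            "simulation": {"sim_start_year": 2010, "sim_end_year": 2011,
                           "replicates": 1},
        }))
        out_dir = tmp_path / "sweep"
        result = CliRunner().invoke(cli_main, [
            "sweep", "--config", str(config), "--out-dir", str(out_dir),
        ])
        assert result.exit_code == 0, result.output
        assert len(list(out_dir.glob("scenario_*.csv"))) == 12

    def test_validate_config_rejects_bad_file(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump({"community": {"population_size": -3}}))
        result = CliRunner().invoke(cli_main, ["validate-config", str(bad)])
        assert result.exit_code != 0

    def test_validate_config_accepts_good_file(self, tmp_path):
        good = tmp_path / "good.yaml"
        good.write_text(yaml.safe_dump({"simulation": {"scenario": "B"}}))
        result = CliRunner().invoke(cli_main, ["validate-config", str(good)])
        assert result.exit_code == 0
        assert "scenario=B" in result.output
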