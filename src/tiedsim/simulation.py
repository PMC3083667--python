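"""Monthly simulation loop, replicate averaging, configuration and output.

A run steps month by month over the simulation window (2010-2090 by
default). Annual events — demographic turnover, t_TRU decline and
known-history extension — fire at the January step; the first simulated
year only initializes histories. Every monthly step emits one
vulnerability record per climate variable: recorded change q (against the
full baseline back to the history start year), community perception P_c,
and their gap v.

The population state is frozen between annual events, so all per-agent
quantities for a year are computed once, vectorized over agents and months,
when the January step runs; monthly steps then read from those caches. The
arithmetic is identical to composing the scalar operations in
:mod:`tiedsim.perception` agent by agent, which the test suite checks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import (
    ClimateGenConfig,
    ClimateVariable,
    MonthlySeries,
    VariableGenConfig,
    generate_synthetic_climate,
    load_climate_table,
)
from .community import (
    SCENARIOS,
    Agent,
    AgeClass,
    AgentType,
    AgeDistribution,
    CommunityConfig,
    Scenario,
    annual_demographic_update,
    initialize_community,
)
from .perception import VulnerabilityRecord, WeightTables, build_known_history

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "RunResult",
    "AveragedResult",
    "ConfigError",
    "step_month",
    "run_simulation",
    "run_replicates",
    "write_results",
    "read_results",
    "load_config",
    "config_to_dict",
]

log = logging.getLogger("tiedsim")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a run.

    ``climate`` is either a generator configuration or a path to a CSV
    climate table. With ``freeze_climate`` (the default) all replicates share
    the single realization produced by the generator's own seed, so
    replicate-to-replicate variation isolates the social process; otherwise
    each replicate regenerates the climate from its own seed.
    """

    climate: Union[ClimateGenConfig, str] = field(default_factory=ClimateGenConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    scenario: str = "A"
    lk_enabled: bool = False
    sim_start_year: int = 2010
    sim_end_year: int = 2090
    history_start_year: int = 1960
    replicates: int = 30
    base_seed: int = 0
    freeze_climate: bool = True
    lk_eligibility: str = "count"
    weight_tables: WeightTables = field(default_factory=WeightTables)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of "
                f"{sorted(SCENARIOS)}"
            )
        if not self.history_start_year <= self.sim_start_year:
            raise ConfigError("history_start_year must not exceed sim_start_year")
        if not self.sim_start_year < self.sim_end_year:
            raise ConfigError("sim_start_year must be before sim_end_year")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.lk_eligibility not in ("count", "span"):
            raise ConfigError("lk_eligibility must be 'count' or 'span'")

    @property
    def scenario_obj(self) -> Scenario:
        return SCENARIOS[self.scenario]


@dataclass
class RunResult:
    """Dense per-(year, month, variable) vulnerability records of one run."""

    frame: pd.DataFrame  # columns: year, month, variable, q, P_c, v, v_abs, degenerate
    scenario: str
    lk_enabled: bool
    seed: int
    config: dict

    @property
    def seeds(self) -> list[int]:
        return [self.seed]


@dataclass
class AveragedResult:
    """Pointwise replicate mean (and sd of v, |v|) per (year, month, variable)."""

    frame: pd.DataFrame  # year, month, variable, q, P_c, v, v_abs, sd_v, sd_v_abs
    scenario: str
    lk_enabled: bool
    replicates: int
    seeds: list[int]
    config: dict


class SimulationState:
    """Mutable state of a single run, advanced one month at a time."""

    def __init__(
        self,
        config: SimulationConfig,
        series: MonthlySeries,
        seed: int,
    ) -> None:
        if not series.covers(config.history_start_year, config.sim_end_year):
            raise ValueError(
                "climate series must cover "
                f"[{config.history_start_year}, {config.sim_end_year}]; "
                f"got [{series.start_year}, {series.end_year}]"
            )
        self.config = config
        self.series = series
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.scenario = config.scenario_obj
        self.population: list[Agent] = initialize_community(
            config.community, self.scenario, self.rng
        )
        self._next_id = len(self.population)
        self.year = config.sim_start_year
        self.month = 1
        self.years_elapsed = 0
        y0 = config.history_start_year
        self._year0 = y0
        n_total = config.sim_end_year - y0 + 1
        self._values: dict[ClimateVariable, np.ndarray] = {}
        self._cumsum: dict[ClimateVariable, np.ndarray] = {}
        off = y0 - series.start_year
        for var in ClimateVariable:
            vals = series.matrix(var)[off : off + n_total]
            self._values[var] = vals
            self._cumsum[var] = np.cumsum(vals, axis=0)
        self._p_c: dict[ClimateVariable, np.ndarray] = {}
        self._q: dict[ClimateVariable, np.ndarray] = {}
        self._degenerate: dict[ClimateVariable, bool] = {}

    # -- annual phase -------------------------------------------------------

    def _annual_phase(self) -> None:
        cfg = self.config
        if self.years_elapsed > 0:
            self._next_id = annual_demographic_update(
                self.population,
                self.scenario,
                self.years_elapsed,
                self.rng,
                exponent=cfg.community.mortality_exponent,
                mortality_enabled=cfg.community.mortality_enabled,
                next_id=self._next_id,
            )
        for agent in self.population:
            build_known_history(agent, self.year, cfg.history_start_year, self.rng)
        self._rebuild_caches()

    def _select_providers(
        self, measures: np.ndarray, ids: np.ndarray, scores: np.ndarray
    ) -> np.ndarray:
        """Vectorized provider choice: argmax score among strictly longer histories.

        Matches :func:`tiedsim.perception.select_lk_provider` exactly
        (strictly greater history measure, max score, ties to smallest id).
        """
        n = len(measures)
        order = np.lexsort((ids, measures))  # measure asc, id asc
        best_after = np.full(n + 1, -1, dtype=int)
        for k in range(n - 1, -1, -1):
            cand = order[k]
            cur = best_after[k + 1]
            if (
                cur == -1
                or scores[cand] > scores[cur]
                or (scores[cand] == scores[cur] and ids[cand] < ids[cur])
            ):
                best_after[k] = cand
            else:
                best_after[k] = cur
        sorted_measures = measures[order]
        pos = np.searchsorted(sorted_measures, measures, side="right")
        return best_after[pos]

    def _rebuild_caches(self) -> None:
        cfg = self.config
        pop = self.population
        n = len(pop)
        n_total = self._values[ClimateVariable.TEMPERATURE].shape[0]
        year_idx = self.year - self._year0

        H = np.zeros((n, n_total), dtype=float)
        for i, agent in enumerate(pop):
            for y in agent.known_history:
                H[i, y - self._year0] = 1.0
        counts = H.sum(axis=1)
        defined = counts > 0

        wp = np.array(
            [cfg.weight_tables.w_p[(a.age_class, a.type)] for a in pop]
        )

        providers: Optional[np.ndarray] = None
        wk = None
        if cfg.lk_enabled:
            if cfg.lk_eligibility == "count":
                measures = counts.astype(int)
            else:
                measures = np.array(
                    [
                        (max(a.known_history) - min(a.known_history))
                        if a.known_history
                        else -1
                        for a in pop
                    ]
                )
            ids = np.array([a.id for a in pop])
            ages = np.array([a.age for a in pop], dtype=float)
            trus = np.array([a.t_tru for a in pop])
            scores = ages / ages.max() * trus
            providers = self._select_providers(measures, ids, scores)
            has = providers >= 0
            wk = np.zeros(n)
            for i in np.flatnonzero(has):
                wk[i] = cfg.weight_tables.w_k[(pop[i].type, pop[providers[i]].type)]

        for var in ClimateVariable:
            V = self._values[var]
            with np.errstate(invalid="ignore", divide="ignore"):
                hist_mean = (H @ V) / counts[:, None]
            p = V[year_idx][None, :] - hist_mean  # (n, 12); NaN rows undefined
            p_defined = defined
            if cfg.lk_enabled:
                has = providers >= 0
                prov_idx = np.clip(providers, 0, None)
                p_prov = np.where(has[:, None], p[prov_idx], 0.0)
                own = np.where(p_defined[:, None], p, 0.0)
                new_defined = p_defined | (has & (wk > 0))
                blend = has & new_defined
                p = np.where(
                    blend[:, None],
                    wk[:, None] * p_prov + (1.0 - wk[:, None]) * own,
                    p,
                )
                p_defined = new_defined

            mask = p_defined
            if not mask.any():
                self._p_c[var] = np.zeros(12)
                self._degenerate[var] = True
            else:
                w = wp[mask]
                total = w.sum()
                if total > 0:
                    p_c = (w @ p[mask]) / total
                else:
                    p_c = p[mask].mean(axis=0)
                self._p_c[var] = p_c
                self._degenerate[var] = False

            baseline_mean = self._cumsum[var][year_idx - 1] / year_idx
            self._q[var] = V[year_idx] - baseline_mean

    # -- monthly step -------------------------------------------------------

    def step(self) -> list[VulnerabilityRecord]:
        """Advance one month; return the three vulnerability records emitted."""
        if self.year > self.config.sim_end_year:
            raise RuntimeError("simulation window exhausted")
        if self.month == 1:
            self._annual_phase()
        records = []
        for var in ClimateVariable:
            q = float(self._q[var][self.month - 1])
            p_c = float(self._p_c[var][self.month - 1])
            records.append(
                VulnerabilityRecord(
                    variable=var,
                    year=self.year,
                    month=self.month,
                    q=q,
                    p_c=p_c,
                    v=q - p_c,
                    v_abs=abs(q - p_c),
                    degenerate=self._degenerate[var],
                )
            )
        self.month += 1
        if self.month > 12:
            self.month = 1
            self.year += 1
            self.years_elapsed += 1
        return records


def step_month(state: SimulationState) -> list[VulnerabilityRecord]:
    """Advance ``state`` by one month (see :meth:`SimulationState.step`)."""
    return state.step()


def _resolve_series(config: SimulationConfig, seed: int) -> MonthlySeries:
    if isinstance(config.climate, (str, Path)):
        return load_climate_table(config.climate)
    clim_cfg = config.climate
    if not config.freeze_climate:
        clim_cfg = dataclasses.replace(clim_cfg, seed=seed)
    return generate_synthetic_climate(clim_cfg)


def run_simulation(config: SimulationConfig, seed: Optional[int] = None) -> RunResult:
    """Run one full simulation and return its dense vulnerability records."""
    if seed is None:
        seed = config.base_seed
    series = _resolve_series(config, seed)
    state = SimulationState(config, series, seed)
    n_steps = (config.sim_end_year - config.sim_start_year + 1) * 12
    rows = {
        "year": np.empty(n_steps * 3, dtype=int),
        "month": np.empty(n_steps * 3, dtype=int),
        "variable": np.empty(n_steps * 3, dtype=object),
        "q": np.empty(n_steps * 3),
        "P_c": np.empty(n_steps * 3),
        "v": np.empty(n_steps * 3),
        "v_abs": np.empty(n_steps * 3),
        "degenerate": np.empty(n_steps * 3, dtype=bool),
    }
    i = 0
    for _ in range(n_steps):
        for rec in state.step():
            rows["year"][i] = rec.year
            rows["month"][i] = rec.month
            rows["variable"][i] = rec.variable.value
            rows["q"][i] = rec.q
            rows["P_c"][i] = rec.p_c
            rows["v"][i] = rec.v
            rows["v_abs"][i] = rec.v_abs
            rows["degenerate"][i] = rec.degenerate
            i += 1
    frame = pd.DataFrame(rows)
    return RunResult(
        frame=frame,
        scenario=config.scenario,
        lk_enabled=config.lk_enabled,
        seed=seed,
        config=config_to_dict(config),
    )


def run_replicates(config: SimulationConfig) -> AveragedResult:
    """Run ``config.replicates`` replicates (seeds base_seed, base_seed+1, ...)
    and average v and |v| pointwise, with replicate standard deviations."""
    seeds = [config.base_seed + i for i in range(config.replicates)]
    frames = []
    for s in seeds:
        log.info("replicate seed=%d scenario=%s lk=%s", s, config.scenario,
                 config.lk_enabled)
        frames.append(run_simulation(config, seed=s).frame)
    base = frames[0][["year", "month", "variable"]].copy()
    q = np.stack([f["q"].to_numpy() for f in frames])
    p_c = np.stack([f["P_c"].to_numpy() for f in frames])
    v = np.stack([f["v"].to_numpy() for f in frames])
    v_abs = np.stack([f["v_abs"].to_numpy() for f in frames])
    ddof = 1 if len(frames) > 1 else 0
    base["q"] = q.mean(axis=0)
    base["P_c"] = p_c.mean(axis=0)
    base["v"] = v.mean(axis=0)
    base["v_abs"] = v_abs.mean(axis=0)
    base["sd_v"] = v.std(axis=0, ddof=ddof)
    base["sd_v_abs"] = v_abs.std(axis=0, ddof=ddof)
    return AveragedResult(
        frame=base,
        scenario=config.scenario,
        lk_enabled=config.lk_enabled,
        replicates=config.replicates,
        seeds=seeds,
        config=config_to_dict(config),
    )


# -- output ----------------------------------------------------------------


def write_results(result: Union[RunResult, AveragedResult], path: str | Path) -> None:
    """Write results as long-format CSV plus a JSON metadata sidecar.

    The CSV has columns ``scenario,lk,year,month,variable,q,P_c,v,v_abs``
    (plus ``sd_v,sd_v_abs`` for replicate-averaged results); the sidecar
    (same path with ``.meta.json`` suffix) echoes the configuration, every
    seed used, and the package version.
    """
    path = Path(path)
    frame = result.frame.copy()
    frame.insert(0, "scenario", result.scenario)
    frame.insert(1, "lk", result.lk_enabled)
    try:
        frame.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"could not write results to {path}: {exc}") from exc
    meta = {
        "package": "tiedsim",
        "version": __version__,
        "scenario": result.scenario,
        "lk_enabled": result.lk_enabled,
        "seeds": result.seeds if isinstance(result, AveragedResult) else [result.seed],
        "config": result.config,
    }
    if isinstance(result, AveragedResult):
        meta["replicates"] = result.replicates
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)


# -- configuration files ---------------------------------------------------


def _enum_key_map(mapping: Mapping, enum_cls) -> dict:
    out = {}
    for key, value in mapping.items():
        out[enum_cls(key)] = value
    return out


def _community_from_dict(d: Mapping) -> CommunityConfig:
    kwargs: dict = {}
    if "population_size" in d:
        kwargs["population_size"] = int(d["population_size"])
    if "type_proportions" in d:
        kwargs["type_proportions"] = _enum_key_map(d["type_proportions"], AgentType)
    if "age_distribution" in d:
        ad = d["age_distribution"]
        ad_kwargs: dict = {}
        if "class_proportions" in ad:
            ad_kwargs["class_proportions"] = _enum_key_map(
                ad["class_proportions"], AgeClass
            )
        if "class_ranges" in ad:
            ad_kwargs["class_ranges"] = {
                AgeClass(k): (int(v[0]), int(v[1]))
                for k, v in ad["class_ranges"].items()
            }
        kwargs["age_distribution"] = AgeDistribution(**ad_kwargs)
    if "mortality_exponent" in d:
        kwargs["mortality_exponent"] = float(d["mortality_exponent"])
    if "mortality_enabled" in d:
        kwargs["mortality_enabled"] = bool(d["mortality_enabled"])
    return CommunityConfig(**kwargs)


def _climate_from_dict(d: Mapping) -> Union[ClimateGenConfig, str]:
    if isinstance(d, str):
        return d
    if "path" in d:
        return str(d["path"])
    kwargs: dict = {}
    for key in ("start_year", "end_year", "seed"):
        if key in d:
            kwargs[key] = int(d[key])
    if "variables" in d:
        defaults = ClimateGenConfig().variables
        variables = dict(defaults)
        for name, vd in d["variables"].items():
            var = ClimateVariable(name)
            base = dataclasses.asdict(defaults[var])
            base.update(vd)
            variables[var] = VariableGenConfig(**base)
        kwargs["variables"] = variables
    return ClimateGenConfig(**kwargs)


def _weights_from_dict(d: Mapping) -> WeightTables:
    """Flat overrides like ``w_p: {"O.alpha": 1.0}`` or nested class maps."""
    class_names = {"Y": AgeClass.YOUNG, "M": AgeClass.MIDDLE, "O": AgeClass.OLD,
                   "younger": AgeClass.YOUNG, "middle": AgeClass.MIDDLE,
                   "older": AgeClass.OLD}
    wp = dict(WeightTables().w_p)
    wk = dict(WeightTables().w_k)
    for key, value in d.get("w_p", {}).items():
        cls_s, type_s = key.split(".")
        wp[(class_names[cls_s], AgentType(type_s))] = float(value)
    for key, value in d.get("w_k", {}).items():
        rec_s, prov_s = key.split(".")
        wk[(AgentType(rec_s), AgentType(prov_s))] = float(value)
    return WeightTables(w_p=wp, w_k=wk)


def load_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML (or JSON) file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: could not parse: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: configuration must be a mapping")
    known = {"climate", "community", "simulation", "weights"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    kwargs: dict = {}
    try:
        if "climate" in raw:
            kwargs["climate"] = _climate_from_dict(raw["climate"])
        if "community" in raw:
            kwargs["community"] = _community_from_dict(raw["community"])
        if "weights" in raw:
            kwargs["weight_tables"] = _weights_from_dict(raw["weights"])
        sim = raw.get("simulation", {})
        for key in (
            "scenario",
            "lk_enabled",
            "sim_start_year",
            "sim_end_year",
            "history_start_year",
            "replicates",
            "base_seed",
            "freeze_climate",
            "lk_eligibility",
        ):
            if key in sim:
                kwargs[key] = sim[key]
        return SimulationConfig(**kwargs)
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid configuration: {exc}") from exc


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable echo of a configuration (for metadata sidecars)."""
    import enum

    def convert(obj):
        if isinstance(obj, dict):
            return {
                (k.value if isinstance(k, enum.Enum) else str(k)): convert(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, enum.Enum):
            return obj.value
        return obj

    d = dataclasses.asdict(config)
    # mappings with tuple or enum keys (weight tables, climate, community)
    # are rebuilt by hand with flat string keys
    wt = config.weight_tables
    d["weight_tables"] = {
        "w_p": {f"{c.value}.{t.value}": v for (c, t), v in wt.w_p.items()},
        "w_k": {f"{r.value}.{p.value}": v for (r, p), v in wt.w_k.items()},
    }
    if isinstance(config.climate, ClimateGenConfig):
        d["climate"] = {
            "start_year": config.climate.start_year,
            "end_year": config.climate.end_year,
            "seed": config.climate.seed,
            "variables": {
                var.value: dataclasses.asdict(vc)
                for var, vc in config.climate.variables.items()
            },
        }
    d["community"] = {
        "population_size": config.community.population_size,
        "type_proportions": {
            t.value: p for t, p in config.community.type_proportions.items()
        },
        "age_distribution": {
            "class_proportions": {
                c.value: p
                for c, p in config.community.age_distribution.class_proportions.items()
            },
            "class_ranges": {
                c.value: list(r)
                for c, r in config.community.age_distribution.class_ranges.items()
            },
        },
        "mortality_exponent": config.community.mortality_exponent,
        "mortality_enabled": config.community.mortality_enabled,
    }
    return convert(d)
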