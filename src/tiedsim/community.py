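"""Agent population: ages, types, mortality, replacement, resource-use decay.

Each community member is an agent with an integer age (>= 18, the minimum
decision-making age), an age class (Y 18-39, M 40-59, O 60+), a behavioural
type (alpha initiators, beta concerned non-initiators, gamma self-serving)
and a traditional-resource-use fraction t_TRU in [0, 1] that gates how much
of the environment the agent directly experiences.

Mortality follows m = (age / max_age)^e, evaluated once per simulated year
against the current eldest age, so the eldest agent always dies at the
annual update. The population is constant: every deceased agent is replaced
by an 18-year-old of the same type whose t_TRU is the mean over surviving
young-class agents. Scenarios prescribe per-age-class initial t_TRU values
and annual percentage-point declines.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, MutableSequence, Sequence

import numpy as np

__all__ = [
    "AgentType",
    "AgeClass",
    "Agent",
    "ClassSchedule",
    "Scenario",
    "SCENARIOS",
    "AgeDistribution",
    "CommunityConfig",
    "age_class_of",
    "mortality_probability",
    "initialize_community",
    "update_tru",
    "annual_demographic_update",
]


class AgentType(str, enum.Enum):
    ALPHA = "alpha"
    BETA = "beta"
    GAMMA = "gamma"


class AgeClass(str, enum.Enum):
    YOUNG = "Y"
    MIDDLE = "M"
    OLD = "O"


def age_class_of(age: int) -> AgeClass:
    """Map an integer age to its class: Y 18-39, M 40-59, O 60 and over."""
    if age < 18:
        raise ValueError(f"agents must be at least 18 years old, got {age}")
    if age <= 39:
        return AgeClass.YOUNG
    if age <= 59:
        return AgeClass.MIDDLE
    return AgeClass.OLD


@dataclass
class Agent:
    """One community member.

    ``known_history`` is the cumulative set of years the agent has
    experienced (maintained by the perception engine); ``considered_years``
    records which candidate years have already faced their one-off
    admission draw, making memory sticky.
    """

    id: int
    age: int
    type: AgentType
    t_tru: float
    known_history: set[int] = field(default_factory=set)
    considered_years: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("agent age must be >= 18")
        if not 0.0 <= self.t_tru <= 1.0:
            raise ValueError("t_TRU must be in [0, 1]")

    @property
    def age_class(self) -> AgeClass:
        return age_class_of(self.age)


@dataclass(frozen=True)
class ClassSchedule:
    """Initial t_TRU and annual percentage-point decline for one age class."""

    initial_tru: float
    annual_decline: float  # fraction of t_TRU subtracted per year (0.05 = 5 pp)

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_tru <= 1.0:
            raise ValueError("initial_tru must be in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """A named trajectory of per-age-class non-municipal water-system use."""

    id: str
    schedules: Mapping[AgeClass, ClassSchedule]

    def scheduled_tru(self, age_class: AgeClass, years_elapsed: int) -> float:
        """The nominal t_TRU of a class after ``years_elapsed`` annual declines."""
        s = self.schedules[age_class]
        return min(1.0, max(0.0, s.initial_tru - s.annual_decline * years_elapsed))


def _scenario(sid: str, y: tuple, m: tuple, o: tuple) -> Scenario:
    return Scenario(
        sid,
        {
            AgeClass.YOUNG: ClassSchedule(*y),
            AgeClass.MIDDLE: ClassSchedule(*m),
            AgeClass.OLD: ClassSchedule(*o),
        },
    )


#: The six published use scenarios: (initial t_TRU, annual decline) per class.
#: A = perfect knowledge, B = traditional use by all, C = diminishing use by
#: the young, D = diminishing use by the old, E = gradual decline by all,
#: F = rapid decline by all. All annual changes are declines, clamped at 0.
SCENARIOS: dict[str, Scenario] = {
    "A": _scenario("A", (1.0, 0.0), (1.0, 0.0), (1.0, 0.0)),
    "B": _scenario("B", (0.95, 0.0), (0.95, 0.0), (0.95, 0.0)),
    "C": _scenario("C", (0.95, 0.05), (0.95, 0.01), (0.95, 0.0)),
    "D": _scenario("D", (0.95, 0.0), (0.95, 0.01), (0.95, 0.05)),
    "E": _scenario("E", (0.95, 0.04), (0.95, 0.025), (0.95, 0.01)),
    "F": _scenario("F", (0.95, 0.15), (0.95, 0.10), (0.95, 0.05)),
}


def _default_class_proportions() -> dict[AgeClass, float]:
    return {AgeClass.YOUNG: 0.45, AgeClass.MIDDLE: 0.35, AgeClass.OLD: 0.20}


def _default_class_ranges() -> dict[AgeClass, tuple[int, int]]:
    return {
        AgeClass.YOUNG: (18, 39),
        AgeClass.MIDDLE: (40, 59),
        AgeClass.OLD: (60, 80),
    }


@dataclass(frozen=True)
class AgeDistribution:
    """Initial age sampling: per-class mass, uniform integer ages within class."""

    class_proportions: Mapping[AgeClass, float] = field(
        default_factory=_default_class_proportions
    )
    class_ranges: Mapping[AgeClass, tuple[int, int]] = field(
        default_factory=_default_class_ranges
    )

    def __post_init__(self) -> None:
        total = 0.0
        for cls in AgeClass:
            p = self.class_proportions.get(cls, 0.0)
            if p < 0:
                raise ValueError("age-class proportions must be >= 0")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError("age-class proportions must sum to 1")
        for cls, (lo, hi) in self.class_ranges.items():
            if lo > hi:
                raise ValueError(f"empty age range for class {cls.value}")
            if age_class_of(lo) is not cls or (
                cls is not AgeClass.OLD and age_class_of(hi) is not cls
            ):
                raise ValueError(f"age range for class {cls.value} leaves the class")


def _default_type_proportions() -> dict[AgentType, float]:
    return {AgentType.ALPHA: 0.40, AgentType.BETA: 0.40, AgentType.GAMMA: 0.20}


@dataclass(frozen=True)
class CommunityConfig:
    """Population size, composition, and mortality settings.

    The default size matches the smaller of the two study communities; the
    mortality exponent defaults to Euler's number so the ratio age/max_age is
    raised to e, as the model prescribes. Setting ``mortality_enabled`` to
    False freezes the population (used for the perfect-knowledge benchmark).
    """

    population_size: int = 152
    type_proportions: Mapping[AgentType, float] = field(
        default_factory=_default_type_proportions
    )
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    mortality_exponent: float = math.e
    mortality_enabled: bool = True

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        total = 0.0
        for t in AgentType:
            p = self.type_proportions.get(t, 0.0)
            if p < 0:
                raise ValueError("type proportions must be >= 0")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if self.mortality_exponent <= 0:
            raise ValueError("mortality_exponent must be positive")


def mortality_probability(age: int, max_age: int, exponent: float = math.e) -> float:
    """Annual death probability m = (age / max_age)^exponent.

    ``max_age`` is the age of the current eldest community member, so the
    eldest agent's probability is exactly 1.
    """
    if age < 18:
        raise ValueError("age must be >= 18")
    if max_age < age:
        raise ValueError("max_age must be >= age")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    return (age / max_age) ** exponent


def initialize_community(
    cfg: CommunityConfig, scenario: Scenario, rng: np.random.Generator
) -> list[Agent]:
    """Sample an initial population.

    Types and age classes are drawn from the configured proportions, ages
    uniformly within each class range, and every agent starts at its class's
    scenario-initial t_TRU with an empty known history.
    """
    types = list(AgentType)
    type_p = np.array([cfg.type_proportions.get(t, 0.0) for t in types])
    classes = list(AgeClass)
    class_p = np.array(
        [cfg.age_distribution.class_proportions.get(c, 0.0) for c in classes]
    )
    type_draw = rng.choice(len(types), size=cfg.population_size, p=type_p)
    class_draw = rng.choice(len(classes), size=cfg.population_size, p=class_p)
    agents: list[Agent] = []
    for i in range(cfg.population_size):
        cls = classes[class_draw[i]]
        lo, hi = cfg.age_distribution.class_ranges[cls]
        age = int(rng.integers(lo, hi + 1))
        agents.append(
            Agent(
                id=i,
                age=age,
                type=types[type_draw[i]],
                t_tru=scenario.schedules[cls].initial_tru,
            )
        )
    return agents


def update_tru(agent: Agent, scenario: Scenario) -> float:
    """New t_TRU after one year's percentage-point decline, clamped to [0, 1].

    The decline rate is that of the agent's *current* age class, so an agent
    aging into a new class inherits that class's rate going forward.
    """
    decline = scenario.schedules[agent.age_class].annual_decline
    return min(1.0, max(0.0, agent.t_tru - decline))


def annual_demographic_update(
    population: MutableSequence[Agent],
    scenario: Scenario,
    years_elapsed: int,
    rng: np.random.Generator,
    *,
    exponent: float = math.e,
    mortality_enabled: bool = True,
    next_id: int | None = None,
) -> int:
    """Advance the population by one year, in place.

    Order: every agent ages by one year; t_TRU declines per its (new) class
    schedule; deaths are drawn against the post-aging eldest age; each
    deceased agent is replaced by an 18-year-old of the same type whose
    t_TRU is the mean over surviving young-class agents (falling back to the
    scenario's scheduled young-class value if none survive) with an empty
    known history. Population size never changes. Returns the next unused
    agent id.
    """
    if not population:
        raise ValueError("population must be nonempty")
    if next_id is None:
        next_id = max(a.id for a in population) + 1
    for agent in population:
        agent.age += 1
    for agent in population:
        agent.t_tru = update_tru(agent, scenario)
    if not mortality_enabled:
        return next_id
    max_age = max(a.age for a in population)
    # One uniform draw per agent, in population order, for reproducibility.
    dead = [
        i
        for i, a in enumerate(population)
        if rng.random() < mortality_probability(a.age, max_age, exponent)
    ]
    dead_set = set(dead)
    survivors_y = [
        a.t_tru
        for i, a in enumerate(population)
        if i not in dead_set and a.age_class is AgeClass.YOUNG
    ]
    if survivors_y:
        newcomer_tru = float(np.mean(survivors_y))
    else:
        newcomer_tru = scenario.scheduled_tru(AgeClass.YOUNG, years_elapsed)
    for i in dead:
        population[i] = Agent(
            id=next_id,
            age=18,
            type=population[i].type,
            t_tru=newcomer_tru,
        )
        next_id += 1
    return next_id
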