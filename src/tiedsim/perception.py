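"""Individual and community perception of climate change, LK transfer.

An agent's perception of change in a variable is the current month's value
minus the mean of that calendar month over the agent's known history — the
set of past years admitted into memory while the agent was engaged in
traditional resource use. Perceptions can be improved by local-knowledge
(LK) transfer from an agent with a longer history; the amount transferred
depends on the recipient/provider behavioural types. Community perception
is a weighted consensus of individual perceptions, with weights set by age
class and type, and community vulnerability is the gap between recorded and
perceived change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .climate import ClimateVariable, MonthlySeries, NoHistoryError
from .community import Agent, AgeClass, AgentType

__all__ = [
    "WeightTables",
    "PerceptionRecord",
    "VulnerabilityRecord",
    "build_known_history",
    "individual_perception",
    "select_lk_provider",
    "knowledge_transfer_weight",
    "apply_knowledge_transfer",
    "perception_weight",
    "community_perception",
    "vulnerability",
]


def _default_wp() -> dict[tuple[AgeClass, AgentType], float]:
    # Influence on community perception by (age class, type): elders and
    # alpha initiators dominate, young gamma agents carry no weight.
    return {
        (AgeClass.YOUNG, AgentType.ALPHA): 0.6,
        (AgeClass.YOUNG, AgentType.BETA): 0.3,
        (AgeClass.YOUNG, AgentType.GAMMA): 0.0,
        (AgeClass.MIDDLE, AgentType.ALPHA): 0.8,
        (AgeClass.MIDDLE, AgentType.BETA): 0.4,
        (AgeClass.MIDDLE, AgentType.GAMMA): 0.1,
        (AgeClass.OLD, AgentType.ALPHA): 1.0,
        (AgeClass.OLD, AgentType.BETA): 0.8,
        (AgeClass.OLD, AgentType.GAMMA): 0.7,
    }


def _default_wk() -> dict[tuple[AgentType, AgentType], float]:
    # Knowledge passed from provider (column) to recipient (row): full
    # between alphas, diminished through betas, minimal from a gamma
    # provider, and none at all to a gamma recipient.
    return {
        (AgentType.ALPHA, AgentType.ALPHA): 1.0,
        (AgentType.ALPHA, AgentType.BETA): 0.8,
        (AgentType.ALPHA, AgentType.GAMMA): 0.5,
        (AgentType.BETA, AgentType.ALPHA): 0.8,
        (AgentType.BETA, AgentType.BETA): 0.5,
        (AgentType.BETA, AgentType.GAMMA): 0.3,
        (AgentType.GAMMA, AgentType.ALPHA): 0.0,
        (AgentType.GAMMA, AgentType.BETA): 0.0,
        (AgentType.GAMMA, AgentType.GAMMA): 0.0,
    }


@dataclass(frozen=True)
class WeightTables:
    """The two model weight tables.

    ``w_p`` maps (age class, agent type) to an influence weight on community
    perception; ``w_k`` maps (recipient type, provider type) to the fraction
    of knowledge transferred. Both live in [0, 1].
    """

    w_p: Mapping[tuple[AgeClass, AgentType], float] = field(default_factory=_default_wp)
    w_k: Mapping[tuple[AgentType, AgentType], float] = field(default_factory=_default_wk)

    def __post_init__(self) -> None:
        for cls in AgeClass:
            for t in AgentType:
                v = self.w_p.get((cls, t))
                if v is None or not 0.0 <= v <= 1.0:
                    raise ValueError(f"w_p[{cls.value},{t.value}] missing or outside [0,1]")
        for r in AgentType:
            for p in AgentType:
                v = self.w_k.get((r, p))
                if v is None or not 0.0 <= v <= 1.0:
                    raise ValueError(f"w_k[{r.value},{p.value}] missing or outside [0,1]")

    @classmethod
    def default(cls) -> "WeightTables":
        return cls()


@dataclass(frozen=True)
class PerceptionRecord:
    """One agent's perceived change in one variable at one monthly step."""

    agent_id: int
    variable: ClimateVariable
    year: int
    month: int
    p: Optional[float]
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and self.p is None:
            raise ValueError("defined perception must carry a value")


@dataclass(frozen=True)
class VulnerabilityRecord:
    """Recorded change, community perception, and their gap at one step."""

    variable: ClimateVariable
    year: int
    month: int
    q: float
    p_c: float
    v: float
    v_abs: float
    degenerate: bool = False  # True when no agent held a defined perception

    def __post_init__(self) -> None:
        if abs(self.v - (self.q - self.p_c)) > 1e-12:
            raise ValueError("v must equal q - P_c")
        if abs(self.v_abs - abs(self.v)) > 1e-12:
            raise ValueError("v_abs must equal |v|")


def build_known_history(
    agent: Agent,
    current_year: int,
    series_start: int,
    rng: np.random.Generator,
) -> set[int]:
    """Extend an agent's known history up to (but excluding) the current year.

    Candidate years are those the agent could have experienced since turning
    18 that lie within the series. Each candidate faces a single admission
    draw the first time it becomes eligible: it enters the history iff the
    agent's current t_TRU exceeds a Uniform[0, 1) draw. Admitted years are
    kept forever (memory is sticky); rejected years are never reconsidered.
    Returns the cumulative history.
    """
    earliest = max(series_start, current_year - (agent.age - 18))
    for year in range(earliest, current_year):
        if year in agent.considered_years:
            continue
        delta = rng.random()
        if agent.t_tru > delta:
            agent.known_history.add(year)
        agent.considered_years.add(year)
    return set(agent.known_history)


def individual_perception(
    agent: Agent,
    series: MonthlySeries,
    var: ClimateVariable,
    month: int,
    current_year: int,
) -> PerceptionRecord:
    """Perceived change: current value minus the agent's own historical mean.

    The current-month observation is available to every agent regardless of
    t_TRU; only the historical reference depends on the known history. With
    an empty history the perception is undefined rather than an error.
    """
    if not agent.known_history:
        return PerceptionRecord(agent.id, var, current_year, month, None, False)
    current = series.value(var, current_year, month)
    from .climate import historical_monthly_mean

    hist = historical_monthly_mean(series, var, month, agent.known_history)
    return PerceptionRecord(agent.id, var, current_year, month, current - hist, True)


def _history_measure(agent: Agent, eligibility: str) -> int:
    if eligibility == "count":
        return len(agent.known_history)
    if eligibility == "span":
        if not agent.known_history:
            return -1
        return max(agent.known_history) - min(agent.known_history)
    raise ValueError(f"unknown eligibility measure {eligibility!r}")


def select_lk_provider(
    agent: Agent,
    population: Sequence[Agent],
    *,
    eligibility: str = "count",
) -> Optional[Agent]:
    """Pick the local-knowledge provider for ``agent``, or None.

    Eligible providers are other agents whose known history strictly exceeds
    the recipient's (by year count by default; by year span with
    ``eligibility='span'``). Among them the provider maximises
    (age / eldest age) * t_TRU — experience weighted by current engagement —
    with ties broken by the smallest agent id.
    """
    if not population:
        raise ValueError("population must be nonempty")
    max_age = max(a.age for a in population)
    mine = _history_measure(agent, eligibility)
    best: Optional[Agent] = None
    best_score = -1.0
    for other in population:
        if other.id == agent.id:
            continue
        if _history_measure(other, eligibility) <= mine:
            continue
        score = (other.age / max_age) * other.t_tru
        if best is None or score > best_score or (
            score == best_score and other.id < best.id
        ):
            best = other
            best_score = score
    return best


def knowledge_transfer_weight(
    recipient_type: AgentType,
    provider_type: AgentType,
    tables: WeightTables,
) -> float:
    """w_k for a (recipient, provider) type pair."""
    return tables.w_k[(AgentType(recipient_type), AgentType(provider_type))]


def apply_knowledge_transfer(
    own: PerceptionRecord,
    provider: PerceptionRecord,
    w_k: float,
) -> PerceptionRecord:
    """Blend a recipient's perception with its provider's.

    The result is the convex combination w_k * p_provider + (1 - w_k) * p_own.
    A recipient with no perception of its own adopts w_k * p_provider and
    becomes defined whenever w_k > 0; with w_k = 0 nothing changes.
    """
    if not provider.defined:
        raise ValueError("provider perception must be defined")
    if not 0.0 <= w_k <= 1.0:
        raise ValueError("w_k must be in [0, 1]")
    if own.defined:
        blended = w_k * provider.p + (1.0 - w_k) * own.p
        return replace(own, p=blended)
    if w_k > 0.0:
        return replace(own, p=w_k * provider.p, defined=True)
    return own


def perception_weight(agent: Agent, tables: WeightTables) -> float:
    """w_p for an agent, looked up by (age class, type)."""
    return tables.w_p[(agent.age_class, agent.type)]


def community_perception(
    records: Sequence[PerceptionRecord],
    weights: Sequence[float],
) -> float:
    """Normalized weighted mean of the defined individual perceptions.

    P_c = sum(w_i p_i) / sum(w_i) over agents with a defined perception.
    If every participating weight is zero the unweighted mean is used; if no
    perception is defined the community perception is 0 (the caller flags
    the step as degenerate).
    """
    if len(records) != len(weights):
        raise ValueError("records and weights must be aligned")
    ps = [r.p for r, w in zip(records, weights) if r.defined]
    ws = [w for r, w in zip(records, weights) if r.defined]
    if not ps:
        return 0.0
    total = sum(ws)
    if total == 0.0:
        return float(np.mean(ps))
    return float(sum(w * p for w, p in zip(ws, ps)) / total)


def vulnerability(q: float, p_c: float) -> tuple[float, float]:
    """Community vulnerability v = q - P_c and its magnitude.

    Positive v means the community under-perceives the recorded change;
    larger |v| means a community whose view of its climate is further from
    what is actually happening.
    """
    v = q - p_c
    return v, abs(v)
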