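"""Population-level success measures for a (snapshot of a) simulation.

Three end-of-run measures, each split by difficulty class and reported in
absolute and relative form:

(i)   *successful conventions per agent* — the mean, over agents, of the
      number of currently-held conventions that at least one neighbour knows
      (by default "knows" means has ever learned or generated it since its
      last rebirth; a stricter currently-holds basis is also available);
(ii)  *population-shared conventions* — the number of conventions currently
      held by at least a given fraction of the population (default 10%);
(iii) *neighbour sharing* — over all (agent, currently-held convention)
      pairs, the mean fraction of that agent's neighbours currently holding
      the convention.

All functions take any state object exposing ``agents`` (list of
:class:`~iapsim.core.AgentState`), ``adjacency`` (neighbour lists),
``registry`` and ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable

import pandas as pd

from .core import EASY, HARD

__all__ = [
    "MEASURE_SUCCESSFUL",
    "MEASURE_SHARED",
    "MEASURE_NEIGHBOUR",
    "MetricsRecord",
    "successful_per_agent",
    "population_shared",
    "neighbour_sharing",
    "relative_split",
    "collect_records",
    "records_to_frame",
]

MEASURE_SUCCESSFUL = "successful-per-agent"
MEASURE_SHARED = "population-shared"
MEASURE_NEIGHBOUR = "neighbour-sharing"


@dataclass(frozen=True)
class MetricsRecord:
    """One measure value for one class in one run snapshot."""

    measure: str
    convention_class: str
    normalization: str  # "absolute" | "relative"
    value: float
    knowledge_basis: str = "-"  # "historical" | "current" for measure (i)
    iteration: int | None = None
    n: int | None = None
    p: float | None = None
    mode: str | None = None
    run_id: int | None = None
    network_id: int | None = None


def relative_split(easy: float, hard: float) -> tuple[float, float]:
    """Proportions ``(e/(e+h), h/(e+h))``; ``(0, 0)`` when both are zero."""
    if easy < 0 or hard < 0:
        raise ValueError("counts must be non-negative")
    total = easy + hard
    if total == 0:
        return (0.0, 0.0)
    return (easy / total, hard / total)


def _pair(absolute: dict[str, float]) -> dict[str, dict[str, float]]:
    rel = relative_split(absolute[EASY], absolute[HARD])
    return {"absolute": absolute, "relative": {EASY: rel[0], HARD: rel[1]}}


def successful_per_agent(state, knowledge_basis: str = "historical") -> dict:
    """Per-class mean count of 'successful' conventions per agent.

    A currently-held convention is successful for an agent when at least one
    neighbour has it in its knowledge basis: ``historical`` uses the
    neighbour's ``ever_known`` (learned or generated at some point since its
    last rebirth), ``current`` the neighbour's current tables.  The mean runs
    over all agents, empty repertoires included.
    """
    if knowledge_basis not in ("historical", "current"):
        raise ValueError(
            f"knowledge_basis must be 'historical' or 'current', "
            f"got {knowledge_basis!r}"
        )
    agents = state.agents
    adjacency = state.adjacency
    class_of = state.registry.class_of
    if knowledge_basis == "historical":
        basis = [a.ever_known for a in agents]
    else:
        basis = [a.token_counts.keys() for a in agents]
    totals = {EASY: 0, HARD: 0}
    for i, agent in enumerate(agents):
        nbrs = adjacency[i]
        for cid in agent.token_counts:
            if any(cid in basis[j] for j in nbrs):
                totals[class_of(cid)] += 1
    n = len(agents)
    return _pair({EASY: totals[EASY] / n, HARD: totals[HARD] / n})


def shared_threshold(fraction: float, n: int) -> int:
    """Minimum holder count: ``ceil(fraction * n)`` (float-noise guarded)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, math.ceil(fraction * n - 1e-9))


def population_shared(state, fraction: float = 0.10) -> dict:
    """Per-class count of conventions held by >= ceil(fraction*n) agents."""
    need = shared_threshold(fraction, state.n)
    holders: dict[int, int] = {}
    for agent in state.agents:
        for cid in agent.token_counts:
            holders[cid] = holders.get(cid, 0) + 1
    class_of = state.registry.class_of
    counts = {EASY: 0, HARD: 0}
    for cid, h in holders.items():
        if h >= need:
            counts[class_of(cid)] += 1
    return _pair({EASY: float(counts[EASY]), HARD: float(counts[HARD])})


def neighbour_sharing(state) -> dict:
    """Mean fraction of neighbours sharing each (agent, convention) pair.

    Pairs are weighted equally; agents with empty repertoires contribute no
    pairs.  A class with no pairs at all yields ``nan`` for its mean.
    """
    agents = state.agents
    adjacency = state.adjacency
    class_of = state.registry.class_of
    sums = {EASY: 0.0, HARD: 0.0}
    counts = {EASY: 0, HARD: 0}
    for i, agent in enumerate(agents):
        nbrs = adjacency[i]
        if not nbrs:
            continue
        inv_deg = 1.0 / len(nbrs)
        for cid in agent.token_counts:
            sharing = sum(1 for j in nbrs if cid in agents[j].token_counts)
            cls = class_of(cid)
            sums[cls] += sharing * inv_deg
            counts[cls] += 1
    means = {
        cls: (sums[cls] / counts[cls]) if counts[cls] else float("nan")
        for cls in (EASY, HARD)
    }
    easy = means[EASY] if counts[EASY] else 0.0
    hard = means[HARD] if counts[HARD] else 0.0
    rel = relative_split(easy, hard)
    return {"absolute": means, "relative": {EASY: rel[0], HARD: rel[1]}}


def collect_records(
    state,
    iteration: int | None = None,
    *,
    fraction: float = 0.10,
    run_keys: dict | None = None,
) -> list[MetricsRecord]:
    """All three measures as tidy records (measure (i) in both bases)."""
    run_keys = run_keys or {}
    out: list[MetricsRecord] = []

    def emit(measure: str, result: dict, basis: str = "-") -> None:
        for norm in ("absolute", "relative"):
            for cls in (EASY, HARD):
                out.append(
                    MetricsRecord(
                        measure=measure,
                        convention_class=cls,
                        normalization=norm,
                        value=float(result[norm][cls]),
                        knowledge_basis=basis,
                        iteration=iteration,
                        **run_keys,
                    )
                )

    for basis in ("historical", "current"):
        emit(MEASURE_SUCCESSFUL, successful_per_agent(state, basis), basis)
    emit(MEASURE_SHARED, population_shared(state, fraction))
    emit(MEASURE_NEIGHBOUR, neighbour_sharing(state))
    return out


def records_to_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """Long-form tidy DataFrame, one row per record."""
    return pd.DataFrame([asdict(r) for r in records])
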