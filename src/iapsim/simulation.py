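"""Iteration protocol for the innovate-and-propagate model.

Per iteration every agent speaks exactly once, in a fresh uniformly random
order: it draws a production from its own restaurant (possibly inventing),
seats the produced token in its own restaurant, and delivers the utterance to
one uniformly chosen network neighbour, who processes it as a heard exposure.

Token loss depends on the transmission mode.  In *horizontal* mode a
forgetting sweep (each stored token lost independently with probability
``p``) runs on every token-adding event — the speaker's own production and
any accepted reception — against the tokens stored before the new token is
seated, which puts the per-agent memory load in balance at ``M * p = 1``.
In *vertical* mode there is no forgetting; instead, after conveying its
utterance the speaker dies with probability ``p`` and is replaced in place by
a blank slate.

Updates are asynchronous by default (a listener can reuse within the same
iteration what it just learned); a synchronous option draws all productions
against the iteration-start repertoires for sensitivity analysis.  All
randomness flows through five named streams spawned from one seed, so runs
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .core import (
    AgentState,
    ConventionRegistry,
    LearningThresholds,
    draw_production,
    _draw_from_tokens,
    forgetting_sweep,
    kill,
    receive,
    seat_token,
)
from .metrics import MetricsRecord, collect_records, records_to_frame

__all__ = [
    "HORIZONTAL",
    "VERTICAL",
    "SimulationConfig",
    "SimulationState",
    "RunResult",
    "step",
    "run",
    "state_to_dict",
    "state_from_dict",
]

HORIZONTAL = "horizontal"
VERTICAL = "vertical"

_STREAMS = ("scheduling", "production", "class", "forgetting", "death")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one run.

    ``p`` is the per-token forgetting probability (horizontal) or the
    per-utterance die-off probability (vertical).  ``metric_cadence = 0``
    snapshots metrics at the final iteration only.
    """

    mode: str
    p: float
    iterations: int = 1000
    thresholds: LearningThresholds = field(default_factory=LearningThresholds)
    class_prob: float = 0.5
    seed: int = 0
    metric_cadence: int = 0
    synchronous: bool = False
    success_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in (HORIZONTAL, VERTICAL):
            raise ValueError(
                f"mode must be {HORIZONTAL!r} or {VERTICAL!r}, got {self.mode!r}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if not 0.0 <= self.class_prob <= 1.0:
            raise ValueError(f"class_prob must be in [0, 1], got {self.class_prob}")
        if self.metric_cadence < 0:
            raise ValueError(
                f"metric_cadence must be >= 0, got {self.metric_cadence}"
            )
        if not 0.0 < self.success_fraction <= 1.0:
            raise ValueError(
                f"success_fraction must be in (0, 1], got {self.success_fraction}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        thr = data.get("thresholds")
        if isinstance(thr, dict):
            data["thresholds"] = LearningThresholds(**thr)
        return cls(**data)


class SimulationState:
    """Mutable state of a running simulation: network, agents, registry, RNG."""

    def __init__(
        self,
        network: nx.Graph,
        config: SimulationConfig,
        *,
        registry: ConventionRegistry | None = None,
        agents: list[AgentState] | None = None,
        iteration: int = 0,
    ) -> None:
        n = network.number_of_nodes()
        if sorted(network.nodes()) != list(range(n)):
            raise ValueError("network nodes must be labelled 0..n-1")
        self.network = network
        self.n = n
        self.adjacency: list[list[int]] = [
            sorted(network.neighbors(i)) for i in range(n)
        ]
        isolated = [i for i, nb in enumerate(self.adjacency) if not nb]
        if isolated:
            raise ValueError(
                f"isolated node(s) {isolated[:5]}: every agent needs at least "
                "one neighbour to speak to"
            )
        self.config = config
        self.registry = registry or ConventionRegistry(config.class_prob)
        self.agents = agents if agents is not None else [AgentState() for _ in range(n)]
        if len(self.agents) != n:
            raise ValueError("agent count must equal network node count")
        self.iteration = iteration
        streams = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
        self.rng = {
            name: np.random.default_rng(s) for name, s in zip(_STREAMS, streams)
        }


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one iteration (every agent speaks once)."""
    cfg = state.config
    horizontal = cfg.mode == HORIZONTAL
    p = cfg.p
    agents = state.agents
    adjacency = state.adjacency
    registry = state.registry
    thresholds = cfg.thresholds
    sched = state.rng["scheduling"]
    prod = state.rng["production"]
    cls_rng = state.rng["class"]
    forget = state.rng["forgetting"]
    death = state.rng["death"]

    n = state.n
    order = sched.permutation(n)
    pick = sched.random(n)  # one uniform per speaker for neighbour choice
    deaths = death.random(n) if (not horizontal and p > 0.0) else None
    snapshot = None
    if cfg.synchronous:
        snapshot = [list(a.tokens) for a in agents]

    for slot in range(n):
        i = int(order[slot])
        speaker = agents[i]
        if snapshot is not None:
            cid = _draw_from_tokens(snapshot[i], registry, prod, cls_rng)
        else:
            cid = draw_production(speaker, registry, prod, cls_rng)
        if horizontal and p > 0.0:
            forgetting_sweep(speaker, p, forget)
        seat_token(speaker, cid)
        nbrs = adjacency[i]
        j = nbrs[int(pick[slot] * len(nbrs))]
        convention = registry.convention(cid)
        if horizontal:
            receive(
                agents[j],
                convention,
                thresholds,
                forget_p=p,
                forget_rng=forget,
            )
        else:
            receive(agents[j], convention, thresholds)
            if deaths is not None and deaths[slot] < p:
                kill(speaker)
    state.iteration += 1
    return state


@dataclass
class RunResult:
    """Final state plus the metric snapshot series of one run."""

    state: SimulationState
    records: list[MetricsRecord]
    mean_tokens: np.ndarray  # population-mean M after each iteration
    config: SimulationConfig

    @property
    def snapshots(self):
        """Metric snapshots as a tidy DataFrame."""
        return records_to_frame(self.records)


def run(
    network: nx.Graph,
    config: SimulationConfig,
    *,
    run_keys: dict | None = None,
) -> RunResult:
    """Execute ``config.iterations`` iterations on ``network``.

    Metric snapshots are taken every ``metric_cadence`` iterations (if
    non-zero) and always at the final iteration.  The per-iteration
    population-mean token count is recorded throughout, which is what the
    ``M * p = 1`` balance diagnostic is computed from.
    """
    state = SimulationState(network, config)
    base_keys = {"n": state.n, "p": config.p, "mode": config.mode}
    base_keys.update(run_keys or {})
    records: list[MetricsRecord] = []
    mean_tokens = np.empty(config.iterations)
    cadence = config.metric_cadence
    for it in range(1, config.iterations + 1):
        step(state)
        mean_tokens[it - 1] = sum(a.M for a in state.agents) / state.n
        if cadence and it % cadence == 0 and it != config.iterations:
            records.extend(
                collect_records(
                    state,
                    iteration=it,
                    fraction=config.success_fraction,
                    run_keys=base_keys,
                )
            )
    records.extend(
        collect_records(
            state,
            iteration=config.iterations,
            fraction=config.success_fraction,
            run_keys=base_keys,
        )
    )
    return RunResult(
        state=state, records=records, mean_tokens=mean_tokens, config=config
    )


# ---------------------------------------------------------------------------
# checkpointing


def state_to_dict(state: SimulationState) -> dict:
    """JSON-serializable snapshot (agents, registry, network, RNG streams)."""
    return {
        "iteration": state.iteration,
        "config": state.config.to_dict(),
        "network": {
            "n": state.n,
            "edges": sorted([int(u), int(v)] for u, v in state.network.edges()),
        },
        "registry": state.registry.to_dict(),
        "agents": [a.to_dict() for a in state.agents],
        "rng": {name: gen.bit_generator.state for name, gen in state.rng.items()},
    }


def state_from_dict(data: dict, network: nx.Graph | None = None) -> SimulationState:
    """Rebuild a state snapshot; RNG streams are restored, so runs resume."""
    if network is None:
        network = nx.Graph()
        network.add_nodes_from(range(data["network"]["n"]))
        network.add_edges_from(data["network"]["edges"])
    config = SimulationConfig.from_dict(data["config"])
    state = SimulationState(
        network,
        config,
        registry=ConventionRegistry.from_dict(data["registry"]),
        agents=[AgentState.from_dict(a) for a in data["agents"]],
        iteration=data["iteration"],
    )
    for name, gen_state in data["rng"].items():
        state.rng[name].bit_generator.state = gen_state
    return state
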