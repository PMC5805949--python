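"""Small deterministic structures with known metrics, for tests and demos."""

from __future__ import annotations

import networkx as nx

from .simulation import SimulationConfig, SimulationState

__all__ = ["FIXTURE_KINDS", "make_fixture", "make_fixture_state"]

FIXTURE_KINDS = ("ring", "complete", "star", "two-agent")


def make_fixture(kind: str, size: int | None = None) -> nx.Graph:
    """A canonical small network: ring, complete, star, or two-agent.

    ``size`` is the total node count; the star has one hub (node 0) and
    ``size - 1`` leaves.  The two-agent network ignores ``size``.
    """
    if kind == "two-agent":
        if size not in (None, 2):
            raise ValueError("two-agent fixture has exactly 2 nodes")
        return nx.path_graph(2)
    if size is None:
        raise ValueError(f"fixture kind {kind!r} requires a size")
    if kind == "ring":
        if size < 3:
            raise ValueError(f"ring needs >= 3 nodes, got {size}")
        return nx.cycle_graph(size)
    if kind == "complete":
        if size < 2:
            raise ValueError(f"complete graph needs >= 2 nodes, got {size}")
        return nx.complete_graph(size)
    if kind == "star":
        if size < 2:
            raise ValueError(f"star needs >= 2 nodes, got {size}")
        return nx.star_graph(size - 1)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def make_fixture_state(
    kind: str, size: int | None, config: SimulationConfig
) -> SimulationState:
    """A fresh (all-agents-empty) simulation state on a fixture network."""
    return SimulationState(make_fixture(kind, size), config)
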