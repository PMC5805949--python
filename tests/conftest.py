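import networkx as nx
import pytest

from iapsim import (
    AgentState,
    ConventionRegistry,
    SimulationConfig,
    SimulationState,
)


def build_state(graph, repertoires, classes, *, ever_known=None, config=None):
    """Hand-built simulation state for metric tests.

    ``repertoires`` is one token-count dict per node; ``classes`` maps each
    convention id (list index) to "Easy"/"Hard"; ``ever_known`` optionally
    widens an agent's historical knowledge beyond its current tables.
    """
    if config is None:
        config = SimulationConfig(mode="horizontal", p=0.0, iterations=1)
    registry = ConventionRegistry.from_dict({"classes": list(classes)})
    agents = []
    for i, counts in enumerate(repertoires):
        known = set(counts)
        if ever_known is not None:
            known |= set(ever_known[i])
        agents.append(
            AgentState(
                token_counts=dict(counts),
                M=sum(counts.values()),
                ever_known=known,
            )
        )
    return SimulationState(graph, config, registry=registry, agents=agents)


@pytest.fixture
def path3():
    return nx.path_graph(3)


@pytest.fixture
def two_agent():
    return nx.path_graph(2)
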