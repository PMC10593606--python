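import networkx as nx
import numpy as np
import pytest

from coopnet.game import GameState


def make_state(n, edges, actions=None, round_t=2, capital=None):
    """Build a GameState directly from an edge list and action vector."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return GameState(
        round_t=round_t,
        graph=g,
        last_action=None if actions is None else np.asarray(actions),
        capital=np.zeros(n) if capital is None else np.asarray(capital, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(rng, n=None, round_t=2):
    """A random valid mid-game state for property tests."""
    if n is None:
        n = int(rng.integers(2, 12))
    g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9), seed=int(rng.integers(2**31)))
    g.add_nodes_from(range(n))
    return GameState(
        round_t=round_t,
        graph=g,
        last_action=rng.integers(0, 2, size=n),
        capital=rng.normal(size=n),
    )
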