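"""Turn-based network cooperation game engine.

Players occupy the vertices of a simple undirected graph. Each round every
player simultaneously chooses to cooperate or defect. Cooperation costs a
fixed amount ``c`` per linked neighbour and pays every neighbour a fixed
benefit ``b`` (with ``b > c``, so mutual cooperation is net-positive for the
group while defection is individually tempting). After payoffs, a social
planner observes the graph and the fresh decisions and recommends edge
additions/deletions; the affected players accept or reject, and the graph is
rewired before the next round begins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import networkx as nx
import numpy as np

ADD = "add"
DELETE = "delete"

_VALENCES = (ADD, DELETE)


def _normalize_pair(pair: tuple[int, int]) -> tuple[int, int]:
    i, j = pair
    if i == j:
        raise ValueError(f"self-pair ({i}, {j}) is not a valid player pair")
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Recommendation:
    """A candidate edge change proposed by the planner.

    ``valence`` is ``"add"`` for a pair that is currently unlinked and
    ``"delete"`` for an existing edge; validity against the current graph is
    enforced when the recommendation is resolved.
    """

    pair: tuple[int, int]
    valence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", _normalize_pair(self.pair))
        if self.valence not in _VALENCES:
            raise ValueError(f"valence must be one of {_VALENCES}, got {self.valence!r}")


@dataclass
class GameConfig:
    """Static parameters of one game.

    ``cost_c`` is the per-neighbour cost of cooperating and ``benefit_b`` the
    per-neighbour benefit conferred, both in capital units per round. The
    defaults (16 players, 15 rounds, c = 0.05, b = 0.1) are the experimental
    conditions this engine models.
    """

    n_players: int = 16
    n_rounds: int = 15
    cost_c: float = 0.05
    benefit_b: float = 0.1
    initial_graph: str = "erdos_renyi"
    initial_graph_params: dict = field(default_factory=lambda: {"p": 0.3})
    rng_seed: int = 0
    # Link formation is bilateral (both endpoints must accept); severance is
    # unilateral (one acceptance suffices). Both switches are exposed.
    add_requires_both: bool = True
    delete_requires_both: bool = False

    def __post_init__(self) -> None:
        if self.n_players < 2:
            raise ValueError("n_players must be >= 2")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.cost_c <= 0:
            raise ValueError("cost_c must be positive")
        if self.benefit_b <= self.cost_c:
            raise ValueError("benefit_b must exceed cost_c")

    def build_initial_graph(self) -> nx.Graph:
        return build_graph(
            self.initial_graph, self.n_players, self.initial_graph_params, self.rng_seed
        )


def build_graph(generator: str, n: int, params: Mapping, seed: int) -> nx.Graph:
    """Build a seeded simple starting topology by generator name."""
    if generator == "erdos_renyi":
        g = nx.gnp_random_graph(n, params.get("p", 0.3), seed=seed)
    elif generator == "empty":
        g = nx.empty_graph(n)
    elif generator == "complete":
        g = nx.complete_graph(n)
    elif generator == "ring":
        g = nx.cycle_graph(n)
    elif generator == "regular":
        g = nx.random_regular_graph(params["d"], n, seed=seed)
    else:
        raise ValueError(f"unknown initial-graph generator {generator!r}")
    g.add_nodes_from(range(n))
    return g


@dataclass
class GameState:
    """Mutable per-round state: graph, last decisions and cumulative capital.

    ``last_action[i]`` is 1 if player ``i`` cooperated in the most recent
    action phase and 0 otherwise; it is ``None`` before the first action
    phase resolves. Capital may go negative.
    """

    round_t: int
    graph: nx.Graph
    last_action: np.ndarray | None
    capital: np.ndarray

    @property
    def n_players(self) -> int:
        return self.graph.number_of_nodes()

    def copy(self) -> "GameState":
        return GameState(
            round_t=self.round_t,
            graph=self.graph.copy(),
            last_action=None if self.last_action is None else self.last_action.copy(),
            capital=self.capital.copy(),
        )

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("graph contains a self-loop")


def initial_state(config: GameConfig) -> GameState:
    g = config.build_initial_graph()
    return GameState(
        round_t=1,
        graph=g,
        last_action=None,
        capital=np.zeros(config.n_players),
    )


@dataclass
class GameLogRecord:
    """One round of play, sufficient to replay and to re-analyse.

    ``edges`` is the graph on which the round's actions and recommendations
    were made (i.e. after the previous round's rewiring); ``edges_after`` is
    the graph left for the next round.
    """

    round_t: int
    actions: list[int]
    payoffs: list[float]
    capital: list[float]
    edges: list[tuple[int, int]]
    recommendations: list[dict]
    changes: list[dict]
    edges_after: list[tuple[int, int]]

    def to_json(self) -> str:
        d = {
            "round": self.round_t,
            "actions": self.actions,
            "payoffs": self.payoffs,
            "capital": self.capital,
            "edges": [list(e) for e in self.edges],
            "recommendations": self.recommendations,
            "changes": self.changes,
            "edges_after": [list(e) for e in self.edges_after],
        }
        return json.dumps(d, separators=(",", ":"))

    @classmethod
    def from_json(cls, line: str) -> "GameLogRecord":
        d = json.loads(line)
        return cls(
            round_t=d["round"],
            actions=d["actions"],
            payoffs=d["payoffs"],
            capital=d["capital"],
            edges=[tuple(e) for e in d["edges"]],
            recommendations=d["recommendations"],
            changes=d["changes"],
            edges_after=[tuple(e) for e in d["edges_after"]],
        )


def write_log(records: Sequence[GameLogRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_log(path) -> list[GameLogRecord]:
    with open(path) as fh:
        return [GameLogRecord.from_json(line) for line in fh if line.strip()]


def export_edge_list(record: GameLogRecord, path) -> None:
    """Write the round's pre-rewiring graph as a two-column CSV edge list."""
    with open(path, "w") as fh:
        fh.write("source,target\n")
        for u, v in record.edges:
            fh.write(f"{u},{v}\n")


def export_graphml(record: GameLogRecord, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(range(len(record.actions)))
    g.add_edges_from(record.edges)
    for i, a in enumerate(record.actions):
        g.nodes[i]["last_action"] = int(a)
    nx.write_graphml(g, path)


def payoff_phase(state: GameState, actions: np.ndarray, cost_c: float, benefit_b: float) -> np.ndarray:
    """Apply one round of payoffs in place and return per-player deltas.

    delta(i) = -c * deg(i) * [i cooperates] + b * (# cooperating neighbours).
    Defectors pay nothing and confer nothing.
    """
    actions = np.asarray(actions)
    n = state.n_players
    if actions.shape != (n,):
        raise ValueError(f"action vector has shape {actions.shape}, expected ({n},)")
    if not np.isin(actions, (0, 1)).all():
        raise ValueError("actions must be binary (1 = cooperate, 0 = defect)")
    adj = nx.to_numpy_array(state.graph, nodelist=range(n))
    deg = adj.sum(axis=1)
    coop = actions.astype(float)
    delta = -cost_c * deg * coop + benefit_b * (adj @ coop)
    state.capital += delta
    return delta


def resolve_recommendations(
    state: GameState,
    recs: Sequence[Recommendation],
    decisions: Mapping[tuple[int, int], tuple[bool, bool]],
    add_requires_both: bool = True,
    delete_requires_both: bool = False,
) -> list[dict]:
    """Apply accepted recommendations to the graph; return the change log.

    ``decisions[pair]`` holds the (lower-id endpoint, higher-id endpoint)
    accept flags. An ``add`` executes iff both endpoints accept; a ``delete``
    executes iff at least one accepts (defaults; both switchable).
    """
    n = state.n_players
    seen: set[tuple[int, int]] = set()
    changes: list[dict] = []
    for rec in recs:
        i, j = rec.pair
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"recommendation references unknown player in pair {rec.pair}")
        if rec.pair in seen:
            raise ValueError(f"duplicate recommendation for pair {rec.pair}")
        seen.add(rec.pair)
        has_edge = state.graph.has_edge(i, j)
        if rec.valence == ADD and has_edge:
            raise ValueError(f"add recommended for existing edge {rec.pair}")
        if rec.valence == DELETE and not has_edge:
            raise ValueError(f"delete recommended for absent edge {rec.pair}")
        acc_i, acc_j = decisions[rec.pair]
        require_both = add_requires_both if rec.valence == ADD else delete_requires_both
        executed = (acc_i and acc_j) if require_both else (acc_i or acc_j)
        if executed:
            if rec.valence == ADD:
                state.graph.add_edge(i, j)
            else:
                state.graph.remove_edge(i, j)
            changes.append({"pair": [i, j], "valence": rec.valence})
    state.validate()
    return changes


class PlannerPolicy(Protocol):
    """Contract for social planners: observe a state, emit recommendations."""

    name: str

    def recommend(self, state: GameState) -> list[Recommendation]: ...


class Population(Protocol):
    """A full set of players: action sampling plus accept/reject decisions."""

    def act(self, state: GameState) -> np.ndarray: ...

    def decide(self, rec: Recommendation, state: GameState) -> tuple[bool, bool]: ...


def run_game(
    config: GameConfig,
    planner: PlannerPolicy,
    population: Population,
    collect_states: bool = False,
) -> list[GameLogRecord]:
    """Play one full game and return its per-round log.

    Round order: act -> payoff -> planner recommends -> accept/reject ->
    rewire. The planner therefore always sees the current round's decisions,
    including in round 1. The run is a pure function of (config, planner,
    population): identical inputs give byte-identical logs.
    """
    state = initial_state(config)
    records: list[GameLogRecord] = []
    for t in range(1, config.n_rounds + 1):
        state.round_t = t
        edges_before = sorted(tuple(sorted(e)) for e in state.graph.edges)
        actions = np.asarray(population.act(state))
        delta = payoff_phase(state, actions, config.cost_c, config.benefit_b)
        # Conservation: total delta == (b - c) * sum of cooperating degrees.
        coop_degree_sum = sum(state.graph.degree(i) for i in range(config.n_players) if actions[i])
        expected = (config.benefit_b - config.cost_c) * coop_degree_sum
        if not np.isclose(delta.sum(), expected):
            raise AssertionError(
                f"payoff conservation violated: {delta.sum()} != {expected}"
            )
        state.last_action = actions
        recs = list(planner.recommend(state))
        for rec in recs:
            i, j = rec.pair
            has_edge = state.graph.has_edge(i, j)
            if (rec.valence == ADD) == has_edge:
                raise ValueError(
                    f"planner {planner.name!r} issued invalid {rec.valence} for pair {rec.pair}"
                )
        decisions = {rec.pair: population.decide(rec, state) for rec in recs}
        rec_dicts = [
            {
                "pair": list(rec.pair),
                "valence": rec.valence,
                "accepted": list(map(bool, decisions[rec.pair])),
            }
            for rec in recs
        ]
        changes = resolve_recommendations(
            state, recs, decisions, config.add_requires_both, config.delete_requires_both
        )
        records.append(
            GameLogRecord(
                round_t=t,
                actions=[int(a) for a in actions],
                payoffs=[float(x) for x in delta],
                capital=[float(x) for x in state.capital],
                edges=edges_before,
                recommendations=rec_dicts,
                changes=changes,
                edges_after=sorted(tuple(sorted(e)) for e in state.graph.edges),
            )
        )
    return records


def all_pairs(n: int) -> list[tuple[int, int]]:
    """All C(n, 2) unordered player pairs in lexicographic order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]
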