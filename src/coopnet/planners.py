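"""Rule-based social planners.

Six planners are provided: static (never recommends), random (30% of
possible pairs toggled each round), cooperative clustering (disengage
defectors from cooperators, then connect cooperators), encouragement
(pair-class x valence x round probability table), neutral
(connectivity-matching, choice-agnostic) and maximum-density (recommend
every missing edge).

"Possible edges" always means the C(n, 2) candidate pairs of the graph, not
the currently active edges; fractional budgets are rounded to the nearest
integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .game import ADD, DELETE, GameState, Recommendation, all_pairs

__all__ = [
    "StaticPlanner",
    "RandomPlanner",
    "ClusteringPlanner",
    "EncouragementTable",
    "EncouragementPlanner",
    "NeutralPlanner",
    "MaxDensityPlanner",
    "default_encouragement_table",
    "PAIR_CLASSES",
]

PAIR_CLASSES = ("CC", "CD", "DD")


def pair_budget(fraction: float, n_pairs: int) -> int:
    """Candidate-pair budget: fraction of C(n,2), rounded half away from zero.

    A small epsilon guards exact-half products (e.g. 0.30 * 465) against
    float representation error.
    """
    return int(math.floor(fraction * n_pairs + 0.5 + 1e-9))


def pair_class(a_i: int, a_j: int) -> str:
    """Classify a pair by its endpoints' most recent choices."""
    s = int(a_i) + int(a_j)
    return ("DD", "CD", "CC")[s]


def _toggle_valence(state: GameState, pair: tuple[int, int]) -> str:
    return DELETE if state.graph.has_edge(*pair) else ADD


class StaticPlanner:
    """Never recommends any change; the reference immutable-network planner."""

    name = "static"

    def recommend(self, state: GameState) -> list[Recommendation]:
        return []


class RandomPlanner:
    """Toggles a uniformly sampled fixed fraction of all possible pairs.

    Each round, round(fraction * C(n, 2)) distinct pairs are drawn without
    replacement; missing pairs are recommended as additions and existing
    edges as deletions, without regard for player choices.
    """

    name = "random"

    def __init__(self, seed: int, fraction: float = 0.30):
        self.fraction = fraction
        self.rng = np.random.default_rng(seed)

    def recommend(self, state: GameState) -> list[Recommendation]:
        pairs = all_pairs(state.n_players)
        k = pair_budget(self.fraction, len(pairs))
        if k == 0:
            return []
        idx = self.rng.choice(len(pairs), size=k, replace=False)
        return [
            Recommendation(pairs[i], _toggle_valence(state, pairs[i])) for i in sorted(idx)
        ]


class ClusteringPlanner:
    """Cooperative clustering: ostracize defectors, cluster cooperators.

    Rule (1): recommend deleting every existing cooperator-defector edge.
    Rule (2): recommend adding every absent cooperator-cooperator pair.
    Plus a random component: round(random_fraction * C(n, 2)) uniformly
    sampled pairs toggled, skipping pairs already covered by the rules
    (rule-based recommendations take precedence).
    """

    name = "clustering"

    def __init__(self, seed: int, random_fraction: float = 0.05):
        self.random_fraction = random_fraction
        self.rng = np.random.default_rng(seed)

    def recommend(self, state: GameState) -> list[Recommendation]:
        a = state.last_action
        recs: list[Recommendation] = []
        covered: set[tuple[int, int]] = set()
        for u, v in state.graph.edges:
            pair = (u, v) if u < v else (v, u)
            if a[u] != a[v]:
                recs.append(Recommendation(pair, DELETE))
                covered.add(pair)
        for pair in all_pairs(state.n_players):
            i, j = pair
            if a[i] and a[j] and not state.graph.has_edge(i, j):
                recs.append(Recommendation(pair, ADD))
                covered.add(pair)
        pairs = all_pairs(state.n_players)
        k = pair_budget(self.random_fraction, len(pairs))
        if k:
            idx = self.rng.choice(len(pairs), size=k, replace=False)
            for i in sorted(idx):
                pair = pairs[i]
                if pair not in covered:
                    recs.append(Recommendation(pair, _toggle_valence(state, pair)))
        return recs


@dataclass
class EncouragementTable:
    """Emission probabilities indexed by (round, pair class, valence).

    ``probs[t-1, class_index, valence_index]`` with classes ordered CC, CD,
    DD and valences ordered (add, delete). All entries lie in [0, 1].
    """

    probs: np.ndarray  # (n_rounds, 3, 2)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[1:] != (3, 2):
            raise ValueError("table must have shape (n_rounds, 3, 2)")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("all table entries must lie in [0, 1]")

    @property
    def n_rounds(self) -> int:
        return self.probs.shape[0]

    def lookup(self, pclass: str, valence: str, round_t: int) -> float:
        if not 1 <= round_t <= self.n_rounds:
            raise ValueError(
                f"round {round_t} outside the table range 1..{self.n_rounds}"
            )
        ci = PAIR_CLASSES.index(pclass)
        vi = 0 if valence == ADD else 1
        return float(self.probs[round_t - 1, ci, vi])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("round,pair_class,valence,probability\n")
            for t in range(1, self.n_rounds + 1):
                for ci, pc in enumerate(PAIR_CLASSES):
                    for vi, val in enumerate((ADD, DELETE)):
                        fh.write(f"{t},{pc},{val},{self.probs[t - 1, ci, vi]:.6g}\n")

    @classmethod
    def from_csv(cls, path) -> "EncouragementTable":
        import pandas as pd

        df = pd.read_csv(path)
        T = int(df["round"].max())
        probs = np.zeros((T, 3, 2))
        for _, row in df.iterrows():
            ci = PAIR_CLASSES.index(row["pair_class"])
            vi = 0 if row["valence"] == ADD else 1
            probs[int(row["round"]) - 1, ci, vi] = row["probability"]
        return cls(probs)


def default_encouragement_table(n_rounds: int = 15) -> EncouragementTable:
    """The default encouragement schedule for a game of ``n_rounds`` rounds.

    Cooperator-defector deletions ramp linearly from 4.8% in round 1 to
    72.2% in the final round; cooperator-defector additions decline linearly
    (mean 58% across rounds). Constant cells: CC-add 99%, CC-delete 3%,
    DD-add 0%, DD-delete 100%.
    """
    t = np.linspace(0.0, 1.0, n_rounds)
    probs = np.zeros((n_rounds, 3, 2))
    probs[:, 0, 0] = 0.99                     # CC add
    probs[:, 0, 1] = 0.03                     # CC delete
    probs[:, 1, 0] = 0.78 - 0.40 * t          # CD add: 0.78 -> 0.38, mean 0.58
    probs[:, 1, 1] = 0.048 + (0.722 - 0.048) * t  # CD delete: 4.8% -> 72.2%
    probs[:, 2, 0] = 0.00                     # DD add
    probs[:, 2, 1] = 1.00                     # DD delete
    return EncouragementTable(probs)


class EncouragementPlanner:
    """Emits each applicable recommendation independently by table lookup.

    For every pair exactly one valence is applicable (add if the pair is
    unlinked, delete if linked); it is emitted with the probability the
    table assigns to (pair class, valence, round).
    """

    name = "encouragement"

    def __init__(self, seed: int, table: EncouragementTable | None = None):
        self.table = table if table is not None else default_encouragement_table()
        self.rng = np.random.default_rng(seed)

    def recommend(self, state: GameState) -> list[Recommendation]:
        a = state.last_action
        recs = []
        for pair in all_pairs(state.n_players):
            i, j = pair
            valence = _toggle_valence(state, pair)
            p = self.table.lookup(pair_class(a[i], a[j]), valence, state.round_t)
            if self.rng.random() < p:
                recs.append(Recommendation(pair, valence))
        return recs


class NeutralPlanner:
    """Connectivity matching without regard for player choices.

    Follows a per-round target density schedule: if the current density is
    below the round's target it recommends uniformly sampled additions, if
    above, deletions, sized so that the *expected* number of executed
    changes (given an assumed acceptance rate) closes the gap.
    """

    name = "neutral"

    def __init__(self, seed: int, density_schedule, expected_accept: float = 0.7):
        self.schedule = np.asarray(density_schedule, dtype=float)
        if ((self.schedule < 0) | (self.schedule > 1)).any():
            raise ValueError("density targets must lie in [0, 1]")
        if not 0 < expected_accept <= 1:
            raise ValueError("expected_accept must lie in (0, 1]")
        self.expected_accept = expected_accept
        self.rng = np.random.default_rng(seed)

    def recommend(self, state: GameState) -> list[Recommendation]:
        t = state.round_t
        if t > len(self.schedule):
            raise ValueError(f"round {t} beyond the density schedule length")
        n_pairs = state.n_players * (state.n_players - 1) // 2
        target_edges = self.schedule[t - 1] * n_pairs
        current = state.graph.number_of_edges()
        gap = target_edges - current
        if abs(gap) < 0.5:
            return []
        if gap > 0:
            candidates = [p for p in all_pairs(state.n_players) if not state.graph.has_edge(*p)]
            valence = ADD
        else:
            candidates = sorted(tuple(sorted(e)) for e in state.graph.edges)
            valence = DELETE
        k = min(len(candidates), math.ceil(abs(gap) / self.expected_accept))
        if k == 0:
            return []
        idx = self.rng.choice(len(candidates), size=k, replace=False)
        return [Recommendation(candidates[i], valence) for i in sorted(idx)]


class MaxDensityPlanner:
    """Recommends every currently missing edge; never recommends deletions."""

    name = "max_density"

    def recommend(self, state: GameState) -> list[Recommendation]:
        return [
            Recommendation(pair, ADD)
            for pair in all_pairs(state.n_players)
            if not state.graph.has_edge(*pair)
        ]
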