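"""Analysis suite: cooperation trajectories, recommendation breakdowns,
mixing structure (choice assortativity, degree bias, core-periphery) and
inequality (Gini coefficient, Lorenz curve).

All functions operate either on raw graphs + label vectors or on the game
logs produced by the engine, and return plain numbers or tidy DataFrames.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .game import ADD, DELETE, GameLogRecord, all_pairs
from .planners import PAIR_CLASSES, pair_class

__all__ = [
    "cooperation_rate",
    "recommendation_breakdown",
    "choice_assortativity",
    "degree_bias",
    "core_periphery",
    "CorePeripheryResult",
    "core_composition_test",
    "gini_and_lorenz",
    "summary_table",
]


def cooperation_rate(log: Sequence[GameLogRecord], round_t: int) -> float:
    """Fraction of players cooperating in the given round."""
    for rec in log:
        if rec.round_t == round_t:
            return float(np.mean(rec.actions))
    raise ValueError(f"round {round_t} not present in log")


def _graph_from_edges(n: int, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


def recommendation_breakdown(
    logs: Sequence[Sequence[GameLogRecord]], ci_level: float = 0.95
) -> pd.DataFrame:
    """Per-(round, pair class, valence) emission counts and probabilities.

    For each round of each game, every candidate pair contributes one
    "chance" to exactly one cell: (its class, add) if the pair is unlinked
    at the planner phase, (its class, delete) if linked. The emission
    probability is recommendations / chances, with an equal-tailed credible
    interval from a uniform Beta(1, 1) prior. Cells with zero chances are
    reported with missing probability.
    """
    rows: dict[tuple[int, str, str], list[int]] = {}
    for game in logs:
        n = len(game[0].actions)
        pairs = all_pairs(n)
        for rec in game:
            edges = set(rec.edges)
            recommended = {tuple(r["pair"]): r["valence"] for r in rec.recommendations}
            for pair in pairs:
                i, j = pair
                pc = pair_class(rec.actions[i], rec.actions[j])
                valence = DELETE if pair in edges else ADD
                key = (rec.round_t, pc, valence)
                cell = rows.setdefault(key, [0, 0])
                cell[1] += 1
                if recommended.get(pair) == valence:
                    cell[0] += 1
    alpha = 1.0 - ci_level
    out = []
    for (t, pc, valence), (emitted, chances) in sorted(rows.items()):
        if chances == 0:
            p = lo = hi = np.nan
        else:
            p = emitted / chances
            lo = beta_dist.ppf(alpha / 2, emitted + 1, chances - emitted + 1)
            hi = beta_dist.ppf(1 - alpha / 2, emitted + 1, chances - emitted + 1)
        out.append(
            {
                "round": t,
                "pair_class": pc,
                "valence": valence,
                "recommendations": emitted,
                "chances": chances,
                "probability": p,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(out)


def choice_assortativity(graph: nx.Graph, last_actions) -> float:
    """Edge-wise Pearson correlation of the binary cooperate/defect label.

    Positive when cooperators tend to link with cooperators and defectors
    with defectors. Undefined (NaN) when every player carries the same
    label or the graph has no edges.
    """
    a = np.asarray(last_actions, dtype=float)
    edges = list(graph.edges)
    if not edges:
        return float("nan")
    # Both orientations of every edge, so the measure is symmetric.
    x = np.array([a[u] for u, v in edges] + [a[v] for u, v in edges])
    y = np.array([a[v] for u, v in edges] + [a[u] for u, v in edges])
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def degree_bias(graph: nx.Graph, last_actions) -> float:
    """Mean degree of cooperators minus mean degree of defectors.

    NaN if either class is empty.
    """
    a = np.asarray(last_actions)
    deg = np.array([graph.degree(i) for i in range(graph.number_of_nodes())], dtype=float)
    coop, defe = deg[a == 1], deg[a == 0]
    if len(coop) == 0 or len(defe) == 0:
        return float("nan")
    return float(coop.mean() - defe.mean())


@dataclass
class CorePeripheryResult:
    core: tuple[int, ...]
    score: float
    coop_share_core: float | None = None
    coop_share_periphery: float | None = None


def _cp_score(adj_vec: np.ndarray, pattern: np.ndarray) -> float:
    """Pearson correlation between adjacency and ideal pattern vectors.

    Defined as 0 when either vector is constant (no structure to correlate).
    """
    if adj_vec.std() == 0 or pattern.std() == 0:
        return 0.0
    return float(np.corrcoef(adj_vec, pattern)[0, 1])


def core_periphery(
    graph: nx.Graph, last_actions=None, exact_limit: int = 16
) -> CorePeripheryResult:
    """Discrete core-periphery fit by correlation with the ideal pattern.

    The ideal pattern links pair (i, j) iff i or j belongs to the core. The
    returned core maximizes the Pearson correlation between the observed
    off-diagonal adjacency and that pattern. For n <= ``exact_limit`` every
    non-trivial assignment (proper, non-empty core) is searched exactly;
    beyond that a degree-ordered sweep (core = top-k highest-degree nodes,
    k = 1..n-2) is used. Ties break toward the smallest core, then
    lexicographically.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("core-periphery structure needs at least 3 nodes")
    pairs = all_pairs(n)
    adj_vec = np.array([1.0 if graph.has_edge(i, j) else 0.0 for i, j in pairs])

    def pattern_for(core_mask: np.ndarray) -> np.ndarray:
        return np.array([1.0 if core_mask[i] or core_mask[j] else 0.0 for i, j in pairs])

    candidates: list[tuple[int, ...]]
    if n <= exact_limit:
        i_idx = np.array([p[0] for p in pairs])
        j_idx = np.array([p[1] for p in pairs])
        best = None
        # Vectorized sweep over all 2^n - 2 non-trivial assignments, in
        # chunks to bound memory.
        masks = np.arange(1, 2**n - 1, dtype=np.int64)
        for chunk in np.array_split(masks, max(1, len(masks) // 8192)):
            member = ((chunk[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
            pat = (member[:, i_idx] | member[:, j_idx]).astype(float)
            pstd = pat.std(axis=1)
            astd = adj_vec.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = ((pat - pat.mean(axis=1, keepdims=True)) * (adj_vec - adj_vec.mean())).mean(axis=1)
                score = np.where((pstd > 0) & (astd > 0), cov / (pstd * astd), 0.0)
            sizes = member.sum(axis=1)
            for s, sz, mem in zip(score, sizes, member):
                key = (-s, sz, tuple(np.flatnonzero(mem)))
                if best is None or key < best[0]:
                    best = (key, float(s), tuple(int(x) for x in np.flatnonzero(mem)))
        score_val, core = best[1], best[2]
    else:
        deg_order = sorted(range(n), key=lambda i: (-graph.degree(i), i))
        best = None
        for k in range(1, n - 1):
            core_mask = np.zeros(n, dtype=bool)
            core_mask[deg_order[:k]] = True
            s = _cp_score(adj_vec, pattern_for(core_mask))
            core_t = tuple(sorted(deg_order[:k]))
            key = (-s, k, core_t)
            if best is None or key < best[0]:
                best = (key, s, core_t)
        score_val, core = best[1], best[2]

    result = CorePeripheryResult(core=core, score=score_val)
    if last_actions is not None:
        a = np.asarray(last_actions)
        core_set = set(core)
        periph = [i for i in range(n) if i not in core_set]
        result.coop_share_core = float(np.mean([a[i] for i in core])) if core else None
        result.coop_share_periphery = (
            float(np.mean([a[i] for i in periph])) if periph else None
        )
    return result


def core_composition_test(
    core: Sequence[int], last_actions, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for cooperator over-representation in the core.

    Labels are shuffled over nodes; p is the (add-one corrected) fraction of
    permutations whose cooperator share of the core is at least the
    observed share.
    """
    a = np.asarray(last_actions)
    core = np.asarray(list(core), dtype=int)
    observed = a[core].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a)
        if perm[core].mean() >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def gini_and_lorenz(capital, shift: str | float = "auto"):
    """Gini coefficient and Lorenz curve of a capital vector.

    Gini = sum_ij |x_i - x_j| / (2 n^2 mean). Only meaningful for
    positive-mean, non-negative data; if negatives occur the vector is
    shifted (``shift="auto"``: so the minimum is 0; or a declared numeric
    endowment). Returns (gini, lorenz) where lorenz is the (n+1)-point
    cumulative-share curve from (0, 0) to (1, 1).
    """
    x = np.asarray(capital, dtype=float).copy()
    if x.min() < 0:
        if shift == "auto":
            x = x - x.min()
        elif isinstance(shift, (int, float)):
            x = x + float(shift)
            if x.min() < 0:
                raise ValueError(
                    f"shift {shift} leaves negative capital (min {x.min():.4g}); "
                    "use a larger endowment or shift='auto'"
                )
        else:
            raise ValueError("shift must be 'auto' or a numeric endowment")
    n = len(x)
    mean = x.mean()
    if mean <= 0:
        if np.allclose(x, 0):
            gini = 0.0
            lorenz = np.stack([np.linspace(0, 1, n + 1), np.linspace(0, 1, n + 1)], axis=1)
            return gini, lorenz
        raise ValueError(
            "Gini undefined for non-positive mean capital; shift by an "
            "initial endowment first"
        )
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    gini = float(diffs / (2 * n * n * mean))
    xs = np.sort(x)
    cum = np.concatenate([[0.0], np.cumsum(xs)]) / xs.sum()
    pop = np.linspace(0, 1, n + 1)
    lorenz = np.stack([pop, cum], axis=1)
    return gini, lorenz


def summary_table(logs: Sequence[Sequence[GameLogRecord]]) -> pd.DataFrame:
    """Tidy per-(group, round) statistics table for plotting.

    One row per group x round with cooperation rate, density, assortativity,
    degree bias and (final round only) Gini and core-periphery score.
    """
    rows = []
    for g, game in enumerate(logs):
        n = len(game[0].actions)
        n_pairs = n * (n - 1) // 2
        for rec in game:
            graph = _graph_from_edges(n, rec.edges_after)
            row = {
                "group": g,
                "round": rec.round_t,
                "cooperation_rate": float(np.mean(rec.actions)),
                "density": graph.number_of_edges() / n_pairs,
                "choice_assortativity": choice_assortativity(graph, rec.actions),
                "degree_bias": degree_bias(graph, rec.actions),
            }
            if rec.round_t == len(game):
                gini, _ = gini_and_lorenz(rec.capital)
                row["gini"] = gini
                if n >= 3:
                    cp = core_periphery(graph, rec.actions)
                    row["core_periphery_score"] = cp.score
                    row["coop_share_core"] = cp.coop_share_core
            rows.append(row)
    return pd.DataFrame(rows)
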