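"""Campaign orchestration: seeded multi-group simulations per condition.

A campaign runs ``n_groups`` independent games of one condition (static,
random, clustering, encouragement, neutral, max_density or graphnet), one
JSONL log per group, with per-group seeds derived as ``base_seed + g`` so
that bot disposition draws are identical across conditions sharing a base
seed (paired comparisons).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bots import BotParams, BotPopulation
from .game import GameConfig, GameLogRecord, GameState, Recommendation, run_game, write_log
from .metrics import summary_table
from .planners import (
    ClusteringPlanner,
    EncouragementPlanner,
    EncouragementTable,
    MaxDensityPlanner,
    NeutralPlanner,
    RandomPlanner,
    StaticPlanner,
)

CONDITIONS = (
    "static",
    "random",
    "clustering",
    "encouragement",
    "neutral",
    "max_density",
    "graphnet",
)


@dataclass
class Campaign:
    condition: str
    n_groups: int
    game_config: GameConfig = field(default_factory=GameConfig)
    bot_params: BotParams = field(default_factory=BotParams)
    planner_config: dict = field(default_factory=dict)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; valid conditions: "
                f"{', '.join(CONDITIONS)}"
            )


def make_planner(condition: str, seed: int, planner_config: dict, game_config: GameConfig):
    if condition == "static":
        return StaticPlanner()
    if condition == "random":
        return RandomPlanner(seed, fraction=planner_config.get("fraction", 0.30))
    if condition == "clustering":
        return ClusteringPlanner(
            seed, random_fraction=planner_config.get("random_fraction", 0.05)
        )
    if condition == "encouragement":
        table = planner_config.get("table")
        if isinstance(table, (str, Path)):
            table = EncouragementTable.from_csv(table)
        return EncouragementPlanner(seed, table=table)
    if condition == "neutral":
        schedule = planner_config.get("density_schedule")
        if schedule is None:
            raise ValueError(
                "neutral condition needs planner_config['density_schedule'] "
                "(e.g. derived from graphnet logs via density_schedule_from_logs)"
            )
        return NeutralPlanner(
            seed, schedule, expected_accept=planner_config.get("expected_accept", 0.7)
        )
    if condition == "max_density":
        return MaxDensityPlanner()
    if condition == "graphnet":
        from .agent.graphnet import GraphNet, GraphNetPlanner

        net = planner_config.get("net")
        if net is None:
            ckpt = planner_config.get("checkpoint")
            if ckpt is None:
                raise ValueError(
                    "graphnet condition needs planner_config['net'] or "
                    "planner_config['checkpoint']"
                )
            net = GraphNet.load(ckpt)
        return GraphNetPlanner(net, game_config.n_rounds, seed)
    raise ValueError(f"unknown condition {condition!r}")


def run_campaign(
    campaign: Campaign, out_dir: str | Path | None = None
) -> tuple[list[list[GameLogRecord]], pd.DataFrame]:
    """Simulate every group of a campaign; return (logs, summary table).

    Group ``g`` uses graph/bot seed ``base_seed + g`` and an independent
    planner stream; the whole campaign is a pure function of its spec. If
    ``out_dir`` is given, writes ``<condition>/group_<g>.jsonl`` per group
    plus ``<condition>/summary.csv``.
    """
    logs = []
    for g in range(campaign.n_groups):
        seed = campaign.base_seed + g
        cfg = replace(campaign.game_config, rng_seed=seed)
        planner = make_planner(
            campaign.condition, 1_000_003 * (seed + 1) % (2**31), campaign.planner_config, cfg
        )
        population = BotPopulation(cfg.n_players, campaign.bot_params, seed=seed)
        logs.append(run_game(cfg, planner, population))
    summary = summary_table(logs)
    summary.insert(0, "condition", campaign.condition)
    if out_dir is not None:
        cond_dir = Path(out_dir) / campaign.condition
        cond_dir.mkdir(parents=True, exist_ok=True)
        for g, game in enumerate(logs):
            write_log(game, cond_dir / f"group_{g}.jsonl")
        summary.to_csv(cond_dir / "summary.csv", index=False)
    return logs, summary


def campaign_digest(logs: list[list[GameLogRecord]]) -> str:
    """SHA-256 over all serialized log records (reproducibility check)."""
    h = hashlib.sha256()
    for game in logs:
        for rec in game:
            h.update(rec.to_json().encode())
            h.update(b"\n")
    return h.hexdigest()


def mean_trajectory(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-round mean cooperation rate across groups (the bold-line analogue)."""
    return (
        summary.groupby("round", as_index=False)["cooperation_rate"]
        .mean()
        .rename(columns={"cooperation_rate": "mean_cooperation_rate"})
    )


def density_schedule_from_logs(logs: list[list[GameLogRecord]]) -> np.ndarray:
    """Per-round mean post-rewiring density, e.g. to drive the neutral planner."""
    T = len(logs[0])
    n = len(logs[0][0].actions)
    n_pairs = n * (n - 1) // 2
    dens = np.zeros(T)
    for game in logs:
        for k, rec in enumerate(game):
            dens[k] += len(rec.edges_after) / n_pairs
    return dens / len(logs)


# ---------------------------------------------------------------------------
# Scripted fixtures


@dataclass
class Fixture:
    """Fully scripted population: deterministic actions and accept flags.

    ``actions[t-1, i]`` is player i's action in round t; ``accepts[t-1, i]``
    is whether i accepts any recommendation delivered to it that round.
    """

    actions: np.ndarray
    accepts: np.ndarray

    def act(self, state: GameState) -> np.ndarray:
        return self.actions[state.round_t - 1].copy()

    def decide(self, rec: Recommendation, state: GameState) -> tuple[bool, bool]:
        i, j = rec.pair
        t = state.round_t - 1
        return bool(self.accepts[t, i]), bool(self.accepts[t, j])


def make_fixture(spec: dict, n_players: int, n_rounds: int) -> Fixture:
    """Build a scripted population from a per-round script.

    ``spec`` maps ``"actions"`` to an (n_rounds, n_players) 0/1 array-like
    and optionally ``"accepts"`` to a same-shaped boolean array-like
    (default: accept everything). Raises on incomplete scripts, naming the
    missing extent.
    """
    actions = np.asarray(spec["actions"], dtype=int)
    if actions.shape != (n_rounds, n_players):
        raise ValueError(
            f"fixture actions have shape {actions.shape}, need "
            f"({n_rounds}, {n_players}): script must cover every player and round"
        )
    if not np.isin(actions, (0, 1)).all():
        raise ValueError("fixture actions must be binary")
    accepts = spec.get("accepts")
    if accepts is None:
        accepts = np.ones((n_rounds, n_players), dtype=bool)
    else:
        accepts = np.asarray(accepts, dtype=bool)
        if accepts.shape != (n_rounds, n_players):
            raise ValueError(
                f"fixture accepts have shape {accepts.shape}, need "
                f"({n_rounds}, {n_players})"
            )
    return Fixture(actions=actions, accepts=accepts)
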