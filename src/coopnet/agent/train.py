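"""Training loop: the GraphNet planner against simulated groups.

Training runs many games in parallel as one batched environment (identical
bot model and payoff rules as the reference engine, vectorized over games)
and applies one actor-critic update per batch of episodes. The per-episode
mean cooperation and loss diagnostics form the learning curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ..bots import BotParams, BotPopulation
from ..game import GameConfig, run_game
from .a2c import Adam, TrainingConfig, Transition, a2c_loss, n_step_returns
from .autodiff import Parameter, Tensor
from .graphnet import GraphNet, GraphNetConfig, GraphNetPlanner, GraphObservation


class BatchedGames:
    """B simultaneous games with vectorized bot dynamics.

    Mirrors the reference engine exactly (same round order, payoff rule,
    bot logistic model, phi acceptance table, bilateral-add /
    unilateral-delete rewiring) but operates on (B, n, n) adjacency arrays
    for speed during training.
    """

    def __init__(self, game_config: GameConfig, bot_params: BotParams,
                 batch: int, rng: np.random.Generator):
        self.cfg = game_config
        self.bp = bot_params
        self.B = batch
        self.rng = rng
        n = game_config.n_players
        self.n = n
        self.pairs_i, self.pairs_j = np.triu_indices(n, k=1)
        self.P = len(self.pairs_i)
        self.reset()

    def reset(self) -> None:
        cfg, n, B = self.cfg, self.n, self.B
        p = cfg.initial_graph_params.get("p", 0.3) if cfg.initial_graph == "erdos_renyi" else None
        adj = np.zeros((B, n, n))
        if cfg.initial_graph == "erdos_renyi":
            up = self.rng.random((B, self.P)) < p
            adj[:, self.pairs_i, self.pairs_j] = up
            adj[:, self.pairs_j, self.pairs_i] = up
        elif cfg.initial_graph == "complete":
            adj = np.ones((B, n, n)) - np.eye(n)
        elif cfg.initial_graph == "empty":
            pass
        else:
            raise ValueError(
                f"batched environment supports erdos_renyi/empty/complete, "
                f"got {cfg.initial_graph!r}"
            )
        self.adj = adj
        self.theta = self.rng.normal(self.bp.mu_theta, self.bp.sigma_theta, size=(B, n))
        self.capital = np.zeros((B, n))
        self.last_action: np.ndarray | None = None
        self.t = 1

    # -- phases --------------------------------------------------------

    def act(self) -> np.ndarray:
        bp = self.bp
        if self.t == 1:
            z = bp.beta0_prime + bp.beta1_prime * self.theta
        else:
            deg = self.adj.sum(axis=2)
            x_n = np.einsum("bij,bj->bi", self.adj, self.last_action.astype(float))
            with np.errstate(invalid="ignore", divide="ignore"):
                x_r = np.where(deg > 0, x_n / np.where(deg > 0, deg, 1.0), 0.0)
            z = bp.beta0 + bp.beta1 * deg + bp.beta2 * x_n + bp.beta3 * x_r + self.theta
        actions = (self.rng.random((self.B, self.n)) < expit(z)).astype(float)
        return actions

    def payoff(self, actions: np.ndarray) -> np.ndarray:
        deg = self.adj.sum(axis=2)
        benefit = np.einsum("bij,bj->bi", self.adj, actions)
        delta = -self.cfg.cost_c * deg * actions + self.cfg.benefit_b * benefit
        self.capital += delta
        return delta

    def observe(self, n_rounds: int) -> GraphObservation:
        a = self.last_action
        deg = self.adj.sum(axis=2)
        V = np.stack([a, 1.0 - a, deg / max(self.n - 1, 1)], axis=2)
        exists = self.adj[:, self.pairs_i, self.pairs_j]
        ai, aj = a[:, self.pairs_i], a[:, self.pairs_j]
        E = np.stack([exists, 0.5 * (ai + aj), ai * aj], axis=2)
        u = np.full((self.B, 1), self.t / n_rounds)
        pairs = list(zip(self.pairs_i.tolist(), self.pairs_j.tolist()))
        return GraphObservation(u=u, V=V, E=E, pairs=pairs)

    def rewire(self, mask: np.ndarray) -> np.ndarray:
        """Resolve a (B, P) recommendation mask; return accepted fractions."""
        bp = self.bp
        a = self.last_action
        exists = self.adj[:, self.pairs_i, self.pairs_j] > 0.5
        make = ~exists
        ai, aj = a[:, self.pairs_i] > 0.5, a[:, self.pairs_j] > 0.5
        phi = np.array(bp.phi)
        # Endpoint i's acceptance depends on the referent j's action.
        phi_i = phi[2 * make.astype(int) + aj.astype(int)]
        phi_j = phi[2 * make.astype(int) + ai.astype(int)]
        m = mask > 0.5
        acc_i = self.rng.random(m.shape) < phi_i
        acc_j = self.rng.random(m.shape) < phi_j
        add_ok = self.cfg.add_requires_both
        del_ok = self.cfg.delete_requires_both
        add_exec = m & make & ((acc_i & acc_j) if add_ok else (acc_i | acc_j))
        del_exec = m & exists & ((acc_i & acc_j) if del_ok else (acc_i | acc_j))
        new_vals = np.where(add_exec, 1.0, np.where(del_exec, 0.0, exists.astype(float)))
        self.adj[:, self.pairs_i, self.pairs_j] = new_vals
        self.adj[:, self.pairs_j, self.pairs_i] = new_vals
        n_rec = m.sum(axis=1)
        n_exec = (add_exec | del_exec).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_rec > 0, n_exec / np.where(n_rec > 0, n_rec, 1), 0.0)
        return frac


def run_training_episode(
    net: GraphNet, env: BatchedGames, config: TrainingConfig
) -> tuple[list[Transition], float]:
    """Play one batched episode with the current policy; collect transitions."""
    env.reset()
    T = env.cfg.n_rounds
    transitions: list[Transition] = []
    final_coop = 0.0
    for t in range(1, T + 1):
        env.t = t
        actions = env.act()
        delta = env.payoff(actions)
        env.last_action = actions
        obs = env.observe(T)
        logits, _ = net.forward(obs)
        probs = expit(np.clip(logits.data, -60, 60))
        mask = (env.rng.random(probs.shape) < probs).astype(float)
        accepted_frac = env.rewire(mask)
        reward = delta.sum(axis=1) / env.n + config.reward_lambda * accepted_frac
        transitions.append(
            Transition(obs=obs, mask=mask, reward=reward, terminal=(t == T))
        )
        if t == T:
            final_coop = float(actions.mean())
    return transitions, final_coop


def train_agent(
    training_config: TrainingConfig,
    game_config: GameConfig | None = None,
    bot_params: BotParams | None = None,
) -> tuple[GraphNet, pd.DataFrame]:
    """Train the GraphNet planner against simulated groups.

    Runs batches of full games, one actor-critic update per batch, until the
    simulated-round budget is exhausted. Fully seeded and deterministic. On
    numerical divergence the last finite parameters are kept and training
    halts. Returns the trained network and the learning curve (one row per
    update: rounds used, mean final-round cooperation, losses).
    """
    cfg = training_config
    game_config = game_config or GameConfig()
    bot_params = bot_params or BotParams()
    rng = np.random.default_rng(cfg.seed)
    net = GraphNet(
        game_config.n_players,
        GraphNetConfig(width=cfg.width),
        seed=int(rng.integers(2**31 - 1)),
    )
    env = BatchedGames(game_config, bot_params, cfg.batch_games, rng)
    optimizer = Adam(net.parameters(), lr=cfg.learning_rate)

    rounds_used = 0
    rows = []
    update = 0
    rounds_per_episode = cfg.batch_games * game_config.n_rounds
    while rounds_used + rounds_per_episode <= cfg.budget_rounds:
        episode, final_coop = run_training_episode(net, env, cfg)
        last_good = net.get_flat_params()
        try:
            loss, diag = a2c_loss(net, episode, cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite loss")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            if not np.isfinite(net.get_flat_params()).all():
                raise FloatingPointError("non-finite parameters after update")
        except FloatingPointError:
            net.set_flat_params(last_good)
            break
        rounds_used += rounds_per_episode
        update += 1
        rows.append(
            {
                "update": update,
                "rounds_used": rounds_used,
                "final_round_cooperation": final_coop,
                "loss": float(loss.data),
                **{k: v for k, v in diag.items()},
            }
        )
    curve = pd.DataFrame(rows)
    return net, curve


def evaluate_agent(
    net: GraphNet,
    game_config: GameConfig,
    bot_params: BotParams,
    n_games: int,
    seed: int,
):
    """Run evaluation games through the reference engine; return the logs."""
    logs = []
    for g in range(n_games):
        cfg = GameConfig(**{**game_config.__dict__, "rng_seed": game_config.rng_seed + g})
        planner = GraphNetPlanner(net, cfg.n_rounds, seed=seed + 7919 * g)
        population = BotPopulation(cfg.n_players, bot_params, seed=seed + 104729 * g)
        logs.append(run_game(cfg, planner, population))
    return logs
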