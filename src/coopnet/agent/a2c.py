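"""Advantage actor-critic for the factorized edge-recommendation policy.

The policy is a product of independent Bernoulli distributions, one per
candidate pair, parameterized by the GraphNet's per-pair logits. The loss is

    L = -sum log pi(a|s) * A  +  c_v * (R - v)^2  -  c_e * H(pi)

averaged over batch and time, with A the n-step discounted return minus the
(detached) value baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..game import ADD, GameState
from .autodiff import Parameter, Tensor
from .graphnet import GraphObservation


@dataclass
class TrainingConfig:
    """Actor-critic hyperparameters and simulation budget.

    ``budget_rounds`` counts simulated game rounds (summed over parallel
    games); the ceiling is 5e7, the desk-scale default far smaller.
    ``reward_lambda`` mixes the acceptance-quality term into the reward.
    """

    discount: float = 0.99
    n_step: int = 15
    value_loss_weight: float = 0.5
    entropy_weight: float = 0.01
    learning_rate: float = 3e-3
    reward_lambda: float = 0.1
    budget_rounds: int = 200_000
    seed: int = 0
    batch_games: int = 20
    width: int = 32

    def __post_init__(self) -> None:
        if not 0 < self.discount <= 1:
            raise ValueError("discount must lie in (0, 1]")
        if self.budget_rounds > 5 * 10**7:
            raise ValueError("budget exceeds the 5e7 simulated-round ceiling")


@dataclass
class Transition:
    """One planner step; arrays may carry a leading batch axis."""

    obs: GraphObservation
    mask: np.ndarray      # 0/1 per candidate pair
    reward: np.ndarray    # scalar per game
    terminal: bool


def compute_reward(
    before: GameState,
    after: GameState,
    recs,
    decisions,
    lam: float = 0.1,
    add_requires_both: bool = True,
    delete_requires_both: bool = False,
) -> float:
    """Planner reward: mean capital gain plus acceptance-quality bonus.

    reward = (total capital change) / n_players
             + lam * (fraction of issued recommendations whose acceptance
                      contract was satisfied); the second term is 0 when no
    recommendations were issued.
    """
    n = before.n_players
    capital_term = float(after.capital.sum() - before.capital.sum()) / n
    if not recs:
        return capital_term
    ok = 0
    for rec in recs:
        acc_i, acc_j = decisions[rec.pair]
        both = add_requires_both if rec.valence == ADD else delete_requires_both
        ok += int((acc_i and acc_j) if both else (acc_i or acc_j))
    return capital_term + lam * ok / len(recs)


def n_step_returns(
    rewards: np.ndarray, values: np.ndarray, discount: float, n_step: int, terminal: bool
) -> np.ndarray:
    """Per-step n-step discounted returns, bootstrapped from the critic.

    ``rewards`` has shape (T, ...) and ``values`` (T, ...) holds the
    critic's (detached) state values. R_t truncates at the episode end
    (no bootstrap past a terminal state).
    """
    T = rewards.shape[0]
    returns = np.zeros_like(rewards)
    for t in range(T):
        horizon = min(n_step, T - t)
        acc = np.zeros_like(rewards[0])
        for k in range(horizon - 1, -1, -1):
            acc = rewards[t + k] + discount * acc
        cut = t + horizon
        if cut < T or not terminal:
            boot = values[cut] if cut < T else np.zeros_like(values[0])
            acc = acc + discount**horizon * boot
        returns[t] = acc
    return returns


def _policy_terms(logits: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """(log pi(a|s), entropy) summed over pairs, per batch element."""
    log_p1 = logits.log_sigmoid()
    log_p0 = (-logits).log_sigmoid()
    m = Tensor(mask)
    logp = (m * log_p1 + (1.0 - m) * log_p0).sum(axis=-1)
    p = logits.sigmoid()
    ent = -(p * log_p1 + (1.0 - p) * log_p0).sum(axis=-1)
    return logp, ent


def a2c_loss(model, episode: Sequence[Transition], config: TrainingConfig,
             returns: np.ndarray | None = None,
             advantages: np.ndarray | None = None):
    """Build the scalar A2C loss tensor for one (possibly batched) episode.

    By default the n-step return targets are bootstrapped from the current
    critic, and both the targets and the advantages are treated as
    constants (no gradient flows through the bootstrap or the baseline).
    Fixed ``returns``/``advantages`` may be supplied instead, e.g. to
    compare gradients against finite differences of the same loss surface.
    """
    logits_seq, values_seq = [], []
    for tr in episode:
        logits, value = model.forward(tr.obs)
        logits_seq.append(logits)
        values_seq.append(value)
    values_detached = np.stack([v.data for v in values_seq])     # (T, B?)
    rewards = np.stack([np.asarray(tr.reward, dtype=float) for tr in episode])
    if returns is None:
        returns = n_step_returns(
            rewards, values_detached, config.discount, config.n_step, episode[-1].terminal
        )
    if advantages is None:
        advantages = returns - values_detached

    total_policy, total_value, total_entropy = None, None, None
    for t, tr in enumerate(episode):
        logp, ent = _policy_terms(logits_seq[t], np.asarray(tr.mask, dtype=float))
        pol = (logp * Tensor(advantages[t])).sum() * -1.0
        diff = values_seq[t] - Tensor(returns[t])
        val = (diff * diff).sum()
        e = ent.sum()
        total_policy = pol if total_policy is None else total_policy + pol
        total_value = val if total_value is None else total_value + val
        total_entropy = e if total_entropy is None else total_entropy + e
    n_terms = len(episode) * (rewards[0].size if rewards[0].ndim else 1)
    scale = 1.0 / n_terms
    loss = (
        total_policy * scale
        + config.value_loss_weight * total_value * scale
        - config.entropy_weight * total_entropy * scale
    )
    diagnostics = {
        "policy_loss": float(total_policy.data) * scale,
        "value_loss": float(total_value.data) * scale,
        "entropy": float(total_entropy.data) * scale,
        "mean_return": float(returns.mean()),
        "mean_advantage": float(advantages.mean()),
    }
    return loss, diagnostics


class BernoulliBanditPolicy:
    """State-independent policy/value with one logit per candidate pair.

    The minimal model satisfying the actor-critic interface; used for
    sanity-checking the learning rule on toy problems where the optimum is
    known in closed form.
    """

    def __init__(self, n_pairs: int):
        self.logits = Parameter(np.zeros(n_pairs))
        self.value = Parameter(np.zeros(1))

    def forward(self, obs) -> tuple[Tensor, Tensor]:
        return self.logits + 0.0, self.value.reshape(())

    def parameters(self) -> list[Parameter]:
        return [self.logits, self.value]

    def emission_probs(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits.data))


class Adam:
    """Standard Adam over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def a2c_update(model, episode: Sequence[Transition], config: TrainingConfig,
               optimizer: Adam | None = None) -> dict:
    """One gradient step on the A2C loss; returns loss diagnostics.

    Raises ``FloatingPointError`` on a non-finite loss, leaving the
    parameters untouched.
    """
    if not episode:
        raise ValueError("episode must be non-empty")
    if optimizer is None:
        optimizer = Adam(model.parameters(), lr=config.learning_rate)
    loss, diagnostics = a2c_loss(model, episode, config)
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite A2C loss: {diagnostics}")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    diagnostics["loss"] = float(loss.data)
    return diagnostics
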