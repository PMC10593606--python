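"""Simulated players: heterogeneous logistic cooperation and acceptance.

Each bot draws a cooperative disposition theta ~ N(mu_theta, sigma_theta)
once at initialization. In round 1 it cooperates with probability
``logistic(beta0' + beta1' * theta)``; in later rounds with probability
``logistic(beta0 + beta1*x_s + beta2*x_n + beta3*x_r + theta)`` where x_s is
its neighbourhood size, x_n its number of cooperating neighbours and
x_r = x_n / x_s the neighbourhood cooperation rate (0 for isolates).
Recommendations are accepted with a probability that depends only on the
valence and the other endpoint's most recent decision (the phi table).

``fit_bot_params`` recovers the betas and the disposition spread by maximum
likelihood (random-intercept logistic, Gauss-Hermite quadrature) and the phi
table by cell-wise frequencies, from game logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .game import ADD, DELETE, GameLogRecord, GameState, Recommendation

__all__ = [
    "BotParams",
    "Bot",
    "BotPopulation",
    "DEFAULT_BOT_PARAMS",
    "cooperate_prob",
    "accept_prob",
    "neighbourhood_covariates",
    "fit_bot_params",
    "BotParamsFit",
]


@dataclass
class BotParams:
    """Shared bot-model parameters.

    phi indexing: phi0 = (break, referent defected), phi1 = (break, referent
    cooperated), phi2 = (make, referent defected), phi3 = (make, referent
    cooperated).
    """

    mu_theta: float = 0.0
    sigma_theta: float = 1.0
    beta0_prime: float = 1.0
    beta1_prime: float = 1.0
    beta0: float = -0.7
    beta1: float = -0.1
    beta2: float = 0.12
    beta3: float = 1.4
    phi0: float = 0.90
    phi1: float = 0.45
    phi2: float = 0.60
    phi3: float = 0.85

    def __post_init__(self) -> None:
        if self.sigma_theta <= 0:
            raise ValueError("sigma_theta must be positive")
        for k in ("phi0", "phi1", "phi2", "phi3"):
            v = getattr(self, k)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must lie in [0, 1], got {v}")

    @property
    def phi(self) -> tuple[float, float, float, float]:
        return (self.phi0, self.phi1, self.phi2, self.phi3)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BotParams":
        return cls(**d)


# Calibrated to reproduce the qualitative static-network signature (mean
# cooperation declining from roughly 70% in round 1 to roughly 43% by round
# 15 on a 16-player G(n, 0.3) graph). These are this package's calibrated
# defaults, not empirically fitted human parameters.
DEFAULT_BOT_PARAMS = BotParams()


@dataclass
class Bot:
    """One simulated player: a fixed disposition draw plus an RNG stream."""

    player_id: int
    theta: float
    params: BotParams
    rng: np.random.Generator = field(repr=False, default_factory=np.random.default_rng)


def neighbourhood_covariates(state: GameState, player: int) -> tuple[float, float, float]:
    """(x_s, x_n, x_r) for one player from the current graph + last actions."""
    if state.last_action is None:
        raise ValueError("last actions undefined; covariates only exist from round 2")
    neigh = list(state.graph.neighbors(player))
    x_s = float(len(neigh))
    x_n = float(sum(state.last_action[j] for j in neigh))
    x_r = x_n / x_s if x_s > 0 else 0.0
    return x_s, x_n, x_r


def cooperate_prob(bot: Bot, state: GameState) -> float:
    """Probability that the bot cooperates in the current round."""
    p = bot.params
    if state.round_t == 1:
        z = p.beta0_prime + p.beta1_prime * bot.theta
    else:
        x_s, x_n, x_r = neighbourhood_covariates(state, bot.player_id)
        z = p.beta0 + p.beta1 * x_s + p.beta2 * x_n + p.beta3 * x_r + bot.theta
    return float(expit(z))


def accept_prob(bot: Bot, rec: Recommendation, referent_last_action: int) -> float:
    """Acceptance probability: phi table lookup by valence and referent action."""
    p = bot.params
    if rec.valence == DELETE:
        return p.phi1 if referent_last_action else p.phi0
    return p.phi3 if referent_last_action else p.phi2


class BotPopulation:
    """A full group of bots with independent, seeded RNG substreams."""

    def __init__(self, n_players: int, params: BotParams, seed: int):
        self.params = params
        ss = np.random.SeedSequence(seed)
        theta_rng = np.random.default_rng(ss.spawn(1)[0])
        thetas = theta_rng.normal(params.mu_theta, params.sigma_theta, size=n_players)
        streams = ss.spawn(n_players)
        self.bots = [
            Bot(player_id=i, theta=float(thetas[i]), params=params,
                rng=np.random.default_rng(streams[i]))
            for i in range(n_players)
        ]

    @property
    def thetas(self) -> np.ndarray:
        return np.array([b.theta for b in self.bots])

    def act(self, state: GameState) -> np.ndarray:
        return np.array(
            [int(b.rng.random() < cooperate_prob(b, state)) for b in self.bots]
        )

    def decide(self, rec: Recommendation, state: GameState) -> tuple[bool, bool]:
        i, j = rec.pair
        bi, bj = self.bots[i], self.bots[j]
        a_i = int(state.last_action[i])
        a_j = int(state.last_action[j])
        acc_i = bi.rng.random() < accept_prob(bi, rec, a_j)
        acc_j = bj.rng.random() < accept_prob(bj, rec, a_i)
        return bool(acc_i), bool(acc_j)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class BotParamsFit:
    params: BotParams
    beta_se: dict
    phi_se: dict
    phi_counts: dict
    log_likelihood: float
    converged: bool


def _extract_choice_data(logs: Sequence[Sequence[GameLogRecord]]):
    """Per-player choice histories with covariates, across games.

    Returns a list of (y_round1, Y_later (T-1,), X_later (T-1, 3)) tuples,
    one per player per game. Covariates for round t come from the graph the
    round was played on and the previous round's actions.
    """
    out = []
    for game in logs:
        n = len(game[0].actions)
        for i in range(n):
            y1 = game[0].actions[i]
            ys, xs = [], []
            for prev, rec in zip(game[:-1], game[1:]):
                neigh = [v for (u, v) in rec.edges if u == i] + [
                    u for (u, v) in rec.edges if v == i
                ]
                x_s = float(len(neigh))
                x_n = float(sum(prev.actions[j] for j in neigh))
                x_r = x_n / x_s if x_s else 0.0
                ys.append(rec.actions[i])
                xs.append((x_s, x_n, x_r))
            out.append((y1, np.array(ys, dtype=float), np.array(xs, dtype=float)))
    return out


def _mixed_logit_nll(params_vec: np.ndarray, data, gh_nodes, gh_weights) -> float:
    """Negative log-likelihood, disposition integrated out by quadrature.

    theta is parameterized as N(0, sigma); the population mean is absorbed
    into the intercepts (mu_theta and beta0 are not separately identifiable).
    """
    b0p, b1p, b0, b1, b2, b3, log_sigma = params_vec
    sigma = np.exp(log_sigma)
    theta = np.sqrt(2.0) * sigma * gh_nodes          # (Q,)
    w = gh_weights / np.sqrt(np.pi)                  # (Q,)
    total = 0.0
    for y1, ys, xs in data:
        z1 = b0p + b1p * theta                       # (Q,)
        ll = log_expit(z1) if y1 else log_expit(-z1)
        if len(ys):
            zl = (b0 + xs @ np.array([b1, b2, b3]))[:, None] + theta[None, :]
            ll = ll + np.where(ys[:, None] > 0, log_expit(zl), log_expit(-zl)).sum(axis=0)
        m = ll.max()
        total += m + np.log(np.dot(w, np.exp(ll - m)))
    return -total


def fit_bot_params(
    logs: Sequence[Sequence[GameLogRecord]],
    n_quad: int = 25,
    x0: np.ndarray | None = None,
) -> BotParamsFit:
    """Fit the bot model to logged play by maximum likelihood.

    Betas and sigma_theta come from the random-intercept logistic likelihood
    (Gauss-Hermite quadrature over the disposition); each phi cell is the
    acceptance frequency among its events with a binomial standard error.
    Cells with no events are reported as missing (None), never as 0.

    Raises ``ValueError`` on complete separation (all recorded choices
    identical), where the likelihood has no interior maximum.
    """
    data = _extract_choice_data(logs)
    all_y = np.concatenate(
        [[y1] + list(ys) for y1, ys, _ in data]
    )
    if all_y.min() == all_y.max():
        raise ValueError(
            "complete separation: every logged choice is identical; "
            "the logistic likelihood is unbounded"
        )

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    if x0 is None:
        x0 = np.array([0.5, 1.0, 0.0, 0.0, 0.0, 0.5, 0.0])
    res = minimize(
        _mixed_logit_nll,
        x0,
        args=(data, nodes, weights),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    b0p, b1p, b0, b1, b2, b3, log_sigma = res.x

    # Standard errors from the numerical Hessian (inverse observed information).
    beta_se = {}
    try:
        if res.hess_inv is not None:
            hinv = res.hess_inv.todense() if hasattr(res.hess_inv, "todense") else res.hess_inv
            ses = np.sqrt(np.clip(np.diag(hinv), 0, None))
            names = ["beta0_prime", "beta1_prime", "beta0", "beta1", "beta2", "beta3", "log_sigma"]
            beta_se = dict(zip(names, map(float, ses)))
    except Exception:
        beta_se = {}

    # phi: cell frequencies over acceptance events. Each recommendation
    # contributes two events (one per endpoint), classified by the *other*
    # endpoint's action.
    counts = {k: [0, 0] for k in range(4)}  # cell -> [accepts, events]
    for game in logs:
        for rec_round in game:
            for r in rec_round.recommendations:
                i, j = r["pair"]
                a_i, a_j = rec_round.actions[i], rec_round.actions[j]
                make = r["valence"] == ADD
                acc_i, acc_j = r["accepted"]
                for referent, acc in ((a_j, acc_i), (a_i, acc_j)):
                    cell = (2 if make else 0) + int(referent)
                    counts[cell][0] += int(acc)
                    counts[cell][1] += 1
    phi_hat, phi_se = {}, {}
    for cell in range(4):
        k, m = counts[cell]
        key = f"phi{cell}"
        if m == 0:
            phi_hat[key] = None
            phi_se[key] = None
        else:
            p = k / m
            phi_hat[key] = p
            phi_se[key] = float(np.sqrt(p * (1 - p) / m))

    params = BotParams(
        mu_theta=0.0,
        sigma_theta=float(np.exp(log_sigma)),
        beta0_prime=float(b0p),
        beta1_prime=float(b1p),
        beta0=float(b0),
        beta1=float(b1),
        beta2=float(b2),
        beta3=float(b3),
        phi0=phi_hat["phi0"] if phi_hat["phi0"] is not None else 0.5,
        phi1=phi_hat["phi1"] if phi_hat["phi1"] is not None else 0.5,
        phi2=phi_hat["phi2"] if phi_hat["phi2"] is not None else 0.5,
        phi3=phi_hat["phi3"] if phi_hat["phi3"] is not None else 0.5,
    )
    return BotParamsFit(
        params=params,
        beta_se=beta_se,
        phi_se=phi_se,
        phi_counts={f"phi{c}": tuple(counts[c]) for c in range(4)},
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
    )
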