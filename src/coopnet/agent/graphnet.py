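"""Graph-network policy/value model for the social planner.

The network consumes a (u, V, E) observation — one global feature vector,
per-node features and per-candidate-pair features over all C(n, 2) pairs —
and runs two message-passing blocks. Each block updates pair latents from
(pair, both endpoints, global) with an MLP, aggregates incident pair
latents to nodes by summation, updates node latents, aggregates everything
to the global latent and updates it. A per-pair readout head emits one
policy logit per candidate pair and a global head emits the scalar value
estimate. All update functions share weights across pairs/nodes, so the
network is equivariant under player relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..game import ADD, DELETE, GameState, Recommendation, all_pairs
from .autodiff import Parameter, Tensor, concat

N_NODE_FEATURES = 3  # cooperated?, defected?, normalized degree
N_EDGE_FEATURES = 3  # exists?, mean endpoint action, both-cooperated?
N_GLOBAL_FEATURES = 1  # normalized round index t / T


@dataclass
class GraphObservation:
    """The (u, V, E) triple plus the fixed pair indexing.

    Arrays may carry a leading batch axis: u (B, du), V (B, n, dv),
    E (B, P, de) with P = C(n, 2). ``pairs`` lists every unordered pair
    exactly once, in lexicographic order.
    """

    u: np.ndarray
    V: np.ndarray
    E: np.ndarray
    pairs: list[tuple[int, int]]

    @property
    def n_players(self) -> int:
        return self.V.shape[-2]


def encode_observation(state: GameState, n_rounds: int) -> GraphObservation:
    """Deterministically encode a game state (unbatched)."""
    if state.last_action is None:
        raise ValueError("cannot encode a state before the first action phase")
    n = state.n_players
    a = np.asarray(state.last_action, dtype=float)
    deg = np.array([state.graph.degree(i) for i in range(n)], dtype=float)
    V = np.stack([a, 1.0 - a, deg / max(n - 1, 1)], axis=1)
    pairs = all_pairs(n)
    E = np.zeros((len(pairs), N_EDGE_FEATURES))
    for k, (i, j) in enumerate(pairs):
        E[k, 0] = 1.0 if state.graph.has_edge(i, j) else 0.0
        E[k, 1] = 0.5 * (a[i] + a[j])
        E[k, 2] = a[i] * a[j]
    u = np.array([state.round_t / n_rounds])
    return GraphObservation(u=u, V=V, E=E, pairs=pairs)


def batch_observations(obs_list: list[GraphObservation]) -> GraphObservation:
    return GraphObservation(
        u=np.stack([o.u for o in obs_list]),
        V=np.stack([o.V for o in obs_list]),
        E=np.stack([o.E for o in obs_list]),
        pairs=obs_list[0].pairs,
    )


@dataclass
class GraphNetConfig:
    width: int = 32
    n_blocks: int = 2
    n_node_features: int = N_NODE_FEATURES
    n_edge_features: int = N_EDGE_FEATURES
    n_global_features: int = N_GLOBAL_FEATURES


class _MLP:
    """Two-layer tanh MLP with shared weights across the leading axes."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        def init(din, dout):
            scale = np.sqrt(2.0 / (din + dout))
            return Parameter(rng.normal(0.0, scale, size=(din, dout)))

        self.w1 = init(d_in, d_hidden)
        self.b1 = Parameter(np.zeros(d_hidden))
        self.w2 = init(d_hidden, d_out)
        self.b2 = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        h = (x @ self.w1 + self.b1).tanh()
        return h @ self.w2 + self.b2

    def parameters(self) -> list[Parameter]:
        return [self.w1, self.b1, self.w2, self.b2]


class GraphNet:
    """Two-block message-passing network with edge-logit and value heads."""

    def __init__(self, n_players: int, config: GraphNetConfig | None = None, seed: int = 0):
        self.config = config or GraphNetConfig()
        self.n_players = n_players
        cfg = self.config
        rng = np.random.default_rng(seed)
        w = cfg.width
        self.pairs = all_pairs(n_players)
        P = len(self.pairs)
        # Constant selection/incidence matrices: S_i/S_j pick endpoint node
        # rows for each pair; A aggregates pair latents back to nodes.
        self._Si = np.zeros((P, n_players))
        self._Sj = np.zeros((P, n_players))
        for k, (i, j) in enumerate(self.pairs):
            self._Si[k, i] = 1.0
            self._Sj[k, j] = 1.0
        self._A = (self._Si + self._Sj).T  # (n, P)

        self.blocks = []
        de, dv, du = cfg.n_edge_features, cfg.n_node_features, cfg.n_global_features
        for _ in range(cfg.n_blocks):
            edge_mlp = _MLP(de + 2 * dv + du, w, w, rng)
            node_mlp = _MLP(w + dv + du, w, w, rng)
            global_mlp = _MLP(2 * w + du, w, w, rng)
            self.blocks.append((edge_mlp, node_mlp, global_mlp))
            de, dv, du = w, w, w
        self.edge_head = _MLP(w, w, 1, rng)
        self.value_head = _MLP(w, w, 1, rng)

    # -- parameter plumbing -------------------------------------------

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for block in self.blocks:
            for mlp in block:
                ps.extend(mlp.parameters())
        ps.extend(self.edge_head.parameters())
        ps.extend(self.value_head.parameters())
        return ps

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.parameters()])

    def set_flat_params(self, flat: np.ndarray) -> None:
        i = 0
        for p in self.parameters():
            p.data = flat[i : i + p.data.size].reshape(p.data.shape).copy()
            i += p.data.size
        if i != flat.size:
            raise ValueError("flat parameter vector has the wrong length")

    # -- forward -------------------------------------------------------

    def forward(self, obs: GraphObservation) -> tuple[Tensor, Tensor]:
        """Return (per-pair logits, value); leading batch axis preserved.

        Accepts batched (B, ...) or unbatched arrays; unbatched inputs give
        logits of shape (P,) and a scalar value.
        """
        batched = obs.u.ndim == 2
        u = obs.u if batched else obs.u[None, :]
        V = obs.V if batched else obs.V[None, :, :]
        E = obs.E if batched else obs.E[None, :, :]
        B, n, _ = V.shape
        P = E.shape[1]
        if n != self.n_players:
            raise ValueError(f"observation has {n} players, model built for {self.n_players}")

        u_t, V_t, E_t = Tensor(u), Tensor(V), Tensor(E)
        Si, Sj, A = Tensor(self._Si), Tensor(self._Sj), Tensor(self._A)

        for edge_mlp, node_mlp, global_mlp in self.blocks:
            du = u_t.shape[-1]
            u_pairs = u_t.reshape(B, 1, du).broadcast_to((B, P, du))
            u_nodes = u_t.reshape(B, 1, du).broadcast_to((B, n, du))
            vi = Si @ V_t  # (B, P, dv)
            vj = Sj @ V_t
            # Symmetrize over endpoint order so the network cannot depend on
            # the arbitrary i < j pair labelling (permutation equivariance).
            e_ij = edge_mlp(concat([E_t, vi, vj, u_pairs], axis=-1))
            e_ji = edge_mlp(concat([E_t, vj, vi, u_pairs], axis=-1))
            E_t = (e_ij + e_ji) * 0.5
            node_agg = A @ E_t  # (B, n, w): summed incident pair latents
            v_in = concat([node_agg, V_t, u_nodes], axis=-1)
            V_t = node_mlp(v_in)
            edge_pool = E_t.sum(axis=1)  # (B, w)
            node_pool = V_t.sum(axis=1)
            u_t = global_mlp(concat([edge_pool, node_pool, u_t], axis=-1))
            if not np.isfinite(E_t.data).all() or not np.isfinite(u_t.data).all():
                raise FloatingPointError("non-finite activations in graph network")

        logits = self.edge_head(E_t).reshape(B, P)
        value = self.value_head(u_t).reshape(B)
        if not batched:
            return logits.reshape(P), value.reshape(())
        return logits, value

    __call__ = forward

    # -- serialization -------------------------------------------------

    def save(self, path, extra_config: dict | None = None) -> None:
        """Checkpoint: flat weights + architecture + config hash, in .npz."""
        import hashlib
        import json

        cfg = {
            "n_players": self.n_players,
            "width": self.config.width,
            "n_blocks": self.config.n_blocks,
            **(extra_config or {}),
        }
        cfg_json = json.dumps(cfg, sort_keys=True)
        np.savez(
            path,
            flat_params=self.get_flat_params(),
            config_json=np.array(cfg_json),
            config_hash=np.array(hashlib.sha256(cfg_json.encode()).hexdigest()),
        )

    @classmethod
    def load(cls, path) -> "GraphNet":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["config_json"]))
            net = cls(
                n_players=int(cfg["n_players"]),
                config=GraphNetConfig(width=int(cfg["width"]), n_blocks=int(cfg["n_blocks"])),
            )
            net.set_flat_params(z["flat_params"])
        return net


def sample_action(
    logits: np.ndarray, state: GameState, rng: np.random.Generator
) -> tuple[list[Recommendation], np.ndarray]:
    """Sample the factorized policy: independent Bernoulli(sigmoid) per pair.

    Returns the recommendation set and the 0/1 action mask over pairs; the
    valence of each emitted recommendation follows the current edge state.
    """
    pairs = all_pairs(state.n_players)
    if len(logits) != len(pairs):
        raise ValueError("one logit per candidate pair required")
    probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
    mask = (rng.random(len(pairs)) < probs).astype(float)
    recs = []
    for k, pair in enumerate(pairs):
        if mask[k]:
            valence = DELETE if state.graph.has_edge(*pair) else ADD
            recs.append(Recommendation(pair, valence))
    return recs, mask


class GraphNetPlanner:
    """Adapter exposing a trained GraphNet under the planner contract."""

    name = "graphnet"

    def __init__(self, net: GraphNet, n_rounds: int, seed: int, greedy: bool = False):
        self.net = net
        self.n_rounds = n_rounds
        self.rng = np.random.default_rng(seed)
        self.greedy = greedy

    def recommend(self, state: GameState) -> list[Recommendation]:
        obs = encode_observation(state, self.n_rounds)
        logits, _ = self.net.forward(obs)
        l = logits.data
        if self.greedy:
            mask = l > 0
            recs = []
            for k, pair in enumerate(obs.pairs):
                if mask[k]:
                    valence = DELETE if state.graph.has_edge(*pair) else ADD
                    recs.append(Recommendation(pair, valence))
            return recs
        recs, _ = sample_action(l, state, self.rng)
        return recs
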