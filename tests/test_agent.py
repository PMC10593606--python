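"""Agent tests: observation encoding, GraphNet symmetries, A2C mechanics."""

import networkx as nx
import numpy as np
import pytest

import coopnet as cn
from coopnet.agent.a2c import (
    Adam,
    BernoulliBanditPolicy,
    TrainingConfig,
    Transition,
    a2c_loss,
    a2c_update,
    compute_reward,
    n_step_returns,
)
from coopnet.agent.graphnet import (
    GraphNet,
    GraphNetConfig,
    encode_observation,
    sample_action,
)
from coopnet.agent.train import BatchedGames, train_agent
from coopnet.game import ADD, DELETE, GameConfig, all_pairs, payoff_phase

from conftest import make_state


def _obs(n=5, seed=3, round_t=2):
    cfg = GameConfig(n_players=n, rng_seed=seed)
    st = cn.initial_state(cfg)
    st.round_t = round_t
    st.last_action = np.arange(n) % 2
    return st, encode_observation(st, 15)


class TestEncoding:
    def test_empty_graph_zero_existence(self):
        st = make_state(5, [], actions=[1, 0, 1, 0, 1])
        obs = encode_observation(st, 15)
        assert np.all(obs.E[:, 0] == 0)

    def test_global_feature_is_normalized_round(self):
        st = make_state(4, [(0, 1)], actions=[1, 0, 1, 0], round_t=1)
        obs = encode_observation(st, 15)
        assert obs.u == pytest.approx([1 / 15])

    def test_relabelling_permutes_features(self):
        st, obs = _obs(n=6)
        perm = np.array([3, 1, 0, 5, 4, 2])
        g2 = nx.relabel_nodes(st.graph, {i: int(perm[i]) for i in range(6)})
        la = np.zeros(6)
        la[perm] = st.last_action
        st2 = cn.GameState(st.round_t, g2, la, st.capital.copy())
        obs2 = encode_observation(st2, 15)
        assert np.allclose(obs2.V[perm], obs.V)

    def test_requires_last_actions(self):
        st = make_state(4, [], actions=None)
        with pytest.raises(ValueError, match="action"):
            encode_observation(st, 15)


class TestGraphNetForward:
    def test_zero_weights_constant_outputs(self):
        st, obs = _obs()
        net = GraphNet(5, GraphNetConfig(width=4), seed=0)
        net.set_flat_params(np.zeros(net.get_flat_params().size))
        logits, value = net.forward(obs)
        assert np.allclose(logits.data, logits.data[0])
        assert value.data == pytest.approx(0.0)

    def test_forward_deterministic(self):
        st, obs = _obs()
        net = GraphNet(5, GraphNetConfig(width=8), seed=1)
        l1, v1 = net.forward(obs)
        l2, v2 = net.forward(obs)
        assert np.array_equal(l1.data, l2.data) and v1.data == v2.data

    def test_permutation_equivariance_exact(self, rng):
        n = 7
        net = GraphNet(n, GraphNetConfig(width=8), seed=2)
        for trial in range(5):
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            g.add_nodes_from(range(n))
            la = rng.integers(0, 2, size=n).astype(float)
            st = cn.GameState(3, g, la, np.zeros(n))
            obs = encode_observation(st, 15)
            logits, value = net.forward(obs)

            perm = rng.permutation(n)
            g2 = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(n)})
            la2 = np.zeros(n)
            la2[perm] = la
            obs2 = encode_observation(cn.GameState(3, g2, la2, np.zeros(n)), 15)
            logits2, value2 = net.forward(obs2)

            pairs = all_pairs(n)
            idx = {p: k for k, p in enumerate(pairs)}
            mapped = np.zeros(len(pairs))
            for k, (i, j) in enumerate(pairs):
                pi, pj = sorted((int(perm[i]), int(perm[j])))
                mapped[idx[(pi, pj)]] = logits.data[k]
            assert np.allclose(mapped, logits2.data, atol=1e-12)
            assert value.data == pytest.approx(float(value2.data), abs=1e-12)

    def test_batched_matches_unbatched(self):
        st, obs = _obs()
        net = GraphNet(5, GraphNetConfig(width=8), seed=3)
        from coopnet.agent.graphnet import batch_observations

        batched = batch_observations([obs, obs])
        lb, vb = net.forward(batched)
        lu, vu = net.forward(obs)
        assert np.allclose(lb.data[0], lu.data) and np.allclose(lb.data[1], lu.data)
        assert np.allclose(vb.data, float(vu.data))

    def test_checkpoint_roundtrip(self, tmp_path):
        st, obs = _obs()
        net = GraphNet(5, GraphNetConfig(width=4), seed=4)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        back = GraphNet.load(path)
        assert np.allclose(back.forward(obs)[0].data, net.forward(obs)[0].data)


class TestSampleAction:
    def test_extreme_logits(self, rng):
        st = make_state(4, [], actions=[1, 0, 1, 0])
        recs, mask = sample_action(np.full(6, -1e9), st, rng)
        assert recs == [] and mask.sum() == 0
        recs, mask = sample_action(np.full(6, 1e9), st, rng)
        assert len(recs) == 6 and all(r.valence == ADD for r in recs)

    def test_zero_logit_half_rate(self, rng):
        st = make_state(2, [], actions=[1, 0])
        hits = sum(sample_action(np.zeros(1), st, rng)[1][0] for _ in range(10_000))
        assert abs(hits / 10_000 - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_valence_follows_edge_state(self, rng):
        st = make_state(3, [(0, 1)], actions=[1, 1, 0])
        recs, _ = sample_action(np.full(3, 1e9), st, rng)
        by_pair = {r.pair: r.valence for r in recs}
        assert by_pair[(0, 1)] == DELETE
        assert by_pair[(0, 2)] == ADD


class TestReward:
    def _states(self, cap_before, cap_after, n=16):
        b = make_state(n, [], actions=[0] * n, capital=cap_before)
        a = make_state(n, [], actions=[0] * n, capital=cap_after)
        return b, a

    def test_no_change_no_recs_zero(self):
        b, a = self._states(np.zeros(16), np.zeros(16))
        assert compute_reward(b, a, [], {}, lam=0.1) == 0.0

    def test_capital_term(self):
        cap = np.zeros(16)
        cap2 = cap.copy()
        cap2[0] = 1.6
        b, a = self._states(cap, cap2)
        assert compute_reward(b, a, [], {}, lam=0.0) == pytest.approx(0.1)

    def test_acceptance_term(self):
        b, a = self._states(np.zeros(16), np.zeros(16))
        recs = [cn.Recommendation((i, i + 1), ADD) for i in range(0, 20, 2)]
        decisions = {r.pair: (True, True) for r in recs}
        assert compute_reward(b, a, recs, decisions, lam=1.0) == pytest.approx(1.0)

    def test_add_needs_both_acceptances_to_count(self):
        b, a = self._states(np.zeros(16), np.zeros(16))
        recs = [cn.Recommendation((0, 1), ADD)]
        assert compute_reward(b, a, recs, {(0, 1): (True, False)}, lam=1.0) == 0.0


class TestA2C:
    def test_n_step_returns_monte_carlo_case(self):
        r = np.array([1.0, 1.0, 1.0])
        v = np.zeros(3)
        R = n_step_returns(r, v, discount=0.5, n_step=5, terminal=True)
        assert R == pytest.approx([1.75, 1.5, 1.0])

    def test_n_step_bootstraps_from_critic(self):
        r = np.array([0.0, 0.0])
        v = np.array([10.0, 4.0])
        R = n_step_returns(r, v, discount=0.5, n_step=1, terminal=True)
        # R_0 = r_0 + 0.5 * V(s_1); R_1 terminal, no bootstrap
        assert R == pytest.approx([2.0, 0.0])

    def test_zero_advantage_kills_policy_gradient(self):
        st, obs = _obs()
        net = GraphNet(5, GraphNetConfig(width=4), seed=5)
        tc = TrainingConfig(width=4, entropy_weight=0.0)
        ep = [Transition(obs=obs, mask=np.ones(10), reward=np.float64(0.0), terminal=True)]
        _, diag = a2c_loss(net, ep, tc, returns=np.array([0.3]), advantages=np.array([0.0]))
        assert diag["policy_loss"] == 0.0

    def test_gradients_match_finite_differences(self):
        st, obs = _obs()
        net = GraphNet(5, GraphNetConfig(width=4), seed=6)
        tc = TrainingConfig(width=4)
        mask = (np.random.default_rng(0).random(10) < 0.5).astype(float)
        ep = [Transition(obs=obs, mask=mask, reward=np.float64(0.3), terminal=True)]
        R, A = np.array([0.3]), np.array([0.17])
        loss, _ = a2c_loss(net, ep, tc, returns=R, advantages=A)
        loss.backward()
        g = np.concatenate(
            [
                (p.grad if p.grad is not None else np.zeros_like(p.data)).ravel()
                for p in net.parameters()
            ]
        )
        flat = net.get_flat_params()
        eps = 1e-6
        sel = np.random.default_rng(1).choice(flat.size, 60, replace=False)
        for i in sel:
            f2 = flat.copy()
            f2[i] += eps
            net.set_flat_params(f2)
            lp = float(a2c_loss(net, ep, tc, returns=R, advantages=A)[0].data)
            f2[i] -= 2 * eps
            net.set_flat_params(f2)
            lm = float(a2c_loss(net, ep, tc, returns=R, advantages=A)[0].data)
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - g[i]) / max(1e-4, abs(fd) + abs(g[i])) < 1e-4
        net.set_flat_params(flat)

    def test_toy_rewarded_pair_learned(self):
        # single-state, two-pair problem: recommending pair 0 always pays
        pol = BernoulliBanditPolicy(2)
        opt = Adam(pol.parameters(), lr=0.05)
        tc = TrainingConfig(discount=1.0, n_step=1, entropy_weight=0.001)
        rng = np.random.default_rng(0)
        for _ in range(3000):
            p = pol.emission_probs()
            m = (rng.random(2) < p).astype(float)
            ep = [Transition(obs=None, mask=m, reward=np.float64(m[0]), terminal=True)]
            a2c_update(pol, ep, tc, opt)
        assert pol.emission_probs()[0] > 0.9

    def test_entropy_domination_drives_to_half(self):
        pol = BernoulliBanditPolicy(2)
        pol.logits.data = np.array([3.0, -3.0])
        opt = Adam(pol.parameters(), lr=0.05)
        tc = TrainingConfig(discount=1.0, n_step=1, entropy_weight=50.0)
        rng = np.random.default_rng(0)
        for _ in range(500):
            p = pol.emission_probs()
            m = (rng.random(2) < p).astype(float)
            ep = [Transition(obs=None, mask=m, reward=np.float64(m[0]), terminal=True)]
            a2c_update(pol, ep, tc, opt)
        assert np.all(np.abs(pol.emission_probs() - 0.5) < 0.05)

    def test_empty_episode_rejected(self):
        pol = BernoulliBanditPolicy(2)
        with pytest.raises(ValueError):
            a2c_update(pol, [], TrainingConfig())


class TestBatchedEnvConsistency:
    """The vectorized training environment must match the reference engine."""

    def test_payoff_matches_engine_formula(self, rng):
        gc = GameConfig(n_players=6, rng_seed=1)
        env = BatchedGames(gc, cn.BotParams(), batch=3, rng=np.random.default_rng(0))
        actions = rng.integers(0, 2, size=(3, 6)).astype(float)
        delta = env.payoff(actions)
        for b in range(3):
            g = nx.from_numpy_array(env.adj[b])
            st = cn.GameState(1, g, None, np.zeros(6))
            ref = payoff_phase(st, actions[b], gc.cost_c, gc.benefit_b)
            assert np.allclose(delta[b], ref)

    def test_observation_matches_encoder(self):
        gc = GameConfig(n_players=6, rng_seed=1)
        env = BatchedGames(gc, cn.BotParams(), batch=2, rng=np.random.default_rng(0))
        env.t = 4
        env.last_action = np.tile(np.array([1.0, 0, 1, 0, 1, 0]), (2, 1))
        obs = env.observe(15)
        for b in range(2):
            g = nx.from_numpy_array(env.adj[b])
            g.add_nodes_from(range(6))
            st = cn.GameState(4, g, env.last_action[b], np.zeros(6))
            ref = encode_observation(st, 15)
            assert np.allclose(obs.V[b], ref.V)
            assert np.allclose(obs.E[b], ref.E)
            assert np.allclose(obs.u[b], ref.u)

    def test_rewire_respects_acceptance_contracts(self):
        gc = GameConfig(n_players=4, rng_seed=1, initial_graph="empty")
        always = cn.BotParams(phi0=1, phi1=1, phi2=1, phi3=1)
        env = BatchedGames(gc, always, batch=1, rng=np.random.default_rng(0))
        env.last_action = np.ones((1, 4))
        frac = env.rewire(np.ones((1, 6)))
        assert frac[0] == 1.0
        assert env.adj[0].sum() == 12  # complete graph, both triangle halves

        never = cn.BotParams(phi0=0, phi1=0, phi2=0, phi3=0)
        env2 = BatchedGames(gc, never, batch=1, rng=np.random.default_rng(0))
        env2.last_action = np.ones((1, 4))
        frac2 = env2.rewire(np.ones((1, 6)))
        assert frac2[0] == 0.0 and env2.adj[0].sum() == 0

    def test_first_round_action_probability_matches_bot_model(self):
        bp = cn.BotParams()
        gc = GameConfig(n_players=16, rng_seed=0)
        env = BatchedGames(gc, bp, batch=2000, rng=np.random.default_rng(5))
        actions = env.act()
        from scipy.special import expit

        expected = expit(bp.beta0_prime + bp.beta1_prime * env.theta).mean()
        assert abs(actions.mean() - expected) < 0.01


class TestTrainAgent:
    def test_zero_budget_returns_initial_params(self):
        tc = TrainingConfig(budget_rounds=0, seed=1, width=4, batch_games=2)
        net, curve = train_agent(tc, GameConfig(n_players=4))
        fresh = GraphNet(4, GraphNetConfig(width=4), seed=int(np.random.default_rng(1).integers(2**31 - 1)))
        assert np.allclose(net.get_flat_params(), fresh.get_flat_params())
        assert len(curve) == 0

    def test_same_seed_identical_learning_curves(self):
        tc = TrainingConfig(budget_rounds=600, seed=3, width=4, batch_games=2)
        _, c1 = train_agent(tc, GameConfig(n_players=4))
        _, c2 = train_agent(tc, GameConfig(n_players=4))
        assert c1.equals(c2)

    def test_budget_ceiling_enforced(self):
        with pytest.raises(ValueError, match="ceiling"):
            TrainingConfig(budget_rounds=10**8)
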