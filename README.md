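# coopnet

Simulation and analysis of **planner-guided cooperation games on dynamic
networks**.

Groups of players sit on the vertices of a simple undirected graph and play a
repeated cooperation game. Each round, every player chooses to **cooperate**
or **defect**: cooperation costs *c* = 0.05 capital per linked neighbour and
pays each neighbour a benefit *b* = 0.1, so mutual cooperation is
group-optimal while free-riding is individually tempting. Between rounds a
**social planner** observes the graph and the fresh decisions and recommends
edge additions or deletions; the affected players accept or reject, and the
graph rewires. The question the toolkit addresses — for researchers in
behavioural network science, evolutionary game theory and multi-agent
reinforcement learning — is *which recommendation policies scaffold group
cooperation, and through which network structures*.

The package provides:

- **`coopnet.game`** — the turn-based engine (payoffs, recommendation
  delivery, bilateral link formation / unilateral severance, JSONL logging).
- **`coopnet.bots`** — simulated players. Bot *i* draws a cooperative
  disposition θᵢ ~ N(μ_θ, σ_θ) once, cooperates in round 1 with probability
  σ(β′₀ + β′₁θᵢ), and thereafter with probability
  σ(β₀ + β₁x_s + β₂x_n + β₃x_r + θᵢ), where x_s is its neighbourhood size,
  x_n its number of cooperating neighbours and x_r = x_n/x_s. Recommendations
  are accepted with a probability φ that depends on the valence (make/break)
  and the other endpoint's last choice. `fit_bot_params` recovers all
  parameters from logs by random-intercept logistic maximum likelihood
  (Gauss–Hermite quadrature) plus cell-wise acceptance frequencies.
- **`coopnet.planners`** — six rule-based planners: static, random (30% of
  possible pairs toggled per round), cooperative clustering (cut
  cooperator–defector edges, join cooperator pairs, +5% random), the
  **encouragement** planner (a pair-class × valence × round probability
  table whose cooperator–defector deletion rate ramps from 4.8% in round 1
  to 72.2% in round 15), connectivity-matching neutral, and maximum-density.
- **`coopnet.agent`** — a graph-network planner: two message-passing blocks
  over global/node/pair features emit one policy logit per candidate pair
  (an independent-Bernoulli factorized policy) and a value estimate, trained
  by advantage actor–critic against batched simulated groups. The network
  is exactly permutation-equivariant, and runs on a small reverse-mode
  autodiff core over numpy.
- **`coopnet.metrics`** — the analysis suite: cooperation trajectories,
  recommendation breakdowns by pair class with uniform-prior credible
  intervals, choice assortativity (edge-wise label correlation), degree bias
  toward cooperators, discrete core–periphery fitting by exhaustive
  correlation maximization with a permutation test on core composition, and
  Gini/Lorenz inequality.
- **`coopnet.experiments`** — seeded multi-group campaigns, scripted
  fixtures and the `coopnet` command line (`run-game`, `run-campaign`,
  `train-agent`, `fit-bots`, `analyze`).

## Worked example

Run a five-group campaign under the encouragement planner and analyse the
final round of the first group:

```python
import networkx as nx
from coopnet.experiments import Campaign, run_campaign, mean_trajectory
from coopnet.metrics import choice_assortativity, core_periphery, gini_and_lorenz

logs, summary = run_campaign(Campaign("encouragement", n_groups=5, base_seed=0))
print(mean_trajectory(summary).tail(1))
#  round  mean_cooperation_rate
#     15                  0.538

final = logs[0][-1]
g = nx.Graph(); g.add_nodes_from(range(16)); g.add_edges_from(final.edges_after)
print(choice_assortativity(g, final.actions))   # -0.186
cp = core_periphery(g, final.actions)
print(len(cp.core), cp.score, cp.coop_share_core)  # 8 0.434 1.0
print(gini_and_lorenz(final.capital)[0])        # 0.107
```

Mean cooperation ends near 54% — well above the ~42% the same bot
population reaches on a static network — while the rewired group shows the
structural signature of the encouraging strategy: assortativity near zero
(cooperators and defectors stay mixed), a pronounced core–periphery fit
whose core is entirely cooperators, and low capital inequality
(Gini ≈ 0.11). The same comparison across planners (static, random,
clustering, encouragement, max-density) is a one-liner per condition via
`run_campaign`, or from a shell:

```bash
coopnet run-campaign --condition encouragement --groups 5 --seed 0 --out out/
coopnet analyze out/encouragement --out tables/
```

Training the graph-network planner at desk scale and inspecting its policy:

```bash
coopnet train-agent --budget 200000 --seed 1 --out ckpt.npz --curve curve.csv
```

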