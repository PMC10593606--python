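# Methods

This note documents the models, the numerical choices and the limitations of
the package, in the order a reader meets them: game, bots, planners, agent,
metrics, campaigns.

## The cooperation game

Players occupy the vertices of a simple undirected graph (no self-loops, no
multi-edges). A round proceeds: simultaneous action phase → payoff phase →
planner recommendation phase → accept/reject phase → rewiring. Cooperating
costs *c* = 0.05 capital per linked neighbour; every neighbour of a
cooperator receives *b* = 0.1. Defectors pay and confer nothing. Because
*b* > *c*, each round's total capital change equals
(*b* − *c*) · Σᵢ deg(i)·[i cooperates] ≥ 0, an identity the engine asserts
on every simulated round. Defaults: 16 players, 15 rounds.

Because the planner phase follows the action phase *within* a round, the
planner (and the acceptance model) always has a current decision for every
player, including in round 1.

**Acceptance semantics.** The game description leaves open what "accept"
means for a pair. We adopt the standard convention of dynamic-network
experiments: link *formation* is bilateral (both endpoints must accept),
link *severance* is unilateral (one acceptance suffices). Both are exposed
as `GameConfig` switches (`add_requires_both`, `delete_requires_both`).

**Initial topology.** Seeded Erdős–Rényi G(n, p) with p = 0.3 by default,
matching the density regime of prior dynamic-network cooperation
experiments; generator and parameters are configurable (`empty`,
`complete`, `ring`, `regular` are also provided).

**Initial capital** is 0 for every player; capital may go negative.
Dropouts are not modelled.

## Bot model

Bot *i* draws a disposition θᵢ ~ N(μ_θ, σ_θ) once at initialization and
keeps it for life. Cooperation probability:

- round 1: σ(β′₀ + β′₁·θᵢ)
- later rounds: σ(β₀ + β₁·x_s + β₂·x_n + β₃·x_r + θᵢ)

with x_s the current degree, x_n the number of neighbours whose last action
was cooperate, and x_r = x_n / x_s, defined as 0 for isolates (the ratio is
otherwise 0/0). Acceptance probability is a four-cell table φ indexed by
valence × referent's last action: φ₀ (break, defector), φ₁ (break,
cooperator), φ₂ (make, defector), φ₃ (make, cooperator).

**Default parameters are calibrated, not fitted to human data.** The
defaults (μ_θ = 0, σ_θ = 1, β′ = (1.0, 1.0), β = (−0.7, −0.1, 0.12, 1.4),
φ = (0.90, 0.45, 0.60, 0.85)) were chosen once, by simulation, so that
static-network groups reproduce the canonical qualitative signature of this
class of experiments: mean cooperation starting near 70% in round 1 and
declining to roughly 43% by round 15 (measured over 30 seeded groups). The
φ defaults encode the empirically plausible ordering "breaking with a
defector and making with a cooperator are readily accepted; breaking with a
cooperator is resisted". Every parameter is config-overridable.

Each bot owns an independent RNG substream spawned from the population
seed, so a population's behaviour is reproducible under any planner and
disposition draws are identical across conditions sharing a seed.

**Fitting.** `fit_bot_params` maximizes the random-intercept logistic
likelihood with the disposition integrated out by Gauss–Hermite quadrature
(25 nodes by default; L-BFGS-B on (β′₀, β′₁, β₀…β₃, log σ_θ)). The
population mean μ_θ is not separately identifiable from the intercepts and
is fixed at 0; simulated data for recovery checks are generated the same
way. β₂ and β₃ are partially collinear (x_n = x_s·x_r), so recovery checks
use logs from the random planner, whose rewiring varies degrees within
players. Complete separation (all logged choices identical) raises an
error rather than returning a divergent fit. φ cells are estimated as
acceptance frequencies with binomial standard errors; an empty cell is
reported as missing, never as 0.

## Planners

All planners obey one contract: only valid recommendations (add for absent
pairs, delete for existing edges), at most one per pair per round.
"Fraction of possible edges" always means a fraction of the C(n, 2)
candidate pairs, rounded half away from zero (with an epsilon guard so
exact halves like 0.30 · 465 round up regardless of float representation).

- **static**: never recommends.
- **random**: 30% of pairs toggled per round, uniformly without
  replacement (36 pairs at n = 16).
- **clustering**: deletes every cooperator–defector edge, adds every
  absent cooperator–cooperator pair (in that priority order), plus 5% of
  pairs toggled at random, skipping pairs the rules already covered.
- **encouragement**: for every pair the applicable valence is emitted with
  probability table[pair class, valence, round]. Only the two
  cooperator–defector deletion anchors are externally given (4.8% in round
  1, 72.2% in round 15); the default table interpolates them linearly over
  rounds. The remaining defaults follow the empirical recommendation
  frequencies of the trained graph-network planner: CC-add 0.99, CC-delete
  0.03, DD-add 0.00, DD-delete 1.00 constant, and CD-add declining
  linearly from 0.78 to 0.38 (mean 0.58). The whole table is loadable from
  CSV.
- **neutral**: choice-agnostic connectivity matching. Given a per-round
  target density schedule (typically `density_schedule_from_logs` applied
  to graph-network logs), it recommends uniform additions or deletions
  sized as ceil(gap / expected acceptance rate) so the *expected* executed
  change closes the gap; the acceptance-rate estimate defaults to 0.7.
- **max_density**: recommends every missing edge.

## The graph-network planner

**Observation.** u = [t/T] (the round index must be an input because the
network is non-recurrent and the task is time-inhomogeneous); per-node
features [cooperated, defected, degree/(n−1)]; per-pair features over all
C(n, 2) candidate pairs [edge exists, mean endpoint action, both
cooperated]. Pair features are symmetric in the endpoints by construction.

**Architecture.** Two message-passing blocks. Each block: a pair update
MLP on (pair latent, both endpoint latents, global latent) — evaluated on
both endpoint orderings and averaged, which makes the block exactly
invariant to the arbitrary i < j pair labelling and hence the whole
network permutation-equivariant — then summation of incident pair latents
into each node, a node update MLP, summation pooling of pair and node
latents into the global latent, and a global update MLP. Readouts: a
per-pair scalar logit head and a global scalar value head. MLPs are
two-layer tanh, shared across pairs/nodes; width 32 by default (16 in the
desk-scale recipe). All computation runs on a purpose-built reverse-mode
autodiff core over numpy (`agent/autodiff.py`), whose gradients are tested
against finite differences.

**Policy.** Independent Bernoulli(σ(logit)) per candidate pair; an emitted
pair's valence follows the current edge state. The factorization keeps the
2^C(n,2) action space tractable and matches the per-pair logit readout.

**Reward.** After each planner turn,
reward = (total capital change)/n + λ·(fraction of issued recommendations
whose acceptance contract was satisfied), λ = 0.1 by default, the second
term 0 when nothing was issued. The mixture weight and the acceptance-based
definition of "recommendation quality" are this package's choices, exposed
in `TrainingConfig`.

**Learning.** Advantage actor–critic:
L = −Σ log π(a|s)·Â + c_v(R − v)² − c_e·H(π), averaged over batch and time,
with Â the n-step discounted return minus the detached value baseline.
Neither the bootstrap target nor the advantage carries gradient. Defaults:
discount 0.99, episode-length (15-step) returns, value weight 0.5, entropy
weight 0.01, Adam at 3e-3. Training plays batches of games in parallel
through a vectorized environment (`BatchedGames`) that reproduces the
reference engine's dynamics on (B, n, n) adjacency arrays — payoffs,
observation features and acceptance contracts are tested for agreement with
the engine — and applies one update per batch of episodes. Divergence
(non-finite loss or parameters) halts training and keeps the last finite
parameters. Checkpoints are .npz files carrying the flat weights, the
architecture and a config hash.

**Desk-scale recipe.** Full-scale training in the literature runs tens of
millions of simulated rounds; this package's default budget is 2×10⁵
rounds, single-process. With a global scalar reward spread over C(n, 2)
independent Bernoulli arms, credit assignment scales roughly with the
square of the number of candidate pairs, so the desk-scale configuration
trains on 8-player groups (28 pairs instead of 120), width-16 MLPs, batches
of 40 games, learning rate 5e-3 and entropy weight 0.001. Under this
recipe the agent reliably learns the class-discriminating signature —
recommending cooperator–cooperator additions far above defector–defector
additions and lifting final-round cooperation above the static baseline —
within the 2×10⁵-round budget. Trained policies evaluated at larger n
require retraining (the incidence matrices are built per group size).

## Metrics

- **Cooperation rate**: cooperators ÷ players, per round.
- **Recommendation breakdown**: each candidate pair contributes one
  "chance" per round to exactly one (pair class, valence) cell — add if
  the pair is absent at the planner phase, delete if present. Emission
  probability = recommendations ÷ chances with equal-tailed 95% credible
  intervals from a uniform Beta(1, 1) prior; zero-chance cells are
  missing, and cell denominators partition pairs × rounds.
- **Choice assortativity**: Pearson correlation of the endpoint labels
  over the directed edge list (each edge counted in both orientations).
  Undefined (NaN) for edgeless graphs or uniform labels. This single
  primary definition replaces robustness sweeps across alternative
  specifications; it coincides with the standard numeric attribute
  assortativity coefficient, which serves as an independent cross-check in
  the tests.
- **Degree bias**: mean cooperator degree − mean defector degree; missing
  if either class is empty.
- **Core–periphery**: the discrete Borgatti–Everett-style estimator —
  maximize the Pearson correlation between the off-diagonal adjacency and
  the ideal pattern linking (i, j) iff i or j is in the core. For n ≤ 16
  all 2ⁿ − 2 non-trivial assignments are scored exactly (vectorized, in
  chunks); beyond that a degree-ordered sweep over core sizes is used and
  documented as a heuristic. A constant adjacency or pattern vector has no
  structure to correlate and scores 0. Ties break toward the smaller,
  then lexicographically smaller core, making the output deterministic;
  note that mathematically tied scores computed along different float
  paths may legitimately select different (equally optimal) cores.
- **Core composition test**: labels permuted over nodes; p = (k + 1)/(N + 1)
  where k counts permutations whose cooperator share of the core reaches
  the observed share (add-one correction for Monte-Carlo p-values).
- **Gini / Lorenz**: Gini = Σᵢⱼ|xᵢ − xⱼ| / (2n²·mean) on end-of-game
  capital; the Lorenz curve is the cumulative share of sorted capital.
  Negative values (possible, since cooperation costs capital) make the
  Gini ill-defined, so vectors containing negatives are shifted — by a
  declared endowment, or by default so the minimum is 0 — before
  computation; an all-zero vector returns Gini 0 by convention.

## Synthetic data and what the tests show

The bots are the package's synthetic participants. They capture the
features the planner-comparison question needs — heterogeneous stable
dispositions, reciprocity to neighbourhood cooperation, valence- and
referent-conditional acceptance — and omit much of real human play: no
learning or strategy revision, no memory beyond one round, no end-game
effects, no dropouts, and calibrated rather than fitted parameters.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative ordering of planner effects under this bot model, not
quantitative predictions about human groups. Simulation sizes in the test
suite (20-group campaigns, 2×10⁵ training rounds, 8-player training
groups) are the package's desk-scale defaults, chosen to make the full
suite convenient to run while leaving the tested contrasts far from their
decision thresholds.

## Known limitations

- Single-process training only; no distributed actor framework.
- The batched training environment supports Erdős–Rényi, empty and
  complete initial graphs.
- The core–periphery estimator is exponential-exact only up to n = 16.
- The mixed-logit fitter assumes the generating model's functional form;
  φ estimation treats the two endpoint decisions of one recommendation as
  independent events.
- Checkpointed policies are tied to the group size they were trained on.
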