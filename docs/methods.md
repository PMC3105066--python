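# Methods

## The game

The population is a set of `n` agents on an undirected, unweighted network;
a link is an opportunity for direct interaction, and `N(i)` denotes agent
i's neighbourhood.  Each agent carries two heritable traits encoded as
3-bit strings: boldness `b` (propensity to defect) and vengefulness `v`
(propensity to punish), each taking the eight values 0/7 … 7/7.

One round has three stages:

1. **Defection.**  Each agent draws an observability level `s_i ~ U(0,1)`
   and defects iff `b_i > s_i`.  A defector gains the temptation `T`; every
   other agent in the population suffers the hurt `H` (the spillover of
   defection is global, not limited to neighbours).
2. **Punishment.**  Each neighbour `j ∈ N(i)` of a defector observes the
   defection independently with probability `s_i` — the same draw that
   gated the defection, so bolder defections are also more visible — and,
   if it observes, punishes with probability `v_j`, paying the enforcement
   cost `E` while the defector receives the punishment `P`.  Multiple
   punishments of one defection are cumulative.
3. **Meta-punishment.**  For every observed-but-unpunished defection, each
   common neighbour `l ∈ N(i) ∩ N(j)` sees the lapse independently with
   probability `s_i` and, with probability `v_l`, pays `ME` to inflict `MP`
   on the non-punisher.  Meta-punishment therefore requires a triangle; on
   triangle-free networks the metanorm channel is structurally absent.
   No agent ever sanctions itself (no self-loops), and role decisions are
   independent: a defector may simultaneously punish others.

A **generation** is `rounds_per_generation` rounds (default 4) with payoffs
accumulated from zero, followed by a synchronous update: each agent draws a
parent from its selection pool — neighbourhood plus itself by default —
with probability proportional to fitness, defined as payoff minus the pool
minimum; the parent's boldness and vengefulness bit-strings are copied as a
pair, and every copied bit then flips independently with the mutation rate.
All-zero-fitness pools (all payoffs equal) resolve to a uniform draw, the
roulette-wheel limit; isolated agents keep their own strategy up to
mutation.  Both conventions, and the exclude-self pool variant, are
switchable on `GameConfig`.

Default parameters: `n = 50` agents, 50 000 generations, mutation rate 0.01
per bit, payoffs `T = 3`, `H = −1`, `E = −2`, `P = −9`, `ME = −2`,
`MP = −9`.  All randomness flows through one `numpy` PCG64 generator per
run with a fixed event order (stage-1 draws for all agents, then stage-2
and stage-3 draws per defection event in agent-index order), so runs are
bit-reproducible given (network, config, seed).  Ensembles and sweeps
spawn child seeds from a master `SeedSequence`, making results independent
of execution order.

## Mean-field analysis

For a defection gated by `b` with `s ~ U(0,1)`, the joint moments are
`P(defect) = b`, `P(defect ∧ observed by one fixed neighbour) =
E[s·1(s<b)] = b²/2`, and `P(defect ∧ observed ∧ seen by one fixed common
neighbour) = E[s²·1(s<b)] = b³/3`.  Summing stage payoffs gives the exact
per-agent expected one-round payoff (implemented in
`expected_payoff_exact`); with homogeneous strategies every term is linear
in the agent's degree `k_i` and triplet count `Δ_i`, so the population mean
depends on topology only through the average degree `⟨k⟩` and the
**interconnectedness** `Λ = mean_i Δ_i` (equivalently `Σ_k p(k) c(k)
k(k−1)/2` over the degree distribution, or 3·#triangles/n):

```
π(b, v) = bT + (n−1)bH + ⟨k⟩ (b²/2) v (E+P) + 2Λ (b³/3) v (1−v) (MP+ME)
```

The factor 2Λ counts ordered (defector-neighbour, common-neighbour) pairs.
Because the source equations are only available as images, these closed
forms are derived from the stage mechanics; their correctness contract is
statistical equivalence with the simulator, which the test suite enforces
at 10⁵ Monte-Carlo rounds (3 standard errors) on a complete graph, a ring
lattice and a random graph, over four strategy states.

Evolutionary stability is probed with a single mutant `(b_m, v_m)` in an
otherwise homogeneous population, holding incumbent behaviour fixed
(`mutant_payoff`).  Its own-strategy gradient at mutant = incumbent,

```
∂π_m/∂b_m = T + P ⟨k⟩ v b
∂π_m/∂v_m = E ⟨k⟩ b²/2 + 2Λ (b³/3) [ME (1−v) − MP v]
```

is the drift field drawn by `gradient_map`.  `find_ess` scans the unit
square: interior candidates need vanishing gradient components that are
local payoff maxima; at clamped coordinates the component must point
outside the box (first-order sign conditions — the derivative need not
vanish at a corner).  Edge roots are refined by bracketing (`brentq`,
xtol 1e−12); the gradient zero-threshold defaults to 1e−8 and the scan grid
to 71 points per axis.  These are necessary conditions, not sufficiency
proofs.  Two states matter in practice: **norm collapse** (b, v) = (1, 0),
stable for every topology and payoff matrix with T > 0 and E, ME < 0, and a
**cooperative ESS** at `b* = −T/(P⟨k⟩)`, `v = 1`, which exists iff
`∂π_m/∂v_m ≥ 0` there, i.e. iff Λ exceeds a degree-dependent threshold.
`minimal_interconnectedness` finds that threshold by bisection on the
cooperative-ESS indicator (relative tolerance 1e−4, doubling search for the
upper bracket); for the default payoffs it coincides with the algebraic
solution Λ* = ⟨k⟩²/2, which the tests use as an independent check.  Since
the mutant payoff is linear in `v_m`, interior-`v` stationary states are
neutral rather than strict maxima and are not reported as cooperative ESS.

The analysis treats (b, v) as continuous; the simulator stays on the
8-level grid.  Expected payoffs are per round; scaling by the rounds per
generation rescales gradient magnitudes but moves no ESS.

## Experiments

Zone occupancy follows the ergodicity argument: with positive mutation the
simulation is an irreducible finite Markov chain, so long-run time
fractions approximate the occupancy distribution.  Zones (inclusive
thresholds): collapse = mean b ≥ 6/7 ∧ mean v ≤ 1/7; establishment =
mean b ≤ 1/7 ∧ mean v ≥ 6/7.  `occupancy` uses the whole trajectory by
default (no burn-in) — at the horizons used here the initial transient is
a small fraction of the run and discarding it is a caller's choice.

The default ensemble (`default_ensemble_specs`) mirrors the sampled-
topology design: Watts networks at ring degree k ∈ {2, 4, 6, 8} and
rewiring β ∈ {0, 0.1, 0.3, 1}, Barabási–Albert at m ∈ {1, 2, 3} (complete
seed graph, attachment without replacement), and Erdős–Rényi matched to
⟨k⟩ ∈ {2, 4, 6}, each at neighbourhood radius 1 and 2 — 44 specs at
n = 50.  The test-scale study conditions are 5000 generations and 3 seeds
per network (one sweep ≈ 6 minutes on one core); the full-scale horizon of
50 000 generations and arbitrarily large ensembles are plain parameters,
not separate code paths.

**Trend statistics.**  The claim "establishment occupancy rises with Λ at
fixed ⟨k⟩ and falls with ⟨k⟩ at fixed Λ" is evaluated by
`topology_trends` two ways: Spearman correlations within quantile bins of
the controlled statistic (the heat-map reading), and partial Spearman
correlations (Pearson on rank residuals).  The partial form is the one
asserted for the degree direction, because Λ spans nearly four orders of
magnitude across the ensemble and no practical binning holds it fixed in
the upper range — within a bin spanning Λ ≈ 80–560 the residual Λ
variation dominates the degree effect.  On the default ensemble the
measured values are ρ(est, Λ | ⟨k⟩-bins) ≈ +0.64 and partial
ρ(est, ⟨k⟩ | Λ) ≈ −0.22.

**Empirical drift maps** initialise all agents homogeneously at a grid
point's nearest 8-level strategy (the initialisation protocol is otherwise
unconstrained — homogeneous starts make the cell's nominal (b, v)
exact), run `horizon` generations (default 1) `reps_per_cell` times
(default 200), and report the mean per-generation displacement of the
population means.  Directions correlate positively with the analytic
gradient map away from the near-zero-drift ridge; magnitudes are not
comparable across the two maps (selection intensity and mutation set the
empirical scale).

## What the tests do and do not show

The simulator is validated against the closed forms (payoff conservation
per event type, Monte-Carlo equivalence at 3 SE) and the analytic layer
against finite differences and bracketing; the occupancy experiments are
validated for reproducibility and for the *direction* of topology effects.
None of this implies the mean-field ESS analysis predicts finite-population
trajectories in detail: the simulation exhibits long metastable
quasi-cooperative episodes on networks whose Λ lies *below* the cooperative
threshold.  In these episodes mean vengefulness sits at a
mutation–selection balance around 0.6–0.85, straddling the establishment
boundary 6/7 ≈ 0.857, so a substantial fraction of generations — ≈ 0.47
averaged over the default ensemble at 5000 generations, and 0.38–0.83 on
clustered topologies even at 50 000 generations — falls outside both
zones.  The uniform-draw convention for all-zero-fitness selection pools
contributes to this neutral drift.  The claim that out-of-zone time is
negligible therefore does **not** reproduce under these mechanics at these
horizons, and the corresponding check is left failing rather than widened;
all other behavioural claims hold.

## Known limitations

* ESS conditions are first-order and necessary only; no sufficiency or
  basin-of-attraction analysis, and no transition-matrix computation (the
  64ⁿ state space rules it out).
* The homogeneous closed form is exact for the population *mean* on any
  topology but per-agent exact only on vertex-transitive networks; degree
  heterogeneity enters the mean-field analysis only through ⟨k⟩ and Λ.
* Synthetic homogeneous statistics used for threshold scans need not be
  realisable by an actual simple graph (for homogeneous degree k,
  Λ ≤ k(k−1)/2 < Λ*, so realisable cooperative-ESS networks require degree
  heterogeneity).
* Generators cover preferential-attachment, ring-rewiring and uniform
  random graphs; community-structured or dynamic topologies are out of
  scope, as are weighted or directed interactions and asynchronous
  updates.
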