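# metanorms

Evolutionary dynamics of norms and metanorms on interaction networks.

Costly punishment can sustain cooperative norms, but punishing is itself a
public good: who punishes the non-punishers?  The *metanorms* mechanism
answers with a second sanctioning layer — agents who are seen failing to
punish an observed defection can themselves be punished.  When interactions
are restricted to a social network, this third-party layer needs a
*triangle* of links (defector – non-punisher – meta-punisher), so network
topology directly gates the mechanism.  This package implements the
metanorms game on arbitrary undirected networks three ways:

* **`metanorms.engine`** — a stochastic agent-based simulator.  Each agent
  carries a 3-bit boldness *b* and vengefulness *v* (eight levels 0/7 … 7/7,
  64 joint strategies).  Per round, agent *i* draws an observability level
  s_i ~ U(0,1) and defects iff b_i > s_i, gaining T while every other agent
  loses |H|; each neighbour observes with probability s_i and punishes with
  probability v_j (costs E, inflicts P); each common neighbour of an
  observed-but-unpunishing pair sees the lapse with probability s_i and
  meta-punishes with probability v_l (costs ME, inflicts MP).  A generation
  is four rounds followed by a synchronous local roulette-wheel update
  (fitness = payoff − neighbourhood minimum) with per-bit mutation.
* **`metanorms.analytic`** — the mean-field model.  With the U(0,1)
  observation moments E[s·1(s<b)] = b²/2 and E[s²·1(s<b)] = b³/3, the
  expected one-round payoff of a homogeneous population on a network with
  average degree ⟨k⟩ and interconnectedness Λ (mean triangles through a
  node) is

      π(b, v) = bT + (n−1)bH + ⟨k⟩ (b²/2) v (E+P) + 2Λ (b³/3) v (1−v) (MP+ME)

  Mutant-payoff gradients over (b, v) yield drift maps and evolutionary
  stable states: norm collapse (b, v) = (1, 0) is always an ESS, and a
  cooperative ESS (b* = −T/(P⟨k⟩), v = 1) exists only above a minimal
  interconnectedness Λ*(⟨k⟩), found by bisection.
* **`metanorms.experiments`** — long-run occupancy of the norm-collapse
  zone (mean b ≥ 6/7, mean v ≤ 1/7) and norm-establishment zone
  (mean b ≤ 1/7, mean v ≥ 6/7) across network ensembles
  (Barabási–Albert, Watts ring-rewiring, Erdős–Rényi; radius 1 or 2), and
  empirical drift maps to compare against the analytic prediction.

Intended users: researchers in evolutionary game theory, social simulation
and cooperation on networks.

## Worked example

```python
from metanorms import (GameConfig, generate_watts, radius2_closure,
                       network_stats, find_ess, minimal_interconnectedness,
                       run_simulation, occupancy)

net = radius2_closure(generate_watts(50, 4, 0.0, seed=1))   # k=4 ring, radius 2
stats = network_stats(net)
print(stats.avg_degree, stats.interconnectedness)           # 8.00  18.00

cfg = GameConfig(generations=5000, seed=42)                 # Table-style defaults
for p in find_ess(stats, cfg).points:
    print(p.label, round(p.b, 4), round(p.v, 4))            # collapse 1.0 0.0
print(minimal_interconnectedness(stats.avg_degree, cfg))    # 32.00

occ = occupancy(run_simulation(net, cfg))
print(occ.collapse, occ.establishment, occ.neither)         # 0.426 0.026 0.548
```

Reading: the radius-2 ring has ⟨k⟩ = 8 and Λ = 18 triplets per agent — too
few triangles for a cooperative ESS (Λ* = 32 at this degree), so the only
stable state is norm collapse at full boldness and zero vengefulness.  The
simulation agrees in the long run (43% of generations in the collapse zone,
3% in establishment) but also shows the metastable quasi-cooperative
episodes near the establishment boundary that the mean-field model does not
capture (55% of generations outside both zones on this topology).

The same pipeline is scriptable from a shell:

```bash
metanorms generate --model watts --n 50 --k 4 --beta 0 --radius 2 --seed 1 --out net.graphml
metanorms stats --in net.graphml --out stats.json
metanorms ess --stats stats.json
metanorms simulate --net net.graphml --generations 5000 --seed 42 --out traj.csv
```

Every CLI output is accompanied by a `*.manifest.json` with the fully
resolved configuration and seeds needed to regenerate it bit-identically.

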