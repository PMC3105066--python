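"""Interaction networks and their topology statistics.

The interaction substrate of the metanorms game is an undirected, unweighted
graph on ``n`` agents.  This module provides the three generators used in the
experiments (Barabási–Albert preferential attachment, Watts ring-rewiring and
Erdős–Rényi), the radius-2 neighbourhood expansion, and the per-node and
aggregate topology statistics that drive both the simulator and the analytic
model: degree distribution, clustering by degree, average degree and
*interconnectedness* — the average number of triplets (connected neighbour
pairs, i.e. triangles through a node) per agent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "NetworkStats",
    "generate_ba",
    "generate_watts",
    "generate_er",
    "radius2_closure",
    "node_triplets",
    "node_clustering",
    "network_stats",
    "sample_networks",
]


class InteractionNetwork:
    """Undirected, unweighted graph on agents ``0..n-1``.

    Invariants enforced on construction: symmetry, no self-loops, indices in
    range, duplicate edges collapsed.  Adjacency is queryable as neighbour
    sets; a boolean adjacency matrix and padded neighbour arrays are cached
    lazily for the vectorised game engine.
    """

    def __init__(self, n: int, edges) -> None:
        if n <= 0:
            raise ValueError(f"agent count must be positive, got {n}")
        self.n = int(n)
        seen: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on agent {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) outside 0..{n - 1}")
            seen.add((min(u, v), max(u, v)))
        self.edges: frozenset[tuple[int, int]] = frozenset(seen)
        nbrs: list[set[int]] = [set() for _ in range(self.n)]
        for u, v in self.edges:
            nbrs[u].add(v)
            nbrs[v].add(u)
        self._nbrs = [frozenset(s) for s in nbrs]
        self._adj: np.ndarray | None = None
        self._pools: tuple[np.ndarray, np.ndarray] | None = None

    # -- queries -----------------------------------------------------------

    def neighbors(self, i: int) -> frozenset[int]:
        return self._nbrs[i]

    def degree(self, i: int) -> int:
        return len(self._nbrs[i])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self._nbrs], dtype=np.int64)

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix (cached; do not mutate)."""
        if self._adj is None:
            a = np.zeros((self.n, self.n), dtype=bool)
            for u, v in self.edges:
                a[u, v] = a[v, u] = True
            self._adj = a
        return self._adj

    def selection_pools(self, include_self: bool = True):
        """Padded (pool_idx, pool_mask) arrays of each agent's neighbourhood
        plus (optionally) itself, used by roulette-wheel selection.

        Isolated agents always have themselves in the pool so selection is
        well defined.  Padding repeats the agent's own index with mask False.
        """
        if self._pools is None or self._pools_include_self != include_self:
            pools = []
            for i in range(self.n):
                p = sorted(self._nbrs[i])
                if include_self or not p:
                    p = p + [i]
                pools.append(p)
            width = max(len(p) for p in pools)
            idx = np.empty((self.n, width), dtype=np.int64)
            mask = np.zeros((self.n, width), dtype=bool)
            for i, p in enumerate(pools):
                idx[i, : len(p)] = p
                idx[i, len(p):] = i
                mask[i, : len(p)] = True
            self._pools = (idx, mask)
            self._pools_include_self = include_self
        return self._pools

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        nodes = sorted(g.nodes())
        relabel = {u: i for i, u in enumerate(nodes)}
        return cls(len(nodes), [(relabel[u], relabel[v]) for u, v in g.edges()])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(sorted(self.edges))
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InteractionNetwork)
            and self.n == other.n
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n, self.edges))

    def __repr__(self) -> str:
        return f"InteractionNetwork(n={self.n}, edges={self.n_edges})"


@dataclass
class NetworkStats:
    """Aggregate topology statistics of an interaction network.

    ``interconnectedness`` is the mean number of triplets per agent,
    Λ = (1/n)·Σ_i Δ_i, where Δ_i counts linked pairs among i's neighbours;
    each triangle of the graph contributes one triplet to each of its three
    corners, so Λ = 3·(#triangles)/n.
    """

    n: int
    avg_degree: float
    interconnectedness: float
    degree_dist: dict[int, float] = field(default_factory=dict)
    clustering_by_degree: dict[int, float] = field(default_factory=dict)

    @property
    def mean_clustering(self) -> float:
        """Degree-distribution-weighted mean clustering, Σ_k p(k)·c(k)."""
        return sum(
            p * self.clustering_by_degree.get(k, 0.0)
            for k, p in self.degree_dist.items()
        )

    @classmethod
    def homogeneous(
        cls, avg_degree: float, interconnectedness: float, n: int = 50
    ) -> "NetworkStats":
        """Synthetic statistics of an idealised degree-homogeneous network,
        used to scan the analytic model over (⟨k⟩, Λ) without constructing a
        graph.  The pair need not be realisable by an actual simple graph.
        """
        k = avg_degree
        c = (
            2.0 * interconnectedness / (k * (k - 1.0))
            if k > 1.0
            else 0.0
        )
        return cls(
            n=n,
            avg_degree=k,
            interconnectedness=interconnectedness,
            degree_dist={round(k): 1.0},
            clustering_by_degree={round(k): c},
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_ba(n: int, m: int, seed=None) -> InteractionNetwork:
    """Barabási–Albert preferential-attachment network.

    Starts from a complete graph on ``m`` nodes; each subsequent node
    attaches to ``m`` distinct existing nodes chosen with probability
    proportional to their current degree (sampling without replacement).
    ``m = 1`` yields a tree; degree distributions follow a discrete Pareto
    law for large ``n``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if n < m + 1:
        raise ValueError(f"need n >= m + 1, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = list(itertools.combinations(range(m), 2))
    # repeated-nodes list: each node appears once per unit of degree
    repeated: list[int] = [u for e in edges for u in e]
    for new in range(m, n):
        targets: set[int] = set()
        if not repeated:
            # m = 1 seed node has degree 0: first attachment is forced
            targets.add(new - 1)
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):
            edges.append((t, new))
            repeated.extend((t, new))
    return InteractionNetwork(n, edges)


def generate_watts(n: int, k: int, beta: float, seed=None) -> InteractionNetwork:
    """Watts ring-rewiring network (small-world interpolation).

    A ring lattice where each node is linked to its ``k`` nearest neighbours
    (``k`` even); one endpoint of every lattice edge is rewired to a uniform
    random non-neighbour with probability ``beta``, rejecting self-loops and
    duplicates.  ``beta = 0`` is the regular lattice, ``beta = 1`` a random
    network of the same density; the edge count n·k/2 is preserved.
    """
    if k % 2 != 0:
        raise ValueError(f"ring degree k must be even, got {k}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {beta}")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    g = nx.watts_strogatz_graph(n, k, beta, seed=_int_seed(seed))
    return InteractionNetwork.from_networkx(g)


def generate_er(n: int, p: float, seed=None) -> InteractionNetwork:
    """Erdős–Rényi G(n, p): every pair linked independently with prob. p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=_int_seed(seed))
    return InteractionNetwork.from_networkx(g)


def _int_seed(seed) -> int | None:
    """Collapse any seed spec to a plain int for networkx generators."""
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    return int(np.random.default_rng(seed).integers(2**31))


def radius2_closure(net: InteractionNetwork) -> InteractionNetwork:
    """Expand neighbourhoods to radius 2: link i, j iff their shortest-path
    distance in ``net`` is 1 or 2.  Idempotent on graphs of diameter ≤ 2."""
    a = net.adjacency()
    two = a @ a  # paths of length 2 (integer counts)
    closure = a | (two > 0)
    np.fill_diagonal(closure, False)
    iu, ju = np.nonzero(np.triu(closure))
    return InteractionNetwork(net.n, zip(iu.tolist(), ju.tolist()))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def node_triplets(net: InteractionNetwork, i: int) -> int:
    """Number of linked pairs among i's neighbours (= triangles through i)."""
    if not 0 <= i < net.n:
        raise IndexError(f"agent index {i} out of range 0..{net.n - 1}")
    nbrs = sorted(net.neighbors(i))
    count = 0
    for a_pos, j in enumerate(nbrs):
        nj = net.neighbors(j)
        for l in nbrs[a_pos + 1:]:
            if l in nj:
                count += 1
    return count


def node_clustering(net: InteractionNetwork, i: int) -> float:
    """Fraction of linked neighbour pairs, Δ_i / C(k_i, 2).

    Defined only for agents with at least two neighbours.
    """
    k = net.degree(i)
    if k < 2:
        raise ValueError(f"clustering undefined for degree {k} (agent {i})")
    return node_triplets(net, i) / math.comb(k, 2)


def network_stats(net: InteractionNetwork) -> NetworkStats:
    """All aggregate statistics of ``net``.

    Nodes of degree < 2 contribute clustering 0 to their degree class so the
    clustering-by-degree map is total; they contribute 0 triplets regardless.
    """
    degrees = net.degrees()
    n = net.n
    triplets = np.array([node_triplets(net, i) for i in range(n)])
    degree_dist = {
        int(k): int(c) / n for k, c in zip(*np.unique(degrees, return_counts=True))
    }
    clustering_by_degree: dict[int, float] = {}
    for k in degree_dist:
        idx = np.nonzero(degrees == k)[0]
        if k < 2:
            clustering_by_degree[k] = 0.0
        else:
            clustering_by_degree[k] = float(
                np.mean(triplets[idx]) / math.comb(k, 2)
            )
    return NetworkStats(
        n=n,
        avg_degree=float(degrees.mean()),
        interconnectedness=float(triplets.mean()),
        degree_dist=degree_dist,
        clustering_by_degree=clustering_by_degree,
    )


# ---------------------------------------------------------------------------
# Ensemble sampling
# ---------------------------------------------------------------------------

_GENERATORS = {"ba": generate_ba, "watts": generate_watts, "er": generate_er}


def sample_networks(
    specs: list[dict],
    samples_per_spec: int = 1,
    seed=None,
) -> list[tuple[dict, InteractionNetwork]]:
    """Sample an ensemble of networks from parameter-grid specs.

    Each spec is a dict with a ``model`` key (``ba`` / ``watts`` / ``er``),
    the generator's parameters, and optionally ``radius: 2`` to expand
    neighbourhoods.  Child seeds are spawned deterministically from ``seed``
    so the ensemble is reproducible regardless of iteration order.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * samples_per_spec)
    out: list[tuple[dict, InteractionNetwork]] = []
    pos = 0
    for spec in specs:
        spec = dict(spec)
        model = spec.pop("model")
        radius = spec.pop("radius", 1)
        if model not in _GENERATORS:
            raise ValueError(f"unknown network model {model!r}")
        for _ in range(samples_per_spec):
            child = int(children[pos].generate_state(1)[0] % (2**31))
            pos += 1
            net = _GENERATORS[model](**spec, seed=child)
            if radius == 2:
                net = radius2_closure(net)
            elif radius != 1:
                raise ValueError(f"radius must be 1 or 2, got {radius}")
            out.append(({"model": model, "radius": radius, **spec, "seed": child}, net))
    return out
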