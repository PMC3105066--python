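"""Mean-field analysis of the metanorms game on networks.

With the observability level s of each defection drawn from U(0,1), the
probability that an agent with boldness b defects is b, that its defection
is also observed by one fixed neighbour is E[s·1(s<b)] = b²/2, and that it
is both observed by a neighbour and seen by one fixed common neighbour is
E[s²·1(s<b)] = b³/3.  These moments turn the stage mechanics into closed
forms for expected one-round payoffs:

*   exact, per agent i on a concrete network (heterogeneous strategies):

    π_i = b_i·T + H·Σ_{j≠i} b_j
          + E·v_i·Σ_{j∈N(i)} b_j²/2  +  P·(b_i²/2)·Σ_{j∈N(i)} v_j
          + MP·(1−v_i)·Σ_{j∈N(i)} (b_j³/3)·Σ_{l∈N(i)∩N(j)} v_l
          + ME·v_i·Σ_{j∈N(i)} (b_j³/3)·Σ_{l∈N(i)∩N(j)} (1−v_l)

*   homogeneous (all agents at (b, v)), in terms of the average degree ⟨k⟩
    and the interconnectedness Λ (mean triplets per agent):

    π(b, v) = bT + (n−1)bH + ⟨k⟩·(b²/2)·v·(E+P)
              + 2Λ·(b³/3)·v·(1−v)·(MP+ME)

Evolutionary stability is probed through the payoff of a single mutant at
(b_m, v_m) in an otherwise homogeneous population: its own-strategy
gradient, evaluated at mutant = incumbent, gives the drift field over the
(b, v) square.  The norm-collapse state (b, v) = (1, 0) is always a local
ESS; a cooperative ESS (low boldness, full vengefulness) appears only when
the interconnectedness exceeds a degree-dependent threshold, computed here
by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .engine import GameConfig
from .network import InteractionNetwork, NetworkStats

__all__ = [
    "HomogeneousState",
    "GradientField",
    "ESSPoint",
    "ESSResult",
    "expected_payoff_exact",
    "expected_payoff_homogeneous",
    "mutant_payoff",
    "mutant_gradient",
    "gradient_map",
    "find_ess",
    "minimal_interconnectedness",
]


@dataclass(frozen=True)
class HomogeneousState:
    """Continuous-relaxation population state (b, v) ∈ [0,1]²."""

    b: float
    v: float

    def __post_init__(self):
        for name, x in (("boldness", self.b), ("vengefulness", self.v)):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {x}")


# ---------------------------------------------------------------------------
# Expected payoffs
# ---------------------------------------------------------------------------


def expected_payoff_exact(
    net: InteractionNetwork,
    boldness: np.ndarray,
    vengefulness: np.ndarray,
    config: GameConfig,
) -> np.ndarray:
    """Exact per-agent expected one-round payoff on a concrete network."""
    b = np.asarray(boldness, dtype=float)
    v = np.asarray(vengefulness, dtype=float)
    n = net.n
    if b.size != n or v.size != n:
        raise ValueError("strategy vectors must have one entry per agent")
    a = net.adjacency().astype(float)
    q2 = b**2 / 2.0  # P(defect & observed by a fixed neighbour)
    q3 = b**3 / 3.0  # P(defect & observed & seen by a fixed common neighbour)

    pi = config.temptation * b + config.hurt * (b.sum() - b)
    pi += config.enforcement * v * (a @ q2)
    pi += config.punishment * q2 * (a @ v)
    # weighted common-neighbour matrices: M[i,j] = Σ_l a_il a_jl w_l
    m_v = a @ (a * v[:, None])
    m_nv = a @ (a * (1.0 - v)[:, None])
    pi += config.meta_punishment * (1.0 - v) * ((a * m_v) @ q3)
    pi += config.meta_enforcement * v * ((a * m_nv) @ q3)
    return pi


def expected_payoff_homogeneous(
    stats: NetworkStats, state: HomogeneousState, config: GameConfig
) -> float:
    """Expected one-round payoff of a homogeneous population at (b, v),
    as a function of average degree and interconnectedness only."""
    b, v = state.b, state.v
    k = stats.avg_degree
    lam = stats.interconnectedness
    return (
        b * config.temptation
        + (stats.n - 1) * b * config.hurt
        + k * (b**2 / 2.0) * v * (config.enforcement + config.punishment)
        + 2.0
        * lam
        * (b**3 / 3.0)
        * v
        * (1.0 - v)
        * (config.meta_punishment + config.meta_enforcement)
    )


def mutant_payoff(
    stats: NetworkStats,
    b_m,
    v_m,
    state: HomogeneousState,
    config: GameConfig,
) -> np.ndarray | float:
    """Expected one-round payoff of a single mutant at (b_m, v_m) embedded
    in a population homogeneous at ``state``, for an agent with the network's
    average degree and triplet count.  Incumbent behaviour is held fixed:
    the mutant is hurt by incumbent defections, pays enforcement at its own
    v_m on incumbent defections, is punished at the incumbents' v, and so
    on.  Accepts scalars or broadcastable arrays for (b_m, v_m).
    """
    b_m = np.asarray(b_m, dtype=float)
    v_m = np.asarray(v_m, dtype=float)
    b, v = state.b, state.v
    k = stats.avg_degree
    lam2 = 2.0 * stats.interconnectedness  # ordered common-neighbour pairs
    out = (
        config.temptation * b_m
        + config.hurt * (stats.n - 1) * b
        + config.enforcement * v_m * k * (b**2 / 2.0)
        + config.punishment * (b_m**2 / 2.0) * k * v
        + config.meta_punishment * (1.0 - v_m) * lam2 * (b**3 / 3.0) * v
        + config.meta_enforcement * v_m * lam2 * (b**3 / 3.0) * (1.0 - v)
    )
    return out if out.shape else float(out)


def mutant_gradient(
    stats: NetworkStats, state: HomogeneousState, config: GameConfig
) -> tuple[float, float]:
    """Own-strategy payoff gradient of a mutant, evaluated at
    mutant = incumbent: (∂π_m/∂b_m, ∂π_m/∂v_m) at (b_m, v_m) = (b, v).

    This is the drift vector used for gradient maps: a positive component
    means a mutant nudging that trait upward gains expected payoff.
    """
    b, v = state.b, state.v
    k = stats.avg_degree
    lam2 = 2.0 * stats.interconnectedness
    db = config.temptation + config.punishment * b * k * v
    dv = (
        config.enforcement * k * (b**2 / 2.0)
        + lam2
        * (b**3 / 3.0)
        * (config.meta_enforcement * (1.0 - v) - config.meta_punishment * v)
    )
    return float(db), float(dv)


# ---------------------------------------------------------------------------
# Gradient maps
# ---------------------------------------------------------------------------


@dataclass
class GradientField:
    """Drift vectors (db, dv) on a grid over the (b, v) square.

    Produced analytically by :func:`gradient_map` or empirically by
    ``experiments.empirical_drift_map``; ``speed`` is the vector norm.
    """

    b: np.ndarray  # (rb, rv) meshgrid, boldness axis
    v: np.ndarray
    db: np.ndarray
    dv: np.ndarray
    stats: NetworkStats | None = None
    config: GameConfig | None = None
    kind: str = "analytic"

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.db, self.dv)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "b": self.b.ravel(),
                "v": self.v.ravel(),
                "db": self.db.ravel(),
                "dv": self.dv.ravel(),
                "speed": self.speed.ravel(),
            }
        )


def gradient_map(
    stats: NetworkStats, config: GameConfig, grid: int = 71
) -> GradientField:
    """Evaluate the mutant gradient on a ``grid`` × ``grid`` lattice over
    [0,1]²; the analytic analogue of an empirical drift map."""
    if grid < 2:
        raise ValueError("grid resolution must be >= 2 per axis")
    bs = np.linspace(0.0, 1.0, grid)
    vs = np.linspace(0.0, 1.0, grid)
    bb, vv = np.meshgrid(bs, vs, indexing="ij")
    db = np.empty_like(bb)
    dv = np.empty_like(bb)
    for i in range(grid):
        for j in range(grid):
            db[i, j], dv[i, j] = mutant_gradient(
                stats, HomogeneousState(bb[i, j], vv[i, j]), config
            )
    return GradientField(bb, vv, db, dv, stats, config, kind="analytic")


# ---------------------------------------------------------------------------
# Evolutionary stable states
# ---------------------------------------------------------------------------


@dataclass
class ESSPoint:
    b: float
    v: float
    label: str  # "collapse" | "cooperative" | "other"
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ESSResult:
    points: list[ESSPoint]
    stats: NetworkStats | None = None

    @property
    def collapse(self) -> ESSPoint | None:
        return next((p for p in self.points if p.label == "collapse"), None)

    @property
    def cooperative(self) -> ESSPoint | None:
        return next((p for p in self.points if p.label == "cooperative"), None)

    @property
    def has_cooperative(self) -> bool:
        return self.cooperative is not None


def _label(b: float, v: float) -> str:
    if b >= 0.5 and v <= 0.5:
        return "collapse"
    if v >= 0.5 and b < 0.5:
        return "cooperative"
    return "other"


def find_ess(
    stats: NetworkStats,
    config: GameConfig,
    grid_resolution: int = 71,
    tolerance: float = 1e-8,
) -> ESSResult:
    """Locate candidate evolutionary stable states on [0,1]².

    A state satisfies the implemented necessary conditions when no mutant
    direction inside the feasible box increases the mutant's expected
    payoff to first order:

    * interior coordinate: the corresponding gradient component vanishes
      and is locally a payoff maximum (non-increasing through the root);
    * boundary coordinate at 0: the component is ≤ 0 (pushing outward);
      at 1: the component is ≥ 0.

    Corners, edges and the interior are scanned on a ``grid_resolution``
    lattice; roots along edges are refined by bracketing.  Points are
    labelled *collapse* (high b, low v) or *cooperative* (low b, high v).
    """

    def g_b(b, v):
        return mutant_gradient(stats, HomogeneousState(b, v), config)[0]

    def g_v(b, v):
        return mutant_gradient(stats, HomogeneousState(b, v), config)[1]

    tol = tolerance
    pts: list[ESSPoint] = []

    def push(b, v, diag):
        for p in pts:
            if abs(p.b - b) < 1e-6 and abs(p.v - v) < 1e-6:
                return
        pts.append(ESSPoint(float(b), float(v), _label(b, v), diag))

    def boundary_ok(x, g):
        # outward-pointing (KKT) condition at a clamped coordinate
        if x <= 0.0:
            return g <= tol
        return g >= -tol

    # corners
    for cb in (0.0, 1.0):
        for cv in (0.0, 1.0):
            gb, gv = g_b(cb, cv), g_v(cb, cv)
            if boundary_ok(cb, gb) and boundary_ok(cv, gv):
                push(cb, cv, {"g_b": gb, "g_v": gv, "type": "corner"})

    xs = np.linspace(0.0, 1.0, max(grid_resolution, 11))

    def edge_roots(gfun):
        """Roots of gfun on (0,1) where gfun crosses from + to − (local
        payoff maximum along the edge)."""
        vals = np.array([gfun(x) for x in xs])
        roots = []
        for i in range(len(xs) - 1):
            if vals[i] > 0.0 >= vals[i + 1]:
                r = optimize.brentq(gfun, xs[i], xs[i + 1], xtol=1e-12)
                roots.append(r)
        return roots

    # horizontal edges (v clamped, b interior)
    for cv in (0.0, 1.0):
        for rb in edge_roots(lambda x: g_b(x, cv)):
            if 0.0 < rb < 1.0:
                gv = g_v(rb, cv)
                if boundary_ok(cv, gv):
                    push(rb, cv, {"g_b": g_b(rb, cv), "g_v": gv, "type": "edge"})
    # vertical edges (b clamped, v interior)
    for cb in (0.0, 1.0):
        for rv in edge_roots(lambda x: g_v(cb, x)):
            if 0.0 < rv < 1.0:
                gb = g_b(cb, rv)
                if boundary_ok(cb, gb):
                    push(cb, rv, {"g_b": gb, "g_v": g_v(cb, rv), "type": "edge"})

    # interior: cells where both components change sign
    gbs = np.array([[g_b(b, v) for v in xs] for b in xs])
    gvs = np.array([[g_v(b, v) for v in xs] for b in xs])
    for i in range(len(xs) - 1):
        for j in range(len(xs) - 1):
            sb = gbs[i : i + 2, j : j + 2]
            sv = gvs[i : i + 2, j : j + 2]
            if sb.min() <= 0.0 <= sb.max() and sv.min() <= 0.0 <= sv.max():
                sol = optimize.root(
                    lambda x: [g_b(*np.clip(x, 0.0, 1.0)), g_v(*np.clip(x, 0.0, 1.0))],
                    [xs[i : i + 2].mean(), xs[j : j + 2].mean()],
                    method="hybr",
                )
                b0, v0 = np.clip(sol.x, 0.0, 1.0)
                if not sol.success or not (0.0 < b0 < 1.0 and 0.0 < v0 < 1.0):
                    continue
                if abs(g_b(b0, v0)) > 1e-6 or abs(g_v(b0, v0)) > 1e-6:
                    continue
                # local-maximum check in each coordinate (finite differences)
                h = 1e-5
                if (
                    g_b(min(b0 + h, 1.0), v0) <= tol
                    and g_b(max(b0 - h, 0.0), v0) >= -tol
                    and g_v(b0, min(v0 + h, 1.0)) <= tol
                    and g_v(b0, max(v0 - h, 0.0)) >= -tol
                ):
                    push(b0, v0, {"g_b": 0.0, "g_v": 0.0, "type": "interior"})

    return ESSResult(pts, stats)


def minimal_interconnectedness(
    avg_degree: float,
    config: GameConfig,
    n: int = 50,
    tol: float = 1e-4,
    lambda_max: float = 1e6,
) -> float:
    """Smallest interconnectedness Λ* at which a cooperative ESS exists for
    an idealised degree-homogeneous network with the given average degree.

    Computed by bisection on Λ of the cooperative-ESS indicator from
    :func:`find_ess`; returns ``inf`` if no cooperative ESS exists below
    ``lambda_max``.  ``tol`` is the relative bisection tolerance.
    """
    if avg_degree < 0:
        raise ValueError("average degree must be >= 0")

    def has_coop(lam: float) -> bool:
        stats = NetworkStats.homogeneous(avg_degree, lam, n=n)
        return find_ess(stats, config, grid_resolution=41).has_cooperative

    hi = 1.0
    while not has_coop(hi):
        hi *= 2.0
        if hi > lambda_max:
            return float("inf")
    lo = 0.0
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if has_coop(mid):
            hi = mid
        else:
            lo = mid
    return hi
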