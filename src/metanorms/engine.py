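"""The three-stage metanorms game and its evolutionary update.

One *round* of the game on a network proceeds in three stages.  Each agent i
draws an observability level s_i ~ U(0,1) and defects iff its boldness
exceeds it (b_i > s_i); a defector collects the temptation payoff T while
every other agent in the population is hurt by H (the spillover of defection
is global).  In stage 2 each network neighbour j of a defector i observes
the defection independently with probability s_i and, if it observes,
punishes with probability equal to its vengefulness v_j, paying the
enforcement cost E to impose the punishment P on i.  Stage 3 implements the
metanorm: for every observed-but-unpunished defection, each common neighbour
l of defector and non-punisher sees the lapse with the same probability s_i
and, with probability v_l, pays the meta-enforcement cost ME to impose the
meta-punishment MP on the non-punisher.  Meta-punishment therefore requires
a triangle of links among defector, non-punisher and meta-punisher.

A *generation* is four rounds with payoffs accumulated from zero, followed
by a synchronous, locally applied roulette-wheel update: each agent copies
the (boldness, vengefulness) bit-strings of a member of its neighbourhood
(including itself by default) with probability proportional to fitness —
payoff minus the minimum payoff in that pool — after which every copied bit
flips independently with the mutation rate.

Boldness and vengefulness are 3-bit traits taking the eight evenly spaced
values 0/7 … 7/7, giving 64 joint strategies per agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import InteractionNetwork

__all__ = [
    "TRAIT_LEVELS",
    "Strategy",
    "GameConfig",
    "Population",
    "RoundEvents",
    "Trajectory",
    "play_round",
    "selection_probabilities",
    "evolve_generation",
    "run_simulation",
    "mc_mean_payoff",
]

#: number of levels each 3-bit trait can take
TRAIT_LEVELS = 8
_MAX = TRAIT_LEVELS - 1


@dataclass(frozen=True)
class Strategy:
    """One agent's heritable strategy: 3-bit boldness and vengefulness."""

    b_level: int
    v_level: int

    def __post_init__(self):
        for name, lv in (("boldness", self.b_level), ("vengefulness", self.v_level)):
            if not 0 <= lv <= _MAX:
                raise ValueError(f"{name} level must be in 0..{_MAX}, got {lv}")

    @property
    def boldness(self) -> float:
        return self.b_level / _MAX

    @property
    def vengefulness(self) -> float:
        return self.v_level / _MAX

    @property
    def b_bits(self) -> str:
        return format(self.b_level, "03b")

    @property
    def v_bits(self) -> str:
        return format(self.v_level, "03b")

    @classmethod
    def from_bits(cls, b_bits: str, v_bits: str) -> "Strategy":
        return cls(int(b_bits, 2), int(v_bits, 2))

    @classmethod
    def all_strategies(cls) -> list["Strategy"]:
        """Enumerate the full joint strategy space (64 strategies)."""
        return [
            cls(b, v) for b in range(TRAIT_LEVELS) for v in range(TRAIT_LEVELS)
        ]


@dataclass
class GameConfig:
    """Payoffs and evolutionary parameters of the metanorms game.

    Defaults are Axelrod's payoff matrix with 50 agents: T = 3, H = −1,
    E = −2, P = −9, ME = −2, MP = −9, mutation rate 0.01 per bit, 4 rounds
    per generation, 50 000 generations.
    """

    temptation: float = 3.0
    hurt: float = -1.0
    enforcement: float = -2.0
    punishment: float = -9.0
    meta_enforcement: float = -2.0
    meta_punishment: float = -9.0
    mutation_rate: float = 0.01
    rounds_per_generation: int = 4
    generations: int = 50_000
    n_agents: int = 50
    seed: int | None = None
    #: include the focal agent in its own selection pool
    include_self: bool = True
    #: apply bit mutation also when an agent re-copies its own strategy
    mutate_on_self_copy: bool = True

    _ALIASES = {
        "T": "temptation",
        "H": "hurt",
        "E": "enforcement",
        "P": "punishment",
        "ME": "meta_enforcement",
        "MP": "meta_punishment",
    }

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.mutation_rate}")
        if self.rounds_per_generation < 1:
            raise ValueError("rounds_per_generation must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "GameConfig":
        """Build a config from a mapping; short payoff keys (T, H, E, P, ME,
        MP) are accepted alongside the full field names."""
        kw = {cls._ALIASES.get(k, k): v for k, v in d.items()}
        return cls(**kw)

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if not k.startswith("_")
        }
        return out

    def replace(self, **kw) -> "GameConfig":
        return replace(self, **kw)


@dataclass
class Population:
    """Per-agent strategy levels as integer arrays in 0..7."""

    b_levels: np.ndarray
    v_levels: np.ndarray

    def __post_init__(self):
        self.b_levels = np.asarray(self.b_levels, dtype=np.int64)
        self.v_levels = np.asarray(self.v_levels, dtype=np.int64)
        if self.b_levels.shape != self.v_levels.shape:
            raise ValueError("boldness/vengefulness arrays must match in length")
        for arr in (self.b_levels, self.v_levels):
            if arr.min(initial=0) < 0 or arr.max(initial=0) > _MAX:
                raise ValueError(f"strategy levels must lie in 0..{_MAX}")

    @property
    def n(self) -> int:
        return self.b_levels.size

    @property
    def boldness(self) -> np.ndarray:
        return self.b_levels / _MAX

    @property
    def vengefulness(self) -> np.ndarray:
        return self.v_levels / _MAX

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "Population":
        """Uniform over the 64 joint strategies, per agent."""
        return cls(rng.integers(0, TRAIT_LEVELS, n), rng.integers(0, TRAIT_LEVELS, n))

    @classmethod
    def homogeneous(cls, n: int, b_level: int, v_level: int) -> "Population":
        return cls(np.full(n, b_level), np.full(n, v_level))

    def strategies(self) -> list[Strategy]:
        return [Strategy(int(b), int(v)) for b, v in zip(self.b_levels, self.v_levels)]


@dataclass
class RoundEvents:
    """Event counts of one round, for payoff-conservation accounting."""

    defections: int = 0
    observations: int = 0
    punishments: int = 0
    meta_punishments: int = 0


@dataclass
class Trajectory:
    """Per-generation record of population mean boldness and vengefulness.

    Index 0 is the initial population; index g the state after generation g,
    so the arrays have ``generations + 1`` entries.  Full strategy snapshots
    are stored at a configurable stride when requested.
    """

    mean_boldness: np.ndarray
    mean_vengefulness: np.ndarray
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    config: GameConfig | None = None

    @property
    def generations(self) -> int:
        return self.mean_boldness.size - 1

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(self.mean_boldness.size),
                "mean_boldness": self.mean_boldness,
                "mean_vengefulness": self.mean_vengefulness,
            }
        )


# ---------------------------------------------------------------------------
# One round
# ---------------------------------------------------------------------------


def play_round(
    net: InteractionNetwork,
    pop: Population,
    config: GameConfig,
    rng: np.random.Generator,
    return_events: bool = False,
):
    """Play one round; returns the per-agent round payoffs.

    Event order is fixed for reproducibility: stage-1 draws for all agents,
    then stage-2 observation/punishment draws per defector in agent-index
    order, then stage-3 draws per (defector, non-punishing observer) pair in
    the same order.  With ``return_events`` also returns a
    :class:`RoundEvents` tally.
    """
    n = net.n
    if pop.n != n:
        raise ValueError(f"strategy vector length {pop.n} != agent count {n}")
    b = pop.boldness
    v = pop.vengefulness
    T, H = config.temptation, config.hurt
    E, P = config.enforcement, config.punishment
    ME, MP = config.meta_enforcement, config.meta_punishment

    payoffs = np.zeros(n)
    events = RoundEvents()

    # stage 1: defection. s_i is both the defection gate and, later, the
    # per-observer observation probability for i's defection.
    s = rng.random(n)
    defect = b > s
    d_idx = np.nonzero(defect)[0]
    nd = d_idx.size
    events.defections = int(nd)
    if nd:
        payoffs += T * defect
        payoffs += H * (nd - defect)  # each agent hurt once per *other* defection

    if nd:
        a = net.adjacency()
        arows = a[d_idx]  # (nd, n) neighbour masks of defectors
        # stage 2: observation and punishment
        obs = (rng.random((nd, n)) < s[d_idx][:, None]) & arows
        pun = obs & (rng.random((nd, n)) < v[None, :])
        events.observations = int(obs.sum())
        events.punishments = int(pun.sum())
        payoffs += E * pun.sum(axis=0)
        payoffs[d_idx] += P * pun.sum(axis=1)

        # stage 3: meta-punishment of observed non-punishers, only on
        # triangles (defector, non-punisher, common neighbour)
        lapse = obs & ~pun
        li, lj = np.nonzero(lapse)
        if li.size:
            di = d_idx[li]
            common = arows[li] & a[lj]
            sees = rng.random((li.size, n)) < s[di][:, None]
            meta = common & sees & (rng.random((li.size, n)) < v[None, :])
            events.meta_punishments = int(meta.sum())
            payoffs += ME * meta.sum(axis=0)
            np.add.at(payoffs, lj, MP * meta.sum(axis=1))

    if return_events:
        return payoffs, events
    return payoffs


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def selection_probabilities(pool_payoffs: np.ndarray) -> np.ndarray:
    """Roulette-wheel probabilities over a selection pool.

    Fitness is payoff minus the pool minimum; all-zero fitness (all payoffs
    equal) degenerates to a uniform draw.
    """
    pool_payoffs = np.asarray(pool_payoffs, dtype=float)
    fit = pool_payoffs - pool_payoffs.min()
    tot = fit.sum()
    if tot <= 0.0:
        return np.full(pool_payoffs.size, 1.0 / pool_payoffs.size)
    return fit / tot


def evolve_generation(
    net: InteractionNetwork,
    pop: Population,
    payoffs: np.ndarray,
    config: GameConfig,
    rng: np.random.Generator,
) -> Population:
    """Synchronous roulette-wheel selection plus per-bit mutation.

    Every agent draws a parent from its pool (neighbourhood plus itself by
    default) with probability proportional to payoff minus the pool minimum,
    copies the parent's boldness and vengefulness bit-strings as a pair, and
    then each of the six copied bits flips independently with the mutation
    rate.  All draws use the old generation's strategies and payoffs.
    """
    n = net.n
    pool_idx, pool_mask = net.selection_pools(config.include_self)
    pool_pay = payoffs[pool_idx]
    fmin = np.where(pool_mask, pool_pay, np.inf).min(axis=1)
    fit = (pool_pay - fmin[:, None]) * pool_mask
    tot = fit.sum(axis=1)
    # degenerate pools (all payoffs equal) fall back to a uniform draw
    weights = np.where(tot[:, None] > 0.0, fit, pool_mask.astype(float))
    cum = np.cumsum(weights, axis=1)
    u = rng.random(n) * cum[:, -1]
    col = (cum < u[:, None]).sum(axis=1)
    parent = pool_idx[np.arange(n), col]

    new_b = pop.b_levels[parent]
    new_v = pop.v_levels[parent]

    mu = config.mutation_rate
    bit_weights = np.array([4, 2, 1])
    flip_b = ((rng.random((n, 3)) < mu) * bit_weights).sum(axis=1)
    flip_v = ((rng.random((n, 3)) < mu) * bit_weights).sum(axis=1)
    if not config.mutate_on_self_copy:
        self_copy = parent == np.arange(n)
        flip_b = np.where(self_copy, 0, flip_b)
        flip_v = np.where(self_copy, 0, flip_v)
    return Population(new_b ^ flip_b, new_v ^ flip_v)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def _as_rng(rng, config: GameConfig) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = config.seed
    return np.random.default_rng(rng)


def run_simulation(
    net: InteractionNetwork,
    config: GameConfig,
    rng=None,
    snapshot_every: int | None = None,
) -> Trajectory:
    """Run the full evolutionary simulation and record population means.

    Strategies are initialised uniformly at random over the 64 joint values.
    Each generation resets payoffs to zero, plays
    ``config.rounds_per_generation`` rounds with fresh observability draws,
    and applies the synchronous selection-and-mutation update.  The run is
    bit-reproducible given (net, config, seed).
    """
    rng = _as_rng(rng, config)
    n = net.n
    g_total = config.generations
    pop = Population.random(n, rng)
    mb = np.empty(g_total + 1)
    mv = np.empty(g_total + 1)
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def record(g: int, pop: Population):
        mb[g] = pop.b_levels.mean() / _MAX
        mv[g] = pop.v_levels.mean() / _MAX
        if snapshot_every and g % snapshot_every == 0:
            snapshots[g] = (pop.b_levels.copy(), pop.v_levels.copy())

    record(0, pop)
    for g in range(1, g_total + 1):
        payoffs = np.zeros(n)
        for _ in range(config.rounds_per_generation):
            payoffs += play_round(net, pop, config, rng)
        pop = evolve_generation(net, pop, payoffs, config, rng)
        record(g, pop)
    return Trajectory(mb, mv, snapshots, config)


def mc_mean_payoff(
    net: InteractionNetwork,
    pop: Population,
    config: GameConfig,
    rounds: int,
    rng=None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the population-mean one-round payoff.

    Plays ``rounds`` independent rounds with frozen strategies and returns
    (mean, standard error) of the per-round population-average payoff.
    Used to validate the closed-form expected payoffs.
    """
    rng = _as_rng(rng, config)
    vals = np.empty(rounds)
    for r in range(rounds):
        vals[r] = play_round(net, pop, config, rng).mean()
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(rounds))
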