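"""Long-run occupancy experiments and empirical drift maps.

For positive mutation rates the simulated game is an ergodic finite Markov
chain, so the long-run fraction of time it spends in a region of the
(mean boldness, mean vengefulness) square approximates its occupancy
distribution.  Two regions are tracked:

* norm collapse:      mean boldness ≥ 6/7 and mean vengefulness ≤ 1/7;
* norm establishment: mean boldness ≤ 1/7 and mean vengefulness ≥ 6/7.

This module classifies trajectories into those zones, sweeps network
ensembles to relate occupancy to topology statistics (average degree,
interconnectedness, clustering), and measures empirical drift fields for
comparison with the analytic gradient maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import GradientField
from .engine import (
    _MAX,
    GameConfig,
    Population,
    Trajectory,
    evolve_generation,
    play_round,
)
from .network import InteractionNetwork, network_stats, sample_networks

__all__ = [
    "ZoneSpec",
    "OccupancyResult",
    "classify_state",
    "occupancy",
    "sweep",
    "bin_occupancy",
    "topology_trends",
    "empirical_drift_map",
    "default_ensemble_specs",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Thresholds of the collapse and establishment zones (inclusive)."""

    collapse_b_min: float = 6.0 / 7.0
    collapse_v_max: float = 1.0 / 7.0
    establish_b_max: float = 1.0 / 7.0
    establish_v_min: float = 6.0 / 7.0

    def classify(self, mean_b: float, mean_v: float) -> str:
        if mean_b >= self.collapse_b_min and mean_v <= self.collapse_v_max:
            return "collapse"
        if mean_b <= self.establish_b_max and mean_v >= self.establish_v_min:
            return "establishment"
        return "neither"


def classify_state(
    mean_b: float, mean_v: float, zones: ZoneSpec | None = None
) -> str:
    """Classify a population state into collapse / establishment / neither.

    Threshold comparisons are inclusive, so (6/7, 1/7) is in the collapse
    zone and (1/7, 6/7) in the establishment zone.
    """
    return (zones or ZoneSpec()).classify(mean_b, mean_v)


@dataclass
class OccupancyResult:
    """Zone occupancy fractions of one trajectory (they sum to 1)."""

    collapse: float
    establishment: float
    neither: float
    n_generations: int
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "collapse": self.collapse,
            "establishment": self.establishment,
            "neither": self.neither,
            "n_generations": self.n_generations,
            **self.metadata,
        }


def occupancy(
    traj: Trajectory, zones: ZoneSpec | None = None, burn_in: int = 0
) -> OccupancyResult:
    """Fraction of recorded generations spent in each zone.

    No burn-in is discarded by default; ``burn_in`` drops the first entries
    (including the initial state) when requested.
    """
    zones = zones or ZoneSpec()
    mb = traj.mean_boldness[burn_in:]
    mv = traj.mean_vengefulness[burn_in:]
    if mb.size == 0:
        raise ValueError("empty trajectory (burn-in exceeds its length?)")
    in_collapse = (mb >= zones.collapse_b_min) & (mv <= zones.collapse_v_max)
    in_establish = (mb <= zones.establish_b_max) & (mv >= zones.establish_v_min)
    c = float(in_collapse.mean())
    e = float(in_establish.mean())
    return OccupancyResult(c, e, 1.0 - c - e, int(mb.size))


# ---------------------------------------------------------------------------
# Ensemble sweeps
# ---------------------------------------------------------------------------


def default_ensemble_specs(n: int = 50) -> list[dict]:
    """Parameter grid mirroring the sampled-topology design: ring-rewiring
    networks across the clustering range, preferential-attachment and random
    networks, each at radius 1 and radius 2."""
    specs: list[dict] = []
    for radius in (1, 2):
        for k in (2, 4, 6, 8):
            for beta in (0.0, 0.1, 0.3, 1.0):
                specs.append(
                    {"model": "watts", "n": n, "k": k, "beta": beta, "radius": radius}
                )
        for m in (1, 2, 3):
            specs.append({"model": "ba", "n": n, "m": m, "radius": radius})
        for kavg in (2, 4, 6):
            specs.append(
                {"model": "er", "n": n, "p": kavg / (n - 1), "radius": radius}
            )
    return specs


def sweep(
    networks,
    config: GameConfig,
    seeds_per_net: int = 3,
    zones: ZoneSpec | None = None,
    base_seed: int | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the simulation on every network with several seeds and tabulate
    zone occupancy against topology statistics.

    ``networks`` is an iterable of :class:`InteractionNetwork` or of
    ``(metadata_dict, network)`` pairs as produced by
    :func:`metanorms.network.sample_networks`.  Run seeds are spawned
    deterministically from ``base_seed`` so the sweep is reproducible
    regardless of execution order.  Returns one row per (network, seed).
    """
    from .engine import run_simulation

    zones = zones or ZoneSpec()
    networks = list(networks)
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(networks) * seeds_per_net)
    rows = []
    pos = 0
    iterator = enumerate(networks)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(list(iterator))  # pragma: no cover
    for net_id, item in iterator:
        meta, net = item if isinstance(item, tuple) else ({}, item)
        stats = network_stats(net)
        for _ in range(seeds_per_net):
            run_seed = int(children[pos].generate_state(1)[0] % (2**31))
            pos += 1
            traj = run_simulation(net, config, rng=np.random.default_rng(run_seed))
            occ = occupancy(traj, zones)
            rows.append(
                {
                    "net_id": net_id,
                    "run_seed": run_seed,
                    "n": stats.n,
                    "avg_degree": stats.avg_degree,
                    "interconnectedness": stats.interconnectedness,
                    "sqrt_interconnectedness": float(
                        np.sqrt(stats.interconnectedness)
                    ),
                    "mean_clustering": stats.mean_clustering,
                    "collapse": occ.collapse,
                    "establishment": occ.establishment,
                    "neither": occ.neither,
                    **{f"net_{k}": v for k, v in meta.items()},
                }
            )
    return pd.DataFrame(rows)


def bin_occupancy(
    df: pd.DataFrame,
    x: str = "avg_degree",
    y: str = "sqrt_interconnectedness",
    bins: int | tuple = 6,
) -> pd.DataFrame:
    """2-D histogram aggregation of sweep rows: mean zone occupancy per
    (x, y) bin, weighted by run counts (each row is one run)."""
    if isinstance(bins, int):
        bins = (bins, bins)
    xb = pd.cut(df[x], bins[0])
    yb = pd.cut(df[y], bins[1])
    grouped = df.groupby([xb, yb], observed=True)
    out = grouped.agg(
        collapse=("collapse", "mean"),
        establishment=("establishment", "mean"),
        neither=("neither", "mean"),
        runs=("collapse", "size"),
    ).reset_index()
    out[x + "_mid"] = out[x].map(lambda iv: iv.mid).astype(float)
    out[y + "_mid"] = out[y].map(lambda iv: iv.mid).astype(float)
    return out


def topology_trends(
    df: pd.DataFrame,
    zone: str = "establishment",
    bins: int = 5,
) -> dict:
    """Binned rank correlations of zone occupancy with topology statistics.

    Mirrors the heat-map reading of the occupancy results: sweep rows are
    binned into ``bins`` quantile classes of average degree, and within each
    class the Spearman correlation of occupancy with interconnectedness is
    computed (and symmetrically: interconnectedness classes, correlation
    with average degree).  Bins with fewer than 6 runs, constant occupancy
    or a constant predictor are skipped.  Returns run-weighted mean
    correlations ``rho_lambda_within_k`` (expected > 0 for the
    establishment zone) and ``rho_k_within_lambda`` (expected < 0), plus
    the per-bin detail.
    """
    from scipy import stats as sps

    def binned_rho(bin_col: str, pred_col: str) -> tuple[float, list]:
        classes = pd.qcut(df[bin_col], bins, duplicates="drop")
        detail = []
        num = den = 0.0
        for cls, sub in df.groupby(classes, observed=True):
            if (
                len(sub) < 6
                or sub[pred_col].nunique() < 3
                or sub[zone].nunique() < 2
            ):
                continue
            rho = sps.spearmanr(sub[pred_col], sub[zone]).statistic
            detail.append({"bin": str(cls), "n": len(sub), "rho": float(rho)})
            num += rho * len(sub)
            den += len(sub)
        return (num / den if den else float("nan")), detail

    def partial_rho(pred_col: str, control_col: str) -> float:
        # Spearman partial correlation: Pearson on rank residuals after
        # regressing out the control.  Quantile bins cannot hold the
        # control fixed where it spans decades, so this is the cleaner
        # "at fixed ..." statistic; the binned detail mirrors the heat-map
        # reading.
        ranks = df[[zone, pred_col, control_col]].rank()
        z = np.c_[np.ones(len(df)), ranks[control_col].to_numpy()]
        ry = ranks[zone].to_numpy()
        rx = ranks[pred_col].to_numpy()
        ry = ry - z @ np.linalg.lstsq(z, ry, rcond=None)[0]
        rx = rx - z @ np.linalg.lstsq(z, rx, rcond=None)[0]
        denom = np.linalg.norm(ry) * np.linalg.norm(rx)
        return float(ry @ rx / denom) if denom > 0 else float("nan")

    rho_lk, detail_lk = binned_rho("avg_degree", "interconnectedness")
    rho_kl, detail_kl = binned_rho("interconnectedness", "avg_degree")
    return {
        "rho_lambda_within_k": rho_lk,
        "rho_k_within_lambda": rho_kl,
        "partial_rho_lambda_given_k": partial_rho("interconnectedness", "avg_degree"),
        "partial_rho_k_given_lambda": partial_rho("avg_degree", "interconnectedness"),
        "detail_lambda_within_k": detail_lk,
        "detail_k_within_lambda": detail_kl,
    }


# ---------------------------------------------------------------------------
# Empirical drift maps
# ---------------------------------------------------------------------------


def empirical_drift_map(
    net: InteractionNetwork,
    config: GameConfig,
    grid: int = 8,
    reps_per_cell: int = 200,
    horizon: int = 1,
    rng=None,
) -> GradientField:
    """Measure the simulated population drift from homogeneous starts.

    For every grid point (b, v) the population is initialised homogeneously
    at the nearest 8-level strategy, run for ``horizon`` generations, and
    the per-generation displacement of the population means is averaged
    over ``reps_per_cell`` replicates.  The result is directly comparable
    to the analytic :func:`metanorms.analytic.gradient_map`.
    """
    if grid < 2:
        raise ValueError("grid resolution must be >= 2 per axis")
    if reps_per_cell < 1 or horizon < 1:
        raise ValueError("reps_per_cell and horizon must be >= 1")
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    bs = np.linspace(0.0, 1.0, grid)
    vs = np.linspace(0.0, 1.0, grid)
    bb, vv = np.meshgrid(bs, vs, indexing="ij")
    db = np.zeros_like(bb)
    dv = np.zeros_like(bb)
    n = net.n
    for i in range(grid):
        for j in range(grid):
            b_lv = int(round(bb[i, j] * _MAX))
            v_lv = int(round(vv[i, j] * _MAX))
            disp_b = 0.0
            disp_v = 0.0
            for _ in range(reps_per_cell):
                pop = Population.homogeneous(n, b_lv, v_lv)
                b0, v0 = pop.b_levels.mean() / _MAX, pop.v_levels.mean() / _MAX
                for _g in range(horizon):
                    pay = np.zeros(n)
                    for _r in range(config.rounds_per_generation):
                        pay += play_round(net, pop, config, rng)
                    pop = evolve_generation(net, pop, pay, config, rng)
                disp_b += (pop.b_levels.mean() / _MAX - b0) / horizon
                disp_v += (pop.v_levels.mean() / _MAX - v0) / horizon
            db[i, j] = disp_b / reps_per_cell
            dv[i, j] = disp_v / reps_per_cell
    return GradientField(bb, vv, db, dv, stats=None, config=config, kind="empirical")
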