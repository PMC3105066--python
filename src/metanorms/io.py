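"""File formats and reproducibility plumbing.

Networks are exchanged as whitespace edge lists (``i j`` per line, ``#``
comments, 0-based by default) or GraphML; results as CSV or JSON; configs
as YAML or JSON.  A :class:`RunManifest` written beside every CLI output
records the fully resolved configuration and seeds so any result can be
regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import InteractionNetwork

__all__ = [
    "read_network",
    "write_network",
    "write_results",
    "read_config_file",
    "RunManifest",
    "spawn_seeds",
]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    return "graphml" if path.suffix.lower() == ".graphml" else "edgelist"


def read_network(
    path, format: str | None = None, one_based: bool = False
) -> InteractionNetwork:
    """Read an undirected network from an edge-list or GraphML file.

    Duplicate edges are collapsed with a warning; self-loops are rejected.
    Edge-list node labels must be integers, 0-based unless ``one_based``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"{path}: self-loop on node {loops[0][0]}")
        try:
            g = nx.relabel_nodes(g, {u: int(u) for u in g.nodes()})
        except (TypeError, ValueError):
            pass  # non-numeric labels: keep sorted-label order
        return InteractionNetwork.from_networkx(g)
    if fmt != "edgelist":
        raise ValueError(f"unknown network format {format!r}")

    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two node labels, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer node label in {line!r}"
                ) from exc
            if one_based:
                u, v = u - 1, v - 1
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on node {parts[0]}")
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative node index")
            key = (min(u, v), max(u, v))
            if key in seen:
                dupes += 1
                continue
            seen.add(key)
            edges.append(key)
    if dupes:
        warnings.warn(f"{path}: collapsed {dupes} duplicate edge(s)")
    n = max((max(e) for e in edges), default=-1) + 1
    return InteractionNetwork(max(n, 1), edges)


def write_network(net: InteractionNetwork, path, format: str | None = None) -> None:
    """Write a network as an edge list or GraphML; round-trips exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write(f"# n={net.n}\n")
            for u, v in sorted(net.edges):
                fh.write(f"{u} {v}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def write_results(rows, path, format: str | None = None, precision: int = 10) -> None:
    """Write tabular results (DataFrame or list of dicts) as CSV or JSON
    with deterministic column order and fixed float precision."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        raise ValueError("refusing to write empty results")
    if fmt == "csv":
        df.to_csv(path, index=False, float_format=f"%.{precision}g")
    elif fmt == "json":
        records = json.loads(
            df.to_json(orient="records", double_precision=min(precision, 15))
        )
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_config_file(path) -> dict:
    """Read a YAML or JSON config mapping."""
    path = Path(path)
    with open(path) as fh:
        data = (
            json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        )
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a CLI invocation bit-identically."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str]
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc
            ).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def spawn_seeds(master_seed: int | None, k: int) -> list[int]:
    """Derive ``k`` independent child seeds from a master seed; the same
    master always yields the same children, independent of use order."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(k)]
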