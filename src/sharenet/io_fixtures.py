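"""File formats, worked-example fixtures, random networks, and sweeps.

Two network dialects are supported: a TSV edge list (``source<TAB>target``,
0-based integer ids) with a sidecar ``<stem>.hunters`` file listing hunter
ids one per line, and GraphML with a boolean ``hunter`` node attribute.
Optimization output is JSON-lines (one record per optimum) plus a CSV feature
table consumed by downstream clustering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .criteria import cost_vector
from .net_features import FEATURE_COLUMNS, feature_vector
from .optimizer import EvolutionConfig, evolve_multi, evolve_single
from .sharing_model import (
    InvalidModelError,
    ModelParams,
    SharingNetwork,
    validate_network,
)

__all__ = [
    "read_network",
    "write_network",
    "fixture_fig1",
    "fixture_star_d1",
    "random_network",
    "SweepConfig",
    "run_sweep",
]

logger = logging.getLogger("sharenet")


class NetworkParseError(ValueError):
    """A network file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


# ---------------------------------------------------------------- file I/O

def _hunters_sidecar(path: Path) -> Path:
    return path.with_suffix(".hunters")


def read_network(path, fmt: str | None = None) -> SharingNetwork:
    """Read a sharing network from an edge-list TSV or a GraphML file.

    Node ids are normalized to ``0..N-1`` preserving first-appearance order
    (edge list) or GraphML node order.
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "edgelist"
    if fmt == "graphml":
        g = nx.read_graphml(path)
        if not isinstance(g, nx.DiGraph):
            g = g.to_directed()
        relabel = {v: i for i, v in enumerate(g.nodes)}
        hunters = set()
        for v, data in g.nodes(data=True):
            flag = data.get("hunter")
            if isinstance(flag, str):
                flag = flag.strip().lower() == "true"
            if flag:
                hunters.add(relabel[v])
        if not hunters:
            raise InvalidModelError(f"{path}: no node carries hunter='true'")
        arcs = {(relabel[u], relabel[v]) for u, v in g.edges}
        net = SharingNetwork(g.number_of_nodes(), frozenset(arcs), frozenset(hunters))
        return validate_network(net)
    if fmt != "edgelist":
        raise ValueError(f"unknown format {fmt!r}")
    arcs = []
    order: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().replace(" ", "").startswith("source"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NetworkParseError("expected two tab-separated columns", lineno)
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise NetworkParseError(str(exc), lineno) from None
            if u == v:
                raise NetworkParseError(f"self-loop at node {u}", lineno)
            for w in (u, v):
                order.setdefault(w, len(order))
            arcs.append((u, v))
    sidecar = _hunters_sidecar(path)
    if not sidecar.exists():
        raise InvalidModelError(f"missing hunter sidecar file {sidecar}")
    hunters = set()
    with open(sidecar) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                hunters.add(int(line))
            except ValueError as exc:
                raise NetworkParseError(str(exc), lineno) from None
    for h in hunters:
        order.setdefault(h, len(order))
    # normalize to 0..N-1 in ascending numeric id order, so files that
    # already use 0-based contiguous ids round-trip unchanged
    relabel = {v: i for i, v in enumerate(sorted(order))}
    net = SharingNetwork(
        len(relabel),
        frozenset((relabel[u], relabel[v]) for u, v in arcs),
        frozenset(relabel[h] for h in hunters),
    )
    return validate_network(net)


def write_network(net: SharingNetwork, path, fmt: str | None = None) -> None:
    """Write a network in the dialect matching ``fmt`` (or the file suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "edgelist"
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(net.arcs):
            fh.write(f"{u}\t{v}\n")
    with open(_hunters_sidecar(path), "w") as fh:
        for h in sorted(net.hunters):
            fh.write(f"{h}\n")


# ---------------------------------------------------------------- fixtures

def fixture_fig1() -> SharingNetwork:
    """The 7-node, 2-hunter worked example (hunters 0 and 4).

    The arc list is reconstructed from the walk structure of the worked
    eating-probability table and reproduces all of its entries exactly.
    """
    arcs = {(0, 1), (0, 3), (1, 2), (2, 3), (3, 1), (4, 5), (5, 6), (6, 1)}
    return SharingNetwork(7, frozenset(arcs), frozenset({0, 4}))


def fixture_star_d1() -> SharingNetwork:
    """Out-star: one hunter (node 0) feeding four consumers.

    At ph=0.08, F=4 each consumer eats with probability 0.02 and the cost
    pair is (RV, WEF) = (0.261, 0.024) at n=1000, k=10.
    """
    arcs = {(0, v) for v in range(1, 5)}
    return SharingNetwork(5, frozenset(arcs), frozenset({0}))


def random_network(N: int, arc_prob: float, nh: int, seed: int) -> SharingNetwork:
    """Uniform random digraph: each ordered pair independently an arc with
    probability ``arc_prob``; hunters are the first ``nh`` nodes of a seeded
    shuffle."""
    if not 0.0 <= arc_prob <= 1.0:
        raise ValueError(f"arc_prob must be in [0, 1], got {arc_prob}")
    if not 1 <= nh <= N:
        raise ValueError(f"need 1 <= nh <= N, got nh={nh}, N={N}")
    rng = np.random.default_rng(seed)
    pairs = [(u, v) for u in range(N) for v in range(N) if u != v]
    mask = rng.random(len(pairs)) < arc_prob
    arcs = frozenset(p for p, m in zip(pairs, mask) if m)
    order = rng.permutation(N)
    hunters = frozenset(int(v) for v in order[:nh])
    return SharingNetwork(N, arcs, hunters)


# ---------------------------------------------------------------- sweeps

@dataclass(frozen=True)
class SweepConfig:
    """Grid of model conditions for batch optimization runs."""

    N: int = 12
    ph_values: tuple[float, ...] = (0.02, 0.08, 0.15, 0.3, 0.6)
    F_values: tuple[int, ...] = (2, 3, 4, 5, 6)
    nh_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n: int = 1000
    k: int = 10
    criteria: tuple[str, ...] = ("rv", "wef", "pareto")
    seeds: tuple[int, ...] = (0,)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    out_dir: str = "sweep_out"

    def cells(self) -> list[dict]:
        cells = []
        for ph in self.ph_values:
            for F in self.F_values:
                for nh in self.nh_values:
                    cells.append(
                        {
                            "ph": ph,
                            "F": F,
                            "nh": nh,
                            "supply_regime": "low" if F * nh <= self.N else "high",
                        }
                    )
        return cells


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run single- and multi-objective optimization over the parameter grid.

    Writes one JSON-lines record per deduplicated optimum to
    ``<out_dir>/optima.jsonl`` and the aggregate feature table to
    ``<out_dir>/features.csv``; returns the feature table.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jsonl_path = out_dir / "optima.jsonl"
    records = []
    with open(jsonl_path, "w") as fh:
        for cell in config.cells():
            params = ModelParams(ph=cell["ph"], F=cell["F"], n=config.n, k=config.k)
            for seed in config.seeds:
                evo = EvolutionConfig(
                    mu=config.evolution.mu,
                    lambda_ratio=config.evolution.lambda_ratio,
                    tournament_size=config.evolution.tournament_size,
                    generations=config.evolution.generations,
                    seed=seed,
                    N=config.N,
                    nh=cell["nh"],
                    init_density_range=config.evolution.init_density_range,
                )
                found: list[tuple[str, object]] = []
                for criterion in config.criteria:
                    if criterion == "pareto":
                        individuals, _ = evolve_multi(params, evo)
                        found.extend(("pf", ind) for ind in individuals)
                    else:
                        found.extend(
                            (criterion, ind)
                            for ind in evolve_single(params, evo, criterion)
                        )
                logger.info(
                    "cell ph=%s F=%s nh=%s seed=%s: %d optima",
                    cell["ph"], cell["F"], cell["nh"], seed, len(found),
                )
                for kind, ind in found:
                    record = {
                        "arcs": sorted(ind.network.arcs),
                        "hunters": sorted(ind.network.hunters),
                        "N": ind.network.n_nodes,
                        "params": {"ph": params.ph, "F": params.F, "n": params.n, "k": params.k},
                        "optimum_type": kind,
                        "costs": {"rv": ind.costs.rv, "wef": ind.costs.wef},
                        "seed": seed,
                        "supply_regime": cell["supply_regime"],
                    }
                    fh.write(json.dumps(record) + "\n")
                    fv = feature_vector(ind.network, params, seed=seed).as_dict()
                    fv.update(
                        optimum_type=kind, ph=params.ph, F=params.F,
                        nh=cell["nh"], seed=seed, supply_regime=cell["supply_regime"],
                    )
                    records.append(fv)
    table = pd.DataFrame(records, columns=list(FEATURE_COLUMNS) + [
        "optimum_type", "ph", "F", "nh", "seed", "supply_regime",
    ])
    table.to_csv(out_dir / "features.csv", index=False)
    return table


def profile_to_json(net: SharingNetwork, params: ModelParams) -> dict:
    """JSON-ready eating profile + cost pair with a parameter echo."""
    from .sharing_model import eating_probabilities

    profile = eating_probabilities(net, params)
    costs = cost_vector(net, params)
    return {
        "params": {"ph": params.ph, "F": params.F, "n": params.n, "k": params.k},
        "pe": {str(v): float(profile.pe[v]) for v in net.nodes},
        "costs": {"rv": costs.rv, "wef": costs.wef},
    }
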