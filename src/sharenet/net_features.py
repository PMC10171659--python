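"""Descriptive features used to characterize optimal sharing networks.

Degree statistics, strongly connected components, local clustering on the
undirected simple projection, pair reciprocity, degree assortativity over
arcs, directed modularity with a stochastic partition search, the average
intra-partition clustering (AIC) cohesion measure, hunter/non-hunter arc-type
counts, and eating-probability summaries.  Metrics that are undefined on a
given network (assortativity with zero degree variance, reciprocity with no
arcs) are reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .criteria import rv_cost, wef_cost
from .sharing_model import ModelParams, SharingNetwork, eating_probabilities

__all__ = [
    "PartitionResult",
    "FeatureVector",
    "reciprocity",
    "arc_type_counts",
    "modularity_of_partition",
    "modularity_search",
    "average_intra_partition_clustering",
    "feature_vector",
    "FEATURE_COLUMNS",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class PartitionResult:
    blocks: tuple[frozenset[int], ...]
    modularity: float
    restarts_used: int
    seed: int


@dataclass(frozen=True)
class FeatureVector:
    std_out_degree: float
    std_in_degree: float
    mean_out_degree: float
    mean_in_degree_hunters: float
    scc_count: int
    mean_local_clustering: float
    reciprocity: float
    in_assortativity: float
    out_assortativity: float
    modularity: float
    avg_intra_partition_clustering: float
    intra_h_arcs: int
    intra_nonh_arcs: int
    inter_h_nonh_arcs: int
    mean_pe: float
    median_pe: float
    hunter_nonhunter_pe_gap: float
    rv_cost: float
    wef_cost: float

    def as_dict(self) -> dict:
        return asdict(self)


FEATURE_COLUMNS = tuple(FeatureVector.__dataclass_fields__)


def reciprocity(net: SharingNetwork) -> float:
    """Fraction of connected unordered node pairs linked in both directions.

    NaN when the network has no arcs.
    """
    pairs = {frozenset(a) for a in net.arcs}
    if not pairs:
        return UNDEFINED
    both = sum(1 for p in pairs if all(a in net.arcs for a in _orient(p)))
    return both / len(pairs)


def _orient(pair: frozenset) -> tuple[tuple[int, int], tuple[int, int]]:
    u, v = sorted(pair)
    return (u, v), (v, u)


def arc_type_counts(net: SharingNetwork) -> tuple[int, int, int]:
    """(intra_h, intra_nonh, inter_h_nonh) directed-arc counts, classified by
    endpoint hunter status ignoring direction."""
    intra_h = intra_nonh = inter = 0
    for u, v in net.arcs:
        hu, hv = u in net.hunters, v in net.hunters
        if hu and hv:
            intra_h += 1
        elif not hu and not hv:
            intra_nonh += 1
        else:
            inter += 1
    return intra_h, intra_nonh, inter


def _degree_arrays(net: SharingNetwork) -> tuple[np.ndarray, np.ndarray]:
    kout = np.zeros(net.n_nodes)
    kin = np.zeros(net.n_nodes)
    for u, v in net.arcs:
        kout[u] += 1
        kin[v] += 1
    return kout, kin


def modularity_of_partition(net: SharingNetwork, blocks) -> float:
    """Directed (Newman-Leicht) modularity of a given partition:
    ``Q = sum_{(u,v) in E, same block} [1/m - kout(u) kin(v) / m^2]``
    minus the expected within-block weight for absent arcs — computed exactly
    from the standard formula ``Q = (1/m) sum_uv (A_uv - kout_u kin_v / m)
    delta(c_u, c_v)``.
    """
    blocks = [frozenset(b) for b in blocks]
    covered = [v for b in blocks for v in b]
    if sorted(covered) != list(net.nodes):
        raise ValueError("blocks must partition the node set")
    m = len(net.arcs)
    if m == 0:
        raise ValueError("modularity needs at least one arc")
    label = {}
    for i, b in enumerate(blocks):
        for v in b:
            label[v] = i
    kout, kin = _degree_arrays(net)
    within = sum(1 for u, v in net.arcs if label[u] == label[v]) / m
    expected = sum(
        float(kout[list(b)].sum() * kin[list(b)].sum()) for b in blocks
    ) / (m * m)
    return within - expected


def _partition_quality_search(
    net: SharingNetwork, restarts: int, seed: int
) -> PartitionResult:
    """Greedy agglomeration plus single-node-move refinement from random
    starts; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    m = len(net.arcs)
    kout, kin = _degree_arrays(net)
    arcs = list(net.arcs)

    def q_of_labels(label: np.ndarray) -> float:
        within = sum(1 for u, v in arcs if label[u] == label[v]) / m
        expected = 0.0
        for b in np.unique(label):
            mask = label == b
            expected += float(kout[mask].sum() * kin[mask].sum())
        return within - expected / (m * m)

    best_label = np.arange(n)
    best_q = q_of_labels(best_label)
    for _ in range(restarts):
        nblocks = int(rng.integers(1, n + 1))
        label = rng.integers(0, nblocks, size=n)
        q = q_of_labels(label)
        improved = True
        while improved:
            improved = False
            for v in range(n):
                current = label[v]
                candidates = set(label) | {int(label.max()) + 1}
                for c in sorted(candidates):
                    if c == current:
                        continue
                    label[v] = c
                    q_new = q_of_labels(label)
                    if q_new > q + 1e-12:
                        q = q_new
                        current = c
                        improved = True
                    else:
                        label[v] = current
        if q > best_q + 1e-12:
            best_q, best_label = q, label.copy()
    blocks = tuple(
        frozenset(np.flatnonzero(best_label == b).tolist())
        for b in np.unique(best_label)
    )
    return PartitionResult(blocks, best_q, restarts, seed)


def modularity_search(net: SharingNetwork, restarts: int = 20, seed: int = 0) -> PartitionResult:
    """Best partition by seeded stochastic maximization of directed modularity.

    Returns an all-NaN singleton result on arcless networks, where modularity
    is undefined.
    """
    if not net.arcs:
        blocks = tuple(frozenset([v]) for v in net.nodes)
        return PartitionResult(blocks, UNDEFINED, 0, seed)
    return _partition_quality_search(net, restarts, seed)


def _undirected_projection(net: SharingNetwork):
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from({tuple(sorted(a)) for a in net.arcs})
    return g


def average_intra_partition_clustering(net: SharingNetwork, blocks) -> float:
    """Mean over blocks of the mean local clustering of each block's induced
    subnetwork (undirected projection; degree < 2 nodes contribute 0)."""
    blocks = [frozenset(b) for b in blocks]
    covered = [v for b in blocks for v in b]
    if sorted(covered) != list(net.nodes):
        raise ValueError("blocks must partition the node set")
    g = _undirected_projection(net)
    block_means = []
    for b in blocks:
        sub = g.subgraph(b)
        if len(b) == 0:
            continue
        cl = nx.clustering(sub)
        block_means.append(sum(cl.values()) / len(b))
    return float(np.mean(block_means)) if block_means else 0.0


def _arc_assortativity(net: SharingNetwork, degrees: np.ndarray) -> float:
    """Pearson correlation of (source, target) degrees over arcs; NaN if
    either endpoint series has zero variance."""
    if not net.arcs:
        return UNDEFINED
    src = np.array([degrees[u] for u, _ in sorted(net.arcs)], dtype=float)
    dst = np.array([degrees[v] for _, v in sorted(net.arcs)], dtype=float)
    if src.std() == 0 or dst.std() == 0:
        return UNDEFINED
    return float(np.corrcoef(src, dst)[0, 1])


def feature_vector(
    net: SharingNetwork,
    params: ModelParams,
    modularity_restarts: int = 20,
    seed: int = 0,
) -> FeatureVector:
    """The full descriptive battery for one network under one parameter set."""
    kout, kin = _degree_arrays(net)
    hunters = sorted(net.hunters)
    non_hunters = [v for v in net.nodes if v not in net.hunters]
    g_dir = net.to_networkx()
    g_und = _undirected_projection(net)
    clustering = nx.clustering(g_und)
    part = modularity_search(net, restarts=modularity_restarts, seed=seed)
    aic = (
        average_intra_partition_clustering(net, part.blocks)
        if not math.isnan(part.modularity)
        else 0.0
    )
    profile = eating_probabilities(net, params)
    pe = profile.pe
    mean_h = float(np.mean(pe[hunters]))
    mean_nh = float(np.mean(pe[non_hunters])) if non_hunters else UNDEFINED
    intra_h, intra_nonh, inter = arc_type_counts(net)
    return FeatureVector(
        std_out_degree=float(kout.std()),
        std_in_degree=float(kin.std()),
        mean_out_degree=float(kout.mean()),
        mean_in_degree_hunters=float(kin[hunters].mean()),
        scc_count=nx.number_strongly_connected_components(g_dir),
        mean_local_clustering=float(np.mean(list(clustering.values()))),
        reciprocity=reciprocity(net),
        in_assortativity=_arc_assortativity(net, kin),
        out_assortativity=_arc_assortativity(net, kout),
        modularity=part.modularity,
        avg_intra_partition_clustering=aic,
        intra_h_arcs=intra_h,
        intra_nonh_arcs=intra_nonh,
        inter_h_nonh_arcs=inter,
        mean_pe=float(pe.mean()),
        median_pe=float(np.median(pe)),
        hunter_nonhunter_pe_gap=mean_h - mean_nh if non_hunters else UNDEFINED,
        rv_cost=rv_cost(profile, params.n, params.k),
        wef_cost=wef_cost(profile),
    )
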