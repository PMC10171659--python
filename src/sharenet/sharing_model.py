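"""Hunter/consumer sharing networks and per-step probabilities of eating.

The model: agents sit on a loop-free simple directed network ``D = (V, E)``.
A subset ``H`` of *hunters* each hunts independently with probability ``ph``
per time step.  A successful hunt yields a package of ``F`` food units; the
hunter eats one unit and passes the remaining ``F - 1`` to a uniformly random
out-neighbor, and every subsequent receiver does the same, so one package
traces a random walk of exactly ``F - 1`` transfers (fewer if it reaches a
node with no out-neighbors).  A node *eats* in a time step if at least one
package visits it; revisits by the same package feed a node only once.

The central quantity is the per-node probability of eating ``pe(v)`` in a
single time step, obtained exactly from first-visit probabilities of the
package walk and inclusion-exclusion over the independent hunters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "SharingNetwork",
    "VisitProbabilities",
    "EatingProfile",
    "InvalidStructureError",
    "InvalidModelError",
    "validate_network",
    "visit_probabilities",
    "eating_probabilities",
    "simulate_events",
]


class InvalidStructureError(ValueError):
    """The directed graph violates a structural invariant (e.g. a self-loop)."""


class InvalidModelError(ValueError):
    """Model-level data is inconsistent (e.g. empty or out-of-range hunter set)."""


@dataclass(frozen=True)
class ModelParams:
    """Environment and survival-window parameters.

    Parameters
    ----------
    ph : float
        Probability that a hunter hunts in one time step, in [0, 1].
    F : int
        Units of food per prey; the number of agents one hunt can feed,
        including the hunter itself.  ``F >= 1``.
    n : int
        Life span in time steps (default 1000).
    k : int
        Critical window: ``k`` consecutive steps without food are lethal.
        ``1 <= k < n`` (default 10).
    """

    ph: float
    F: int
    n: int = 1000
    k: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 1.0:
            raise InvalidModelError(f"ph must be in [0, 1], got {self.ph}")
        if self.F < 1 or int(self.F) != self.F:
            raise InvalidModelError(f"F must be an integer >= 1, got {self.F}")
        if self.n < 2:
            raise InvalidModelError(f"n must be >= 2, got {self.n}")
        if not 1 <= self.k < self.n:
            raise InvalidModelError(f"k must satisfy 1 <= k < n, got k={self.k}, n={self.n}")


@dataclass(frozen=True)
class SharingNetwork:
    """A loop-free simple digraph with a designated nonempty hunter subset.

    Nodes are the integers ``0 .. n_nodes - 1``.  Isolated nodes are allowed
    (they are essential to the every-man-for-himself regime).
    """

    n_nodes: int
    arcs: frozenset[tuple[int, int]]
    hunters: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        object.__setattr__(self, "hunters", frozenset(self.hunters))
        validate_network(self)

    @property
    def nodes(self) -> range:
        return range(self.n_nodes)

    @property
    def nh(self) -> int:
        return len(self.hunters)

    def out_neighbors(self) -> list[list[int]]:
        """Adjacency lists, sorted for determinism."""
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in sorted(self.arcs):
            adj[u].append(v)
        return adj

    def with_arcs(self, arcs) -> "SharingNetwork":
        return SharingNetwork(self.n_nodes, frozenset(arcs), self.hunters)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for v in self.nodes:
            g.add_node(v, hunter=v in self.hunters)
        g.add_edges_from(sorted(self.arcs))
        return g

    @classmethod
    def from_networkx(cls, g) -> "SharingNetwork":
        relabel = {v: i for i, v in enumerate(g.nodes)}
        hunters = frozenset(relabel[v] for v, d in g.nodes(data=True) if d.get("hunter"))
        arcs = frozenset((relabel[u], relabel[v]) for u, v in g.edges)
        return cls(g.number_of_nodes(), arcs, hunters)


def validate_network(net: SharingNetwork) -> SharingNetwork:
    """Check all structural and model invariants; return the network unchanged.

    Raises
    ------
    InvalidStructureError
        On self-loops or arcs referencing nodes outside ``0..n_nodes-1``.
    InvalidModelError
        On an empty hunter set or hunter ids outside the node range.
    """
    if net.n_nodes < 1:
        raise InvalidStructureError("network needs at least one node")
    for u, v in net.arcs:
        if u == v:
            raise InvalidStructureError(f"self-loop at node {u}")
        if not (0 <= u < net.n_nodes and 0 <= v < net.n_nodes):
            raise InvalidStructureError(f"arc ({u}, {v}) outside node range 0..{net.n_nodes - 1}")
    if not net.hunters:
        raise InvalidModelError("hunter set must be nonempty")
    for h in net.hunters:
        if not 0 <= h < net.n_nodes:
            raise InvalidModelError(f"hunter id {h} outside node range 0..{net.n_nodes - 1}")
    return net


@dataclass(frozen=True)
class VisitProbabilities:
    """First-visit probabilities of the package walk.

    ``q[i, v]`` is the probability that the walk started at ``hunters[i]``
    visits node ``v`` within ``F - 1`` transfer steps (step 0 counts: a hunter
    always visits itself, so ``q[i, hunters[i]] = 1``).
    """

    hunters: tuple[int, ...]
    q: np.ndarray  # shape (nh, n_nodes)

    def __getitem__(self, hv: tuple[int, int]) -> float:
        h, v = hv
        return float(self.q[self.hunters.index(h), v])


def visit_probabilities(net: SharingNetwork, params: ModelParams) -> VisitProbabilities:
    """Exact first-visit probabilities within ``F - 1`` walk steps.

    For each target ``v`` the quantity ``g_t(u) = P(walk from u visits v
    within t steps)`` satisfies ``g_0(u) = [u = v]`` and, for ``u != v``,
    ``g_t(u) = mean over out-neighbors w of g_{t-1}(w)`` (0 if ``u`` has no
    out-neighbors, where the walk halts).  One backward recursion per target
    yields the whole matrix; revisits cannot inflate the probability because
    ``v`` acts as an absorbing state.
    """
    validate_network(net)
    n = net.n_nodes
    hunters = tuple(sorted(net.hunters))
    adj = net.out_neighbors()
    steps = params.F - 1
    q = np.zeros((len(hunters), n))
    for v in range(n):
        g = np.zeros(n)
        g[v] = 1.0
        for _ in range(steps):
            g_next = np.zeros(n)
            g_next[v] = 1.0
            for u in range(n):
                if u != v and adj[u]:
                    g_next[u] = sum(g[w] for w in adj[u]) / len(adj[u])
            g = g_next
        for i, h in enumerate(hunters):
            q[i, v] = g[h]
    return VisitProbabilities(hunters, q)


@dataclass(frozen=True)
class EatingProfile:
    """Per-node probability of eating in a single time step."""

    pe: np.ndarray
    hunters: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pe", np.asarray(self.pe, dtype=float))

    def __len__(self) -> int:
        return len(self.pe)

    def __getitem__(self, v: int) -> float:
        return float(self.pe[v])


def eating_probabilities(net: SharingNetwork, params: ModelParams) -> EatingProfile:
    """Exact probability of eating per node.

    Hunts are independent Bernoulli(ph) events across hunters, so by
    inclusion-exclusion ``pe(v) = 1 - prod_h (1 - ph * q[h, v])``.
    """
    vp = visit_probabilities(net, params)
    pe = 1.0 - np.prod(1.0 - params.ph * vp.q, axis=0)
    return EatingProfile(pe, net.hunters)


def simulate_events(
    net: SharingNetwork,
    params: ModelParams,
    num_events: int,
    seed: int,
) -> EatingProfile:
    """Monte-Carlo estimate of the eating profile by running the literal protocol.

    One *event* is a single time step: each hunter independently hunts with
    probability ``ph``; each successful hunt spawns a package of ``F`` units
    that walks the network, feeding each holder one unit (a node counts as fed
    once per event however many units reach it) and halting early at nodes
    with no out-neighbors.  The empirical ``pe(v)`` is the fraction of events
    in which ``v`` was fed at least once.
    """
    validate_network(net)
    if num_events < 1:
        raise ValueError(f"num_events must be >= 1, got {num_events}")
    rng = np.random.default_rng(seed)
    adj = net.out_neighbors()
    hunters = sorted(net.hunters)
    fed_counts = np.zeros(net.n_nodes, dtype=np.int64)
    hunts = rng.random((num_events, len(hunters))) < params.ph
    for e in range(num_events):
        fed: set[int] = set()
        for i, h in enumerate(hunters):
            if not hunts[e, i]:
                continue
            fed.add(h)
            pos, units = h, params.F - 1
            while units > 0 and adj[pos]:
                pos = adj[pos][rng.integers(len(adj[pos]))]
                fed.add(pos)
                units -= 1
        for v in fed:
            fed_counts[v] += 1
    return EatingProfile(fed_counts / num_events, net.hunters)
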