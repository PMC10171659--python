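"""The two minimization criteria and Pareto dominance machinery.

WEF (Welfare) is the population standard deviation of the eating
probabilities across all nodes, hunters included: an egalitarian-access
objective.  The RV criterion is the node average of the RV risk function:
an individual starvation-risk objective.  Both are to be minimized; the
multi-objective solution concept is the Pareto front under coordinate-wise
dominance.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .run_risk import rv_function
from .sharing_model import EatingProfile, ModelParams, SharingNetwork, eating_probabilities

__all__ = [
    "CostVector",
    "wef_cost",
    "rv_cost",
    "cost_vector",
    "dominates",
    "pareto_filter",
]


class CostVector(NamedTuple):
    rv: float
    wef: float


def _pe_array(profile) -> np.ndarray:
    pe = profile.pe if isinstance(profile, EatingProfile) else np.asarray(profile, dtype=float)
    if pe.size == 0:
        raise ValueError("profile must be nonempty")
    return pe


def wef_cost(profile) -> float:
    """Population (1/N) standard deviation of pe over all nodes."""
    return float(np.std(_pe_array(profile)))


def rv_cost(profile, n: int = 1000, k: int = 10) -> float:
    """Mean over all nodes of the RV function evaluated at each node's pe."""
    pe = _pe_array(profile)
    return float(np.mean([rv_function(float(p), n, k) for p in pe]))


def cost_vector(net: SharingNetwork, params: ModelParams) -> CostVector:
    """(RV, WEF) of the network's exact eating profile."""
    profile = eating_probabilities(net, params)
    return CostVector(rv_cost(profile, params.n, params.k), wef_cost(profile))


def dominates(u: Sequence[float], v: Sequence[float]) -> bool:
    """True iff ``u`` dominates ``v``: no worse in every coordinate, strictly
    better in at least one.  Defines a strict partial order."""
    return all(a <= b for a, b in zip(u, v)) and any(a < b for a, b in zip(u, v))


def pareto_filter(items: Sequence[Sequence[float]]) -> list:
    """Nondominated subset of ``items``, in stable input order.

    Duplicates are retained (identical vectors do not dominate each other).
    """
    items = list(items)
    if not items:
        raise ValueError("items must be nonempty")
    return [u for u in items if not any(dominates(v, u) for v in items)]
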