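"""Success-run statistics and the Reduction-of-Variability (RV) risk function.

A node that eats with probability ``pe`` per step experiences, over its life
span of ``n`` i.i.d. steps, "successes" (steps WITHOUT food) with probability
``q = 1 - pe``.  Lethal exposure is a maximal run of at least ``k`` successes;
``G_{n,k}`` counts such runs.  The RV function normalizes the sum of mean and
standard deviation of ``G_{n,k}`` by the maximum possible number of runs,
``gmax = floor((n+1)/(k+1))``::

    RV(pe) = (k+1)/(n+1) * (E[G_{n,k}] + sigma[G_{n,k}])

RV vanishes at ``pe = 1`` (never hungry), equals ``(k+1)/(n+1)`` at ``pe = 0``
(one long run, deterministic) and has an interior maximum at ``pe*``; below
``pe*`` extra food *raises* individual risk, which drives the model's
every-man-for-himself regime.

Two exact routes are provided: a Markov-chain embedding that yields the full
pmf of ``G_{n,k}``, and closed-form first/second moments from the indicator
decomposition of run starts.  They agree to machine precision; the closed
form is the fast default inside network-cost evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "RunCountDistribution",
    "run_count_distribution",
    "run_count_moments",
    "exact_run_moments",
    "rv_function",
    "rv_argmax",
    "simulate_run_counts",
]


@dataclass(frozen=True)
class RunCountDistribution:
    """Exact law of the number of maximal success runs of length >= k."""

    n: int
    k: int
    success_prob: float  # q = 1 - pe, probability of NOT eating in a step
    pmf: np.ndarray      # index g = 0 .. gmax

    @property
    def gmax(self) -> int:
        return (self.n + 1) // (self.k + 1)


def _check_nk(n: int, k: int) -> None:
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")


def run_count_distribution(n: int, k: int, pe: float) -> RunCountDistribution:
    """Exact pmf of ``G_{n,k}`` by Markov-chain embedding.

    State ``(r, g)``: current success-run length ``r`` capped at ``k`` and
    qualifying-run count ``g``.  A failure (eating) resets ``r``; the k-th
    consecutive success increments ``g``; further successes of the same run
    leave ``g`` unchanged (runs are counted maximally, once each).
    """
    _check_nk(n, k)
    if not 0.0 <= pe <= 1.0:
        raise ValueError(f"pe must be in [0, 1], got {pe}")
    q = 1.0 - pe
    gmax = (n + 1) // (k + 1)
    P = np.zeros((k + 1, gmax + 1))
    P[0, 0] = 1.0
    for _ in range(n):
        Q = np.zeros_like(P)
        Q[0, :] = (1.0 - q) * P.sum(axis=0)          # failure resets the run
        Q[1:k, :] += q * P[0:k - 1, :]               # run grows below k
        Q[k, 1:] += q * P[k - 1, :-1]                # k-th success: count a run
        Q[k, :] += q * P[k, :]                       # run already counted
        P = Q
    return RunCountDistribution(n, k, q, P.sum(axis=0))


def run_count_moments(dist: RunCountDistribution) -> tuple[float, float]:
    """(E, sigma) of the run count from its exact pmf."""
    g = np.arange(len(dist.pmf))
    e = float(dist.pmf @ g)
    var = float(dist.pmf @ (g - e) ** 2)
    return e, math.sqrt(max(var, 0.0))


def exact_run_moments(n: int, k: int, q: float) -> tuple[float, float]:
    """Closed-form ``(E[G], E[G^2])`` for the maximal-run count.

    Write ``G = sum_i I_i`` where ``I_i`` indicates a qualifying run starting
    at trial ``i`` (trial ``i-1`` fails, or ``i = 1``; trials ``i..i+k-1``
    succeed).  Then ``E[G] = q^k (1 + (n-k) p)`` with ``p = 1 - q``, and the
    cross terms ``E[I_i I_j]`` factorize because two run starts at distance
    ``>= k+1`` involve disjoint trials.
    """
    _check_nk(n, k)
    p = 1.0 - q
    e = q ** k * (1.0 + (n - k) * p)
    cross = 0.0
    if n >= 2 * k + 1:
        # i = 1 pairs with n-2k later starts (no leading failure needed);
        # each later start i >= 2 pairs with n-2k+1-i starts after it.
        c1 = n - 2 * k
        rest = (n - 2 * k - 1) * (n - 2 * k) / 2.0
        cross = q ** (2 * k) * p * (c1 + p * rest)
    return e, e + 2.0 * cross


@lru_cache(maxsize=200_000)
def _rv_cached(pe: float, n: int, k: int) -> float:
    e, e2 = exact_run_moments(n, k, 1.0 - pe)
    return (k + 1) / (n + 1) * (e + math.sqrt(max(e2 - e * e, 0.0)))


def rv_function(pe: float, n: int = 1000, k: int = 10, method: str = "moments") -> float:
    """RV(pe) = (k+1)/(n+1) * (E[G_{n,k}] + sigma[G_{n,k}]).

    ``method="moments"`` (default) uses the exact closed-form moments and is
    memoized; ``method="embedding"`` recomputes from the full pmf.  Both are
    exact and agree to ~1e-12.
    """
    if not 0.0 <= pe <= 1.0:
        raise ValueError(f"pe must be in [0, 1], got {pe}")
    if method == "moments":
        return _rv_cached(round(pe, 12), n, k)
    if method == "embedding":
        e, sigma = run_count_moments(run_count_distribution(n, k, pe))
        return (k + 1) / (n + 1) * (e + sigma)
    raise ValueError(f"unknown method {method!r}")


def rv_argmax(n: int = 1000, k: int = 10, tol: float = 1e-6) -> float:
    """Location ``pe*`` of the interior maximum of RV, by grid scan + refinement.

    A 1e-3 grid brackets the maximum; bounded scalar minimization of ``-RV``
    refines it to ``tol``.
    """
    if tol > 1e-4:
        raise ValueError("tol must be <= 1e-4")
    grid = np.linspace(0.0, 1.0, 1001)
    vals = np.array([rv_function(p, n, k) for p in grid])
    i = int(vals.argmax())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda p: -rv_function(float(p), n, k),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol / 10.0},
    )
    return float(res.x)


def simulate_run_counts(
    n: int, k: int, pe: float, reps: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo ``(E, sigma)`` of the run count by direct sequence simulation.

    Vectorized over replicates: a per-replicate run-length register advances
    on each no-food step and the count increments exactly when it hits ``k``.
    """
    _check_nk(n, k)
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    q = 1.0 - pe
    run = np.zeros(reps, dtype=np.int32)
    count = np.zeros(reps, dtype=np.int32)
    for _ in range(n):
        success = rng.random(reps) < q
        run = np.where(success, run + 1, 0)
        count += run == k
    return float(count.mean()), float(count.std())
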