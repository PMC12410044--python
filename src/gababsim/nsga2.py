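"""Elitist nondominated-sorting genetic algorithm (NSGA-II).

Standard Deb et al. (2002) components: fast nondominated sort, crowding
distance, binary tournament on (rank, crowding), simulated binary crossover
and polynomial mutation with bound clipping.  Fully seeded and
deterministic; objective vectors are minimized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["NSGA2Result", "fast_nondominated_sort", "crowding_distance",
           "nsga2_minimize"]


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition objective vectors into Pareto fronts (rank 0 first)."""
    n = len(F)
    # dominance matrix: d[i, j] True if i dominates j
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.arange(n)
    while len(remaining):
        mask = n_dominators[remaining] == 0
        if not mask.any():  # numerical pathology: break ties arbitrarily
            mask = n_dominators[remaining] == n_dominators[remaining].min()
        front = remaining[mask]
        fronts.append(front)
        remaining = remaining[~mask]
        if len(remaining):
            n_dominators[remaining] -= dom[np.ix_(front, remaining)].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each point within one front."""
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    d = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        fk = F[order, k]
        span = fk[-1] - fk[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return d


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(fast_nondominated_sort(F)):
        rank[front] = r
        crowd[front] = crowding_distance(F[front])
    return rank, crowd


def _tournament(rng, rank, crowd, k: int) -> np.ndarray:
    n = len(rank)
    a = rng.integers(0, n, size=k)
    b = rng.integers(0, n, size=k)
    better_b = (rank[b] < rank[a]) | ((rank[b] == rank[a]) & (crowd[b] > crowd[a]))
    return np.where(better_b, b, a)


def _sbx(rng, p1, p2, lo, hi, eta=15.0, prob=0.9):
    """Simulated binary crossover, per-variable."""
    c1, c2 = p1.copy(), p2.copy()
    do = (rng.random(p1.shape) < 0.5) & (np.abs(p1 - p2) > 1e-14)
    if rng.random() < prob and do.any():
        u = rng.random(p1.shape)
        beta = np.where(u <= 0.5,
                        (2 * u) ** (1 / (eta + 1)),
                        (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
        mean = 0.5 * (p1 + p2)
        diff = 0.5 * np.abs(p1 - p2)
        c1 = np.where(do, mean - beta * diff, c1)
        c2 = np.where(do, mean + beta * diff, c2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(rng, x, lo, hi, eta=20.0, prob=None):
    n = len(x)
    prob = 1.0 / n if prob is None else prob
    y = x.copy()
    span = hi - lo
    for i in range(n):
        if rng.random() < prob and span[i] > 0:
            u = rng.random()
            delta1 = (y[i] - lo[i]) / span[i]
            delta2 = (hi[i] - y[i]) / span[i]
            if u < 0.5:
                dq = (2 * u + (1 - 2 * u) * (1 - delta1) ** (eta + 1)) \
                    ** (1 / (eta + 1)) - 1
            else:
                dq = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - delta2)
                          ** (eta + 1)) ** (1 / (eta + 1))
            y[i] = np.clip(y[i] + dq * span[i], lo[i], hi[i])
    return y


@dataclass
class NSGA2Result:
    X: np.ndarray            # final population decision vectors
    F: np.ndarray            # final population objectives
    history: list[np.ndarray]  # per-generation objective arrays
    n_evaluations: int


def nsga2_minimize(evaluate: Callable[[np.ndarray], np.ndarray],
                   bounds: Sequence[tuple[float, float]],
                   pop_size: int, n_gen: int, seed: int,
                   log_scale: Sequence[bool] | None = None,
                   log_floor: float = 1e-3,
                   eta_c: float = 15.0, p_c: float = 0.9,
                   eta_m: float = 20.0, p_m: float | None = None,
                   x_init: np.ndarray | None = None) -> NSGA2Result:
    """Minimize a vector objective over box bounds.

    ``evaluate`` maps one decision vector to an objective vector (all
    objectives minimized; infeasible evaluations should return a large
    finite sentinel).  ``log_scale`` marks variables whose bounds span
    orders of magnitude and are initialized log-uniformly (the search
    itself stays in linear coordinates).
    """
    if pop_size < 8 or pop_size % 2:
        raise ValueError("pop_size must be even and >= 8")
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    nv = len(bounds)
    log_scale = np.array(log_scale if log_scale is not None
                         else [False] * nv)

    # Latin-hypercube initialization: stratified coverage of every
    # variable; log-scaled variables are stratified in log coordinates.
    u = (rng.permuted(np.tile(np.arange(pop_size), (nv, 1)), axis=1).T
         + rng.random((pop_size, nv))) / pop_size
    X = lo + u * (hi - lo)
    for i in np.nonzero(log_scale)[0]:
        llo = np.log(max(lo[i], log_floor))
        X[:, i] = np.exp(llo + u[:, i] * (np.log(hi[i]) - llo))
    if x_init is not None:
        k = min(len(x_init), pop_size)
        X[:k] = np.clip(x_init[:k], lo, hi)

    F = np.array([evaluate(x) for x in X])
    n_eval = pop_size
    history = [F.copy()]

    for _ in range(n_gen):
        rank, crowd = _rank_and_crowd(F)
        parents = _tournament(rng, rank, crowd, pop_size)
        children = []
        for j in range(0, pop_size, 2):
            c1, c2 = _sbx(rng, X[parents[j]], X[parents[j + 1]], lo, hi,
                          eta=eta_c, prob=p_c)
            children.append(_poly_mutation(rng, c1, lo, hi, eta=eta_m,
                                           prob=p_m))
            children.append(_poly_mutation(rng, c2, lo, hi, eta=eta_m,
                                           prob=p_m))
        CX = np.array(children)
        CF = np.array([evaluate(x) for x in CX])
        n_eval += pop_size
        # environmental selection over parents + children
        AX = np.vstack([X, CX])
        AF = np.vstack([F, CF])
        keep: list[int] = []
        for front in fast_nondominated_sort(AF):
            if len(keep) + len(front) <= pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(AF[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order][: pop_size - len(keep)].tolist())
                break
        X, F = AX[keep], AF[keep]
        history.append(F.copy())
    return NSGA2Result(X=X, F=F, history=history, n_evaluations=n_eval)
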