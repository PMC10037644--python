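"""Compact elitist multi-objective evolutionary optimizer (NSGA-II).

Minimizes a vector-valued objective f: R^d -> R^m over a box, using fast
non-dominated sorting, crowding-distance selection, binary tournaments,
simulated binary crossover (SBX) and polynomial mutation.  Fully
deterministic for a fixed seed.  The population evaluator is vectorized:
``f(X)`` receives an (N, d) array and returns (N, m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class GAConfig:
    pop_size: int = 80
    generations: int = 60
    seed: int = 1234
    tol: float = 1e-6            # function tolerance on the front's ideal point
    tol_window: int = 10         # stall generations before tolerance stop
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0
    crossover_prob: float = 0.9


@dataclass
class GAResult:
    X: np.ndarray                # (K, d) nondominated decision vectors
    F: np.ndarray                # (K, m) their objectives
    n_generations: int = 0
    converged: bool = False
    history: list = field(default_factory=list)   # per-gen ideal points


def nondominated_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of Pareto-efficient rows (minimization, strict dominance)."""
    n = len(F)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        dominates = (np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1))
        if dominates.any():
            mask[i] = False
    return mask


def _fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    n = len(F)
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt                        # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = np.flatnonzero(remaining & (n_dominators == 0))
        if len(current) == 0:            # numerical safety: break ties arbitrarily
            current = np.flatnonzero(remaining)[:1]
        fronts.append(current)
        remaining[current] = False
        n_dominators = n_dominators - dom[current].sum(axis=0)
        n_dominators[~remaining] = -1
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


def _sbx(parents: np.ndarray, lb: np.ndarray, ub: np.ndarray, eta: float,
         prob: float, rng: np.random.Generator) -> np.ndarray:
    a, b = parents[0::2], parents[1::2]
    u = rng.random(a.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    do = rng.random(a.shape) < prob
    beta = np.where(do, beta, 1.0)
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    out = np.empty_like(parents)
    out[0::2], out[1::2] = c1, c2
    return np.clip(out, lb, ub)


def _poly_mutation(X: np.ndarray, lb: np.ndarray, ub: np.ndarray, eta: float,
                   rng: np.random.Generator) -> np.ndarray:
    span = ub - lb
    prob = 1.0 / X.shape[1]
    do = rng.random(X.shape) < prob
    u = rng.random(X.shape)
    delta = np.where(u < 0.5, (2 * u) ** (1 / (eta + 1)) - 1,
                     1 - (2 * (1 - u)) ** (1 / (eta + 1)))
    return np.clip(X + np.where(do, delta * span, 0.0), lb, ub)


def _tournament(rank: np.ndarray, crowd: np.ndarray, n: int,
                rng: np.random.Generator) -> np.ndarray:
    i = rng.integers(0, len(rank), size=n)
    j = rng.integers(0, len(rank), size=n)
    better = (rank[i] < rank[j]) | ((rank[i] == rank[j]) & (crowd[i] > crowd[j]))
    return np.where(better, i, j)


def nsga2(f: Callable[[np.ndarray], np.ndarray], lb: np.ndarray, ub: np.ndarray,
          cfg: GAConfig | None = None) -> GAResult:
    """Minimize the vectorized multi-objective ``f`` over the box [lb, ub]."""
    cfg = cfg or GAConfig()
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    d = len(lb)
    rng = np.random.default_rng(cfg.seed)
    N = cfg.pop_size + (cfg.pop_size % 2)

    X = lb + rng.random((N, d)) * (ub - lb)
    F = np.asarray(f(X), dtype=float)
    history: list[np.ndarray] = []
    stall = 0
    converged = False
    gen = 0
    for gen in range(1, cfg.generations + 1):
        fronts = _fast_nondominated_sort(F)
        rank = np.empty(N, dtype=int)
        crowd = np.empty(N)
        for r, fr in enumerate(fronts):
            rank[fr] = r
            crowd[fr] = _crowding_distance(F[fr])
        parents = X[_tournament(rank, crowd, N, rng)]
        children = _sbx(parents, lb, ub, cfg.crossover_eta, cfg.crossover_prob, rng)
        children = _poly_mutation(children, lb, ub, cfg.mutation_eta, rng)
        Fc = np.asarray(f(children), dtype=float)

        Xall = np.vstack([X, children])
        Fall = np.vstack([F, Fc])
        fronts = _fast_nondominated_sort(Fall)
        keep: list[int] = []
        for fr in fronts:
            if len(keep) + len(fr) <= N:
                keep.extend(fr.tolist())
            else:
                cd = _crowding_distance(Fall[fr])
                order = np.argsort(-cd, kind="stable")
                keep.extend(fr[order[: N - len(keep)]].tolist())
                break
        X, F = Xall[keep], Fall[keep]

        ideal = F.min(axis=0)
        history.append(ideal)
        if len(history) > 1:
            scale = np.maximum(np.abs(history[-2]), 1.0)
            if np.all(np.abs(history[-1] - history[-2]) / scale < cfg.tol):
                stall += 1
            else:
                stall = 0
            if stall >= cfg.tol_window:
                converged = True
                break

    mask = nondominated_mask(F)
    Xf, Ff = X[mask], F[mask]
    # deduplicate identical objective rows for a clean front
    _, unique = np.unique(np.round(Ff, 15), axis=0, return_index=True)
    unique = np.sort(unique)
    return GAResult(X=Xf[unique], F=Ff[unique], n_generations=gen,
                    converged=converged, history=history)
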