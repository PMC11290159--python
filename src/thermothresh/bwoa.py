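"""Black Widow Optimization Algorithm (BWOA).

A population metaheuristic modeled on black-widow mating behavior. Each
candidate ("widow") is a real vector in a box. Every generation:

1. the best ``round(PP * N)`` widows form the breeding pool and are paired
   at random;
2. each pair procreates by convex recombination (``V1 = a*x1 + (1-a)*x2``,
   ``V2 = a*x2 + (1-a)*x1`` with fresh uniform ``a`` per offspring pair);
3. cannibalism discards the lower-fitness parent (sexual) and keeps only the
   ``ceil(CR * n)`` best offspring per pair (sibling);
4. ``round(PM * N)`` members of the merged survivor pool mutate;
5. the next generation is the ``N`` best of the merged pool and the current
   population (elitist truncation, so the best fitness never decreases).

All randomness flows through a single ``numpy`` Generator in a fixed draw
order (pairing permutation, alpha, [Levy steps], mutation selection,
mutation values, [QOBL draws]), so runs are bit-reproducible from a seed.
The fitness function must accept a batch of positions, shape (n, d), and
return shape (n,); maximization throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .image import ValidationError

FitnessFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class Widow:
    """A candidate solution: a position vector and its cached fitness."""

    position: np.ndarray
    fitness: Optional[float] = None


@dataclass
class Population:
    """Array-of-struct view of the population (positions row-wise)."""

    positions: np.ndarray  # (N, d)
    fitness: np.ndarray    # (N,)

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def best(self) -> Widow:
        i = int(np.argmax(self.fitness))
        return Widow(self.positions[i].copy(), float(self.fitness[i]))

    def widows(self) -> list[Widow]:
        return [Widow(p.copy(), float(f)) for p, f in zip(self.positions, self.fitness)]


@dataclass
class BWOAConfig:
    """Hyperparameters of the search.

    Defaults follow the standard protocol for multilevel thresholding:
    population 50, 350 iterations, procreation (crossover) rate 0.8,
    cannibalism rate 0.5, mutation rate 0.4.
    """

    dim: int = 2
    lower: float | np.ndarray = 0.0
    upper: float | np.ndarray = 254.0
    n_pop: int = 50
    max_iter: int = 350
    procreate_rate: float = 0.8
    cannibalism_rate: float = 0.5
    mutation_rate: float = 0.4
    n_offspring: Optional[int] = None  # per pair; default 2*ceil(dim/2), min 2
    mutation_strategy: str = "reset"   # "reset" or "swap"
    seed: Optional[int] = None
    stop: str = "max_iter"             # "max_iter" | "fitness_stall" | "target_fitness"
    stall_patience: int = 50
    stall_tol: float = 0.0
    target_fitness: Optional[float] = None

    def __post_init__(self):
        lo = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValidationError("bounds must be finite")
        if np.any(lo >= hi):
            raise ValidationError("lower bounds must be strictly below upper bounds")
        self.lower = lo
        self.upper = hi
        for name in ("procreate_rate", "cannibalism_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_pop < 4:
            raise ValidationError("population size must be at least 4")
        if self.mutation_strategy not in ("reset", "swap"):
            raise ValidationError(f"unknown mutation strategy {self.mutation_strategy!r}")

    def offspring_per_pair(self) -> int:
        if self.n_offspring is not None:
            n = int(self.n_offspring)
        else:
            n = max(2, 2 * math.ceil(self.dim / 2))
        if n < 2 or n % 2:
            raise ValidationError("n_offspring must be an even integer >= 2")
        return n


@dataclass
class ConvergenceTrace:
    """Per-iteration best/mean fitness and the best position so far."""

    best_fitness: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_fitness: np.ndarray = field(default_factory=lambda: np.empty(0))
    best_position: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __len__(self) -> int:
        return self.best_fitness.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(len(self)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
            }
        ).to_csv(path, index=False)


def _rng(seed_or_rng) -> np.random.Generator:
    if seed_or_rng is None or isinstance(seed_or_rng, (int, np.integer)):
        return np.random.default_rng(seed_or_rng)
    return seed_or_rng  # a Generator, or any object with the same draw API


def initialize_population(cfg: BWOAConfig, fitness_fn: FitnessFn,
                          rng=None) -> Population:
    """Uniform random population in the box, all widows evaluated."""
    rng = _rng(cfg.seed if rng is None else rng)
    pos = rng.uniform(cfg.lower, cfg.upper, size=(cfg.n_pop, cfg.dim))
    return Population(pos, np.asarray(fitness_fn(pos), dtype=float))


def procreate(x1: np.ndarray, x2: np.ndarray, n_offspring: int, rng) -> list[np.ndarray]:
    """Convex-recombination offspring of a parent pair.

    Offspring come in pairs: a fresh uniform alpha vector yields
    ``V1 = a*x1 + (1-a)*x2`` and ``V2 = a*x2 + (1-a)*x1``, so each pair
    conserves the componentwise parent sum.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValidationError("parents must have the same dimension")
    if n_offspring < 2 or n_offspring % 2:
        raise ValidationError("n_offspring must be an even integer >= 2")
    rng = _rng(rng)
    alpha = rng.random((n_offspring // 2, x1.size))
    v1 = alpha * x1 + (1 - alpha) * x2
    v2 = alpha * x2 + (1 - alpha) * x1
    return [*v1, *v2]


def cannibalism(parents: tuple[Widow, Widow], offspring: list[Widow],
                cr: float) -> list[Widow]:
    """Sexual + sibling cannibalism.

    The lower-fitness parent is eaten (ties keep the first-listed parent);
    the ``ceil(cr * len(offspring))`` best offspring survive. Returns the
    surviving parent followed by surviving offspring, best first.
    """
    p1, p2 = parents
    survivor = p1 if p1.fitness >= p2.fitness else p2
    n_keep = min(len(offspring), max(1, math.ceil(cr * len(offspring))))
    ranked = sorted(offspring, key=lambda w: -w.fitness)
    return [survivor, *ranked[:n_keep]]


def mutate(pop: Population, pm: float, strategy: str, rng,
           lower: np.ndarray, upper: np.ndarray,
           fitness_fn: FitnessFn) -> Population:
    """Mutate ``round(pm * N)`` widows chosen without replacement.

    ``swap`` exchanges two distinct components; ``reset`` redraws one
    component uniformly within bounds. Mutants are re-evaluated. With a
    single dimension ``swap`` degrades to ``reset``.
    """
    rng = _rng(rng)
    pos = pop.positions.copy()
    fit = pop.fitness.copy()
    n, d = pos.shape
    m = min(n, int(round(pm * n)))
    if m == 0:
        return Population(pos, fit)
    sel = rng.choice(n, size=m, replace=False)
    if strategy == "swap" and d >= 2:
        cols = np.argsort(rng.random((m, d)), axis=1)[:, :2]
        a = pos[sel, cols[:, 0]].copy()
        pos[sel, cols[:, 0]] = pos[sel, cols[:, 1]]
        pos[sel, cols[:, 1]] = a
    else:
        comp = rng.integers(0, d, size=m)
        vals = lower[comp] + rng.random(m) * (upper[comp] - lower[comp])
        pos[sel, comp] = vals
    fit[sel] = fitness_fn(pos[sel])
    return Population(pos, fit)


def _merge_keep_best(pos_a, fit_a, pos_b, fit_b, n: int):
    """Best *n* of two candidate sets; stable, first set wins ties."""
    pos = np.concatenate((pos_a, pos_b), axis=0)
    fit = np.concatenate((fit_a, fit_b))
    order = np.argsort(-fit, kind="stable")[:n]
    return pos[order], fit[order]


def _evolve(cfg: BWOAConfig, fitness_fn: FitnessFn, rng: np.random.Generator,
            levy=None, qobl_jump_rate: float = 0.0, initial_positions=None):
    """Shared generation loop for BWOA and IBWOA.

    ``levy`` (a LevyConfig) perturbs the recombination alphas with
    heavy-tailed steps; ``qobl_jump_rate > 0`` enables quasi-opposition
    merges at initialization and, with that probability, per generation.
    Disabled operators consume no random draws, so the plain-BWOA stream
    is reproduced exactly when both are off.
    """
    from .ibwoa import _levy_steps, _qobl_batch  # local import to avoid a cycle

    lo, hi = cfg.lower, cfg.upper
    n, d = cfg.n_pop, cfg.dim
    use_levy = levy is not None and levy.scale != 0.0
    use_qobl = qobl_jump_rate > 0.0

    pos = rng.uniform(lo, hi, size=(n, d))
    if initial_positions is not None:
        init = np.clip(np.atleast_2d(np.asarray(initial_positions, dtype=float)),
                       lo, hi)
        pos[: init.shape[0]] = init
    fit = np.asarray(fitness_fn(pos), dtype=float)
    if use_qobl:
        qpos = _qobl_batch(pos, lo, hi, rng)
        qfit = np.asarray(fitness_fn(qpos), dtype=float)
        pos, fit = _merge_keep_best(pos, fit, qpos, qfit, n)

    best_i = int(np.argmax(fit))
    best_pos = pos[best_i].copy()
    best_fit = float(fit[best_i])

    n_off = cfg.offspring_per_pair()
    keep = min(n_off, max(1, math.ceil(cfg.cannibalism_rate * n_off)))
    nr = int(round(cfg.procreate_rate * n))
    n_pairs = nr // 2

    trace_best, trace_mean, trace_pos = [], [], []
    stall = 0

    for _ in range(cfg.max_iter):
        if n_pairs >= 1:
            order = np.argsort(-fit, kind="stable")
            pool_idx = order[:nr]
            perm = rng.permutation(nr)
            pairs = pool_idx[perm[: 2 * n_pairs]].reshape(n_pairs, 2)
            x1 = pos[pairs[:, 0]]
            x2 = pos[pairs[:, 1]]
            alpha = rng.random((n_pairs, n_off // 2, d))
            v1 = alpha * x1[:, None, :] + (1 - alpha) * x2[:, None, :]
            v2 = alpha * x2[:, None, :] + (1 - alpha) * x1[:, None, :]
            if use_levy:
                delta = _levy_steps(alpha.shape, levy, rng) * (hi - lo)
                v1 = v1 + delta
                v2 = v2 - delta
            off = np.concatenate((v1, v2), axis=1)  # (pairs, n_off, d)
            off = np.clip(off, lo, hi)
            off_fit = np.asarray(
                fitness_fn(off.reshape(-1, d)), dtype=float
            ).reshape(n_pairs, n_off)

            pf = np.stack((fit[pairs[:, 0]], fit[pairs[:, 1]]), axis=1)
            surv = np.argmax(pf, axis=1)  # ties -> first-listed parent
            surv_pos = np.where(surv[:, None] == 0, x1, x2)
            surv_fit = pf[np.arange(n_pairs), surv]

            rank = np.argsort(-off_fit, axis=1, kind="stable")[:, :keep]
            rows = np.arange(n_pairs)[:, None]
            kept_pos = off[rows, rank].reshape(-1, d)
            kept_fit = off_fit[rows, rank].reshape(-1)

            pool_pos = np.concatenate((surv_pos, kept_pos), axis=0)
            pool_fit = np.concatenate((surv_fit, kept_fit))
        else:
            pool_pos = np.empty((0, d))
            pool_fit = np.empty(0)

        if cfg.mutation_rate > 0 and pool_pos.shape[0] > 0:
            m = min(pool_pos.shape[0], int(round(cfg.mutation_rate * n)))
            if m > 0:
                sel = rng.choice(pool_pos.shape[0], size=m, replace=False)
                if cfg.mutation_strategy == "swap" and d >= 2:
                    cols = np.argsort(rng.random((m, d)), axis=1)[:, :2]
                    a = pool_pos[sel, cols[:, 0]].copy()
                    pool_pos[sel, cols[:, 0]] = pool_pos[sel, cols[:, 1]]
                    pool_pos[sel, cols[:, 1]] = a
                else:
                    comp = rng.integers(0, d, size=m)
                    pool_pos[sel, comp] = lo[comp] + rng.random(m) * (hi[comp] - lo[comp])
                pool_fit[sel] = fitness_fn(pool_pos[sel])

        pos, fit = _merge_keep_best(pool_pos, pool_fit, pos, fit, n)

        if use_qobl and rng.random() < qobl_jump_rate:
            qpos = _qobl_batch(pos, lo, hi, rng)
            qfit = np.asarray(fitness_fn(qpos), dtype=float)
            pos, fit = _merge_keep_best(pos, fit, qpos, qfit, n)

        it_best = int(np.argmax(fit))
        delta = float(fit[it_best]) - best_fit
        if delta > 0:
            best_fit = float(fit[it_best])
            best_pos = pos[it_best].copy()
        trace_best.append(best_fit)
        trace_mean.append(float(fit.mean()))
        trace_pos.append(best_pos.copy())

        if cfg.stop == "target_fitness" and cfg.target_fitness is not None:
            if best_fit >= cfg.target_fitness:
                break
        elif cfg.stop == "fitness_stall":
            stall = 0 if delta > cfg.stall_tol else stall + 1
            if stall >= cfg.stall_patience:
                break

    trace = ConvergenceTrace(
        best_fitness=np.asarray(trace_best),
        mean_fitness=np.asarray(trace_mean),
        best_position=np.asarray(trace_pos),
    )
    return Widow(best_pos, best_fit), trace


def bwoa_optimize(cfg: BWOAConfig, fitness_fn: FitnessFn, rng=None,
                  initial_positions=None) -> tuple[Widow, ConvergenceTrace]:
    """Run the standard BWOA; returns the best widow and the trace.

    ``initial_positions`` replaces the first rows of the random initial
    population (e.g. to seed a known candidate; elitism then guarantees the
    returned fitness is at least as good).
    """
    return _evolve(cfg, fitness_fn, _rng(cfg.seed if rng is None else rng),
                   initial_positions=initial_positions)
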