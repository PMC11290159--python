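"""Thresholding objectives: Otsu between-class variance and Kapur entropy.

Both objectives are functions of the histogram only. A threshold vector
``th_1 < ... < th_k`` partitions the gray levels into ``k + 1`` contiguous
classes ``[0, th_1], [th_1+1, th_2], ..., [th_k+1, L-1]``.

Otsu's criterion is the between-class variance

    sigma_B^2 = sum_j omega_j (mu_j - mu_T)^2,

with class mass ``omega_j``, class mean ``mu_j`` and global mean ``mu_T``;
Kapur's criterion is the sum of Shannon entropies (natural log) of the
normalized within-class distributions

    H_j = - sum_{i in class j} (p_i / omega_j) ln(p_i / omega_j).

Both are maximized. Empty classes contribute 0 to either objective so that
stochastic search may traverse degenerate candidates; levels with
``p_i = 0`` contribute 0 to the entropy (the ``x ln x -> 0`` limit).

Everything is computed from three prefix-sum vectors (of ``p_i``,
``i * p_i`` and ``p_i ln p_i``), giving O(1) per-class statistics; the
exhaustive oracle enumerates every threshold combination with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Histogram, ValidationError, validate_thresholds


class CapabilityError(ValueError):
    """Raised when an exact method is requested beyond its feasible range."""


OBJECTIVES = ("otsu", "kapur")


@dataclass(frozen=True)
class ObjectiveResult:
    """Fitness of a threshold vector plus per-class statistics.

    ``per_class`` holds ``(omega_j, mu_j)`` pairs for Otsu and
    ``(omega_j, H_j)`` pairs for Kapur; ``empty`` flags classes with zero
    probability mass (their statistic is reported as 0).
    """

    fitness: float
    per_class: tuple
    objective_name: str
    empty: tuple


def _check_objective(objective: str) -> str:
    if objective not in OBJECTIVES:
        raise ValidationError(f"objective must be one of {OBJECTIVES}, got {objective!r}")
    return objective


def _prefix_sums(h: Histogram):
    """Cumulative sums of p, i*p and p*ln(p), each with a leading zero."""
    p = h.p
    i = np.arange(p.size, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plnp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    zero = np.zeros(1)
    return (
        np.concatenate((zero, np.cumsum(p))),
        np.concatenate((zero, np.cumsum(i * p))),
        np.concatenate((zero, np.cumsum(plnp))),
    )


def _class_edges(th: np.ndarray, levels: int):
    lo = np.concatenate(([0], th + 1))
    hi = np.concatenate((th, [levels - 1]))
    return lo, hi


def class_statistics(h: Histogram, th) -> list[tuple[float, float]]:
    """Per-class ``(omega_j, mu_j)``; an empty class gets ``mu_j = 0``.

    ``omega_j`` is the probability mass of class j and ``mu_j`` its mean
    gray level ``sum(i p_i) / omega_j``.
    """
    th = validate_thresholds(th, h.levels)
    cp, cip, _ = _prefix_sums(h)
    lo, hi = _class_edges(th, h.levels)
    omega = cp[hi + 1] - cp[lo]
    s1 = cip[hi + 1] - cip[lo]
    mu = np.where(omega > 0, s1 / np.where(omega > 0, omega, 1.0), 0.0)
    return list(zip(omega.tolist(), mu.tolist()))


def otsu_fitness(h: Histogram, th) -> ObjectiveResult:
    """Between-class variance of the partition induced by *th*."""
    th = validate_thresholds(th, h.levels)
    cp, cip, _ = _prefix_sums(h)
    lo, hi = _class_edges(th, h.levels)
    fitness = float(_otsu_contrib(cp, cip, lo, hi, _global_mean(h)).sum())
    stats = class_statistics(h, th)
    empty = tuple(w == 0 for w, _ in stats)
    return ObjectiveResult(fitness=fitness, per_class=tuple(stats),
                           objective_name="otsu", empty=empty)


def kapur_fitness(h: Histogram, th) -> ObjectiveResult:
    """Sum of within-class Shannon entropies (natural log)."""
    th = validate_thresholds(th, h.levels)
    cp, _, cplnp = _prefix_sums(h)
    lo, hi = _class_edges(th, h.levels)
    contrib = _kapur_contrib(cp, cplnp, lo, hi)
    omega = cp[hi + 1] - cp[lo]
    fitness = float(contrib.sum())
    empty = tuple(w == 0 for w in omega)
    per_class = tuple(zip(omega.tolist(), contrib.tolist()))
    return ObjectiveResult(fitness=fitness, per_class=per_class,
                           objective_name="kapur", empty=empty)


def evaluate(h: Histogram, th, objective: str) -> ObjectiveResult:
    """Dispatch to :func:`otsu_fitness` or :func:`kapur_fitness`."""
    return (otsu_fitness if _check_objective(objective) == "otsu" else kapur_fitness)(h, th)


def _global_mean(h: Histogram) -> float:
    return float(np.arange(h.levels) @ h.p)


def _otsu_contrib(cp, cip, lo, hi, mu_t):
    """omega_j (mu_j - mu_T)^2 for segments [lo, hi], 0 when empty."""
    omega = cp[hi + 1] - cp[lo]
    s1 = cip[hi + 1] - cip[lo]
    dev = s1 - omega * mu_t
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(omega > 0, dev * dev / np.where(omega > 0, omega, 1.0), 0.0)
    return out


def _kapur_contrib(cp, cplnp, lo, hi):
    """H_j = ln(omega_j) - (sum p ln p)_j / omega_j for segments, 0 when empty."""
    omega = cp[hi + 1] - cp[lo]
    s = cplnp[hi + 1] - cplnp[lo]
    safe = np.where(omega > 0, omega, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(omega > 0, np.log(safe) - s / safe, 0.0)
    return out


def decode_positions(positions: np.ndarray, levels: int = 256) -> np.ndarray:
    """Map real-valued search positions to integer threshold vectors.

    Clamp to ``[0, L-2]``, round half-up, then sort each row. Duplicate
    thresholds after rounding produce empty classes (which score 0), so the
    decoded vector is always a valid candidate for the objectives.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    th = np.floor(np.clip(pos, 0, levels - 2) + 0.5).astype(np.int64)
    th.sort(axis=1)
    return th


def make_batch_evaluator(h: Histogram, objective: str):
    """Vectorized fitness over a batch of real positions, shape (n, k) -> (n,).

    The returned callable decodes each row (clamp, round, sort) and scores
    it with the shared prefix-sum class contributions, so its values agree
    bit-for-bit with :func:`otsu_fitness` / :func:`kapur_fitness` on the
    decoded thresholds.
    """
    _check_objective(objective)
    cp, cip, cplnp = _prefix_sums(h)
    levels = h.levels
    mu_t = _global_mean(h)

    def fitness(positions: np.ndarray) -> np.ndarray:
        th = decode_positions(positions, levels)
        n, k = th.shape
        lo = np.concatenate((np.zeros((n, 1), dtype=np.int64), th + 1), axis=1)
        hi = np.concatenate((th, np.full((n, 1), levels - 1, dtype=np.int64)), axis=1)
        # duplicated thresholds give lo > hi segments; force them empty
        hi_c = np.maximum(hi, lo - 1)
        if objective == "otsu":
            contrib = _otsu_contrib(cp, cip, lo, hi_c, mu_t)
        else:
            contrib = _kapur_contrib(cp, cplnp, lo, hi_c)
        return contrib.sum(axis=1)

    return fitness


def _segment_score_matrix(h: Histogram, objective: str) -> np.ndarray:
    """S[a, b] = contribution of class [a, b] to the objective (0 if a > b)."""
    cp, cip, cplnp = _prefix_sums(h)
    levels = h.levels
    a = np.arange(levels)[:, None]
    b = np.arange(levels)[None, :]
    lo = np.broadcast_to(a, (levels, levels))
    hi = np.maximum(b, a - 1)  # a > b -> empty segment -> score 0
    if objective == "otsu":
        s = _otsu_contrib(cp, cip, lo, hi, _global_mean(h))
    else:
        s = _kapur_contrib(cp, cplnp, lo, hi)
    return np.where(a <= b, s, 0.0)


def exhaustive_optimal(h: Histogram, k: int, objective: str):
    """Globally optimal thresholds by enumeration of all C(L-1, k) vectors.

    Supports ``k in {1, 2, 3}``; ties are broken by the lexicographically
    smallest threshold vector. Returns ``(thresholds, fitness)`` where the
    fitness is re-evaluated through the same code path the metaheuristics
    use, so equality checks against optimizer output are exact.
    """
    _check_objective(objective)
    if not 1 <= k <= 3:
        raise CapabilityError(
            f"exhaustive search supports k <= 3 (got k={k}); use the metaheuristic"
        )
    levels = h.levels
    t_max = levels - 2  # a threshold at L-1 would guarantee an empty top class
    S = _segment_score_matrix(h, objective)
    top = S[:, levels - 1]  # top[a] = score of class [a, L-1]

    if k == 1:
        t = np.arange(t_max + 1)
        vals = S[0, t] + top[t + 1]
        best = int(np.argmax(vals))  # first max -> lexicographically smallest
        th = (best,)
    elif k == 2:
        t1 = np.arange(t_max + 1)[:, None]
        t2 = np.arange(t_max + 1)[None, :]
        vals = S[0, t1.ravel()][:, None] + S[t1 + 1, t2] + top[(t2 + 1).ravel()][None, :]
        vals = np.where(t1 < t2, vals, -np.inf)
        flat = int(np.argmax(vals))  # row-major first max -> lexicographic
        th = (flat // (t_max + 1), flat % (t_max + 1))
    else:
        t2 = np.arange(t_max + 1)[:, None]
        t3 = np.arange(t_max + 1)[None, :]
        tail = np.where(t2 < t3, S[t2 + 1, t3] + top[(t3 + 1).ravel()][None, :], -np.inf)
        best_val = -np.inf
        th = (0, 1, 2)
        n = t_max + 1
        for t1 in range(t_max - 1):
            vals = S[t1 + 1, t2.ravel()][:, None] + tail
            vals[: t1 + 1, :] = -np.inf  # require t2 > t1
            flat = int(np.argmax(vals))
            v = float(vals.flat[flat]) + float(S[0, t1])
            if v > best_val:  # strict: keeps the smallest t1 on ties
                best_val = v
                th = (t1, flat // n, flat % n)

    th = tuple(int(t) for t in th)
    fitness = float(evaluate(h, th, objective).fitness)
    return th, fitness
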