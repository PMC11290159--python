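"""Synthetic thermogram-like images with known histogram mode structure.

Real breast thermograms have smooth multimodal gray-level histograms: a
cool background plus a few warmer tissue regions, each contributing a
roughly Gaussian intensity mode. The generator emulates exactly that
histogram shape — a 2-6 component Gaussian mixture on [0, 255] — while
arranging the modes as smooth elliptical blobs over a background region so
the images also carry gradients and phase structure for FSIM.

Two outputs per specification:

* :func:`generate_histogram` — the analytic mixture discretized to 256
  levels (no sampling noise); the fast input for oracle/optimizer tests.
* :func:`generate_image` — a sampled image whose per-mode pixel counts
  match the mixture weights exactly and whose gray values are drawn by
  quantile (stratified) sampling from each mode's discretized
  distribution, so the empirical histogram tracks the analytic one
  closely even at 128 x 128.

:func:`fixture_suite` builds a reproducible corpus with cached
exhaustive-oracle optima for k in {1, 2, 3} under both objectives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .image import (DEFAULT_LEVELS, Histogram, ValidationError,
                    compute_histogram, load_gray_image, save_gray_image)
from .objectives import OBJECTIVES, exhaustive_optimal


@dataclass(frozen=True)
class MixtureSpec:
    """A Gaussian intensity mixture plus image geometry.

    ``modes`` is a sequence of ``(mean, sd, weight)`` with means in
    [0, 255], positive sd, and weights summing to 1. ``background`` names
    the mean of the mode rendered as the background region (default: the
    heaviest mode).
    """

    modes: tuple
    shape: tuple = (128, 128)
    background: float | None = None
    seed: int = 0

    def __post_init__(self):
        modes = tuple((float(m), float(s), float(w)) for m, s, w in self.modes)
        if not 2 <= len(modes) <= 6:
            raise ValidationError("need between 2 and 6 modes")
        for m, s, w in modes:
            if not 0 <= m <= 255:
                raise ValidationError(f"mode mean {m} outside [0, 255]")
            if s <= 0 or w <= 0:
                raise ValidationError("mode sd and weight must be positive")
        if abs(sum(w for _, _, w in modes) - 1.0) > 1e-9:
            raise ValidationError("mode weights must sum to 1")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValidationError("image shape must be 2-D and non-empty")
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "shape", (int(self.shape[0]), int(self.shape[1])))

    @property
    def means(self) -> tuple:
        return tuple(m for m, _, _ in self.modes)

    def background_index(self) -> int:
        if self.background is None:
            return int(np.argmax([w for _, _, w in self.modes]))
        means = np.asarray(self.means)
        return int(np.argmin(np.abs(means - self.background)))

    def to_dict(self) -> dict:
        return {
            "modes": [list(m) for m in self.modes],
            "shape": list(self.shape),
            "background": self.background,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(modes=tuple(tuple(m) for m in d["modes"]),
                   shape=tuple(d["shape"]), background=d.get("background"),
                   seed=int(d.get("seed", 0)))


def _mode_level_probs(mean: float, sd: float,
                      levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Truncated-to-[0, L-1] rounded Gaussian as a discrete distribution."""
    edges = np.arange(levels + 1) - 0.5
    edges[0], edges[-1] = -np.inf, np.inf  # truncate: all mass inside [0, L-1]
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    p = np.diff(cdf)
    return p / p.sum()


def generate_histogram(spec: MixtureSpec) -> Histogram:
    """Analytic mixture density discretized to 256 levels."""
    p = np.zeros(DEFAULT_LEVELS)
    for mean, sd, weight in spec.modes:
        p += weight * _mode_level_probs(mean, sd)
    return Histogram.from_probabilities(p, n_total=spec.shape[0] * spec.shape[1])


def _mode_pixel_counts(spec: MixtureSpec) -> np.ndarray:
    """Integer pixel counts per mode matching the weights (largest remainder)."""
    total = spec.shape[0] * spec.shape[1]
    raw = np.array([w for _, _, w in spec.modes]) * total
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: total - counts.sum()]:
        counts[i] += 1
    return counts


def _quantile_values(probs: np.ndarray, n: int, rng) -> np.ndarray:
    """n gray values by stratified inverse-CDF sampling, shuffled."""
    cdf = np.cumsum(probs)
    u = (np.arange(n) + 0.5) / n
    vals = np.searchsorted(cdf, u).clip(0, probs.size - 1)
    return rng.permutation(vals)


def generate_image(spec: MixtureSpec) -> np.ndarray:
    """Render the mixture as elliptical blobs over a background region."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    bg = spec.background_index()
    counts = _mode_pixel_counts(spec)

    # one elliptical blob per non-background mode: pixels are claimed in
    # order of elliptical distance, so each region is connected and smooth
    labels = np.full(rows * cols, bg, dtype=int)
    taken = np.zeros(rows * cols, dtype=bool)
    order = [j for j in range(len(spec.modes)) if j != bg]
    for j in order:
        cy = rng.uniform(0.2, 0.8) * rows
        cx = rng.uniform(0.2, 0.8) * cols
        aspect = rng.uniform(0.6, 1.6)
        angle = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = np.cos(angle) * dx + np.sin(angle) * dy
        v = -np.sin(angle) * dx + np.cos(angle) * dy
        r = (u * aspect) ** 2 + (v / aspect) ** 2
        r = r.ravel()
        r[taken] = np.inf
        idx = np.argpartition(r, counts[j] - 1)[: counts[j]]
        labels[idx] = j
        taken[idx] = True

    img = np.empty(rows * cols, dtype=np.int64)
    for j, (mean, sd, _) in enumerate(spec.modes):
        mask = labels == j
        n = int(mask.sum())
        if n:
            img[mask] = _quantile_values(_mode_level_probs(mean, sd), n, rng)
    return img.reshape(rows, cols)


@dataclass
class FixtureCase:
    """One generated image with spec, histogram and cached oracle optima."""

    spec: MixtureSpec
    image: np.ndarray
    histogram: Histogram = field(repr=False)
    oracle: dict = field(default_factory=dict)  # (objective, k) -> (th, fitness)
    well_separated: bool = False


def _is_well_separated(spec: MixtureSpec, factor: float = 2.5) -> bool:
    """Equal weights and consecutive means at least factor*(sd_i+sd_j) apart."""
    weights = [w for _, _, w in spec.modes]
    if max(weights) - min(weights) > 1e-9:
        return False
    modes = sorted(spec.modes)
    for (m1, s1, _), (m2, s2, _) in zip(modes, modes[1:]):
        if m2 - m1 < factor * (s1 + s2):
            return False
    return True


def _suite_spec(i: int, rng) -> MixtureSpec:
    n_modes = [2, 3, 4][i % 3]
    lo, hi = 35.0, 220.0
    base = np.linspace(lo, hi, n_modes)
    jitter = rng.uniform(-8, 8, n_modes)
    means = np.clip(base + jitter, 5, 250)
    max_sd = {2: 14.0, 3: 12.0, 4: 9.0}[n_modes]
    sds = rng.uniform(6.0, max_sd, n_modes)
    if i % 4 == 3:  # a minority of unequal-weight cases
        w = rng.dirichlet(np.full(n_modes, 6.0))
    else:
        w = np.full(n_modes, 1.0 / n_modes)
    w = w / w.sum()
    modes = tuple((float(m), float(s), float(x)) for m, s, x in zip(means, sds, w))
    return MixtureSpec(modes=modes, shape=(128, 128),
                       seed=int(rng.integers(0, 2 ** 31 - 1)))


def fixture_suite(n: int = 20, seed: int = 0, oracle_ks=(1, 2, 3)) -> list[FixtureCase]:
    """Reproducible corpus of *n* fixtures with cached oracle answers.

    Covers 2-, 3- and 4-mode mixtures; oracle optima are computed on each
    sampled image's histogram (the histogram the optimizers see).
    """
    if n < 1:
        raise ValidationError("need n >= 1 fixtures")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        spec = _suite_spec(i, rng)
        img = generate_image(spec)
        hist = compute_histogram(img)
        oracle = {}
        for objective in OBJECTIVES:
            for k in oracle_ks:
                oracle[(objective, k)] = exhaustive_optimal(hist, k, objective)
        cases.append(FixtureCase(spec=spec, image=img, histogram=hist,
                                 oracle=oracle,
                                 well_separated=_is_well_separated(spec)))
    return cases


def save_fixture(case: FixtureCase, directory, name: str) -> None:
    """Write a fixture as PNG plus a JSON sidecar (spec + oracle answers)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_gray_image(case.image, directory / f"{name}.png")
    sidecar = {
        "spec": case.spec.to_dict(),
        "well_separated": case.well_separated,
        "oracle": {
            f"{obj}:{k}": {"thresholds": list(th), "fitness": fit}
            for (obj, k), (th, fit) in case.oracle.items()
        },
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def load_fixture(directory, name: str) -> FixtureCase:
    directory = Path(directory)
    img = load_gray_image(directory / f"{name}.png")
    sidecar = json.loads((directory / f"{name}.json").read_text())
    oracle = {}
    for key, val in sidecar["oracle"].items():
        obj, k = key.split(":")
        oracle[(obj, int(k))] = (tuple(val["thresholds"]), float(val["fitness"]))
    return FixtureCase(spec=MixtureSpec.from_dict(sidecar["spec"]), image=img,
                       histogram=compute_histogram(img), oracle=oracle,
                       well_separated=bool(sidecar["well_separated"]))
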