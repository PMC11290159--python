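"""Model/results interface for multilevel thresholding.

:class:`MultilevelThreshold` treats the k threshold values as parameters of
a piecewise-constant intensity model fitted to an image (or directly to a
histogram) by maximizing either the Otsu between-class variance or the
Kapur entropy criterion. ``fit()`` runs an optimizer — the improved black
widow algorithm by default, the plain BWOA, or exact exhaustive search for
k <= 3 — and returns a :class:`ThresholdResults` carrying the thresholds,
the attained fitness, per-class statistics, the convergence trace, and
quality metrics of the implied reconstruction.

Example
-------
>>> from thermothresh import MultilevelThreshold, synthetic
>>> spec = synthetic.MixtureSpec(modes=((80, 12, 0.5), (180, 12, 0.5)))
>>> img = synthetic.generate_image(spec)
>>> res = MultilevelThreshold(img, n_thresholds=2, objective="otsu").fit(seed=0)
>>> res.thresholds                                        # doctest: +SKIP
(104, 158)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import metrics as _metrics
from .bwoa import BWOAConfig, ConvergenceTrace, bwoa_optimize
from .ibwoa import DEFAULT_QOBL_JUMP_RATE, LevyConfig, ibwoa_optimize
from .image import (Histogram, ValidationError, apply_thresholds,
                    as_gray_image, compute_histogram, load_gray_image)
from .objectives import (ObjectiveResult, OBJECTIVES, evaluate,
                         exhaustive_optimal, make_batch_evaluator)

METHODS = ("ibwoa", "bwoa", "exhaustive")


class MultilevelThreshold:
    """Multilevel thresholding model for a gray image or histogram.

    Parameters
    ----------
    image : array-like, optional
        2-D integer gray image. Optional if *histogram* is given, but then
        image-dependent results (segmentation, quality metrics) are
        unavailable.
    histogram : Histogram, optional
        Used directly when given; otherwise computed from the image.
    n_thresholds : int
        Number of thresholds k (classes = k + 1).
    objective : {"otsu", "kapur"}
    """

    def __init__(self, image=None, histogram: Optional[Histogram] = None,
                 n_thresholds: int = 2, objective: str = "otsu"):
        if image is None and histogram is None:
            raise ValidationError("provide an image or a histogram")
        if objective not in OBJECTIVES:
            raise ValidationError(f"objective must be one of {OBJECTIVES}")
        if not 1 <= n_thresholds <= 8:
            raise ValidationError("n_thresholds must be in 1..8")
        self.image = None if image is None else as_gray_image(image)
        self.histogram = histogram if histogram is not None else compute_histogram(self.image)
        self.n_thresholds = int(n_thresholds)
        self.objective = objective

    @classmethod
    def from_image_file(cls, path, n_thresholds: int = 2,
                        objective: str = "otsu") -> "MultilevelThreshold":
        return cls(image=load_gray_image(path), n_thresholds=n_thresholds,
                   objective=objective)

    def _config(self, seed, config: Optional[BWOAConfig]) -> BWOAConfig:
        if config is not None:
            if config.dim != self.n_thresholds:
                raise ValidationError("config.dim must equal n_thresholds")
            if seed is not None:
                config.seed = seed
            return config
        return BWOAConfig(dim=self.n_thresholds, lower=0.0,
                          upper=self.histogram.levels - 2, seed=seed)

    def fit(self, method: str = "ibwoa", seed: Optional[int] = None,
            config: Optional[BWOAConfig] = None,
            levy: Optional[LevyConfig] = None,
            qobl_jump_rate: float = DEFAULT_QOBL_JUMP_RATE) -> "ThresholdResults":
        """Estimate the thresholds; returns a results object."""
        if method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}")
        if method == "exhaustive":
            th, fitness = exhaustive_optimal(self.histogram, self.n_thresholds,
                                             self.objective)
            trace = None
        else:
            cfg = self._config(seed, config)
            fitness_fn = make_batch_evaluator(self.histogram, self.objective)
            if method == "ibwoa":
                best, trace = ibwoa_optimize(cfg, fitness_fn, levy=levy,
                                             qobl_jump_rate=qobl_jump_rate)
            else:
                best, trace = bwoa_optimize(cfg, fitness_fn)
            from .objectives import decode_positions

            th = tuple(int(t) for t in decode_positions(
                best.position, self.histogram.levels)[0])
            fitness = float(best.fitness)
        detail = evaluate(self.histogram, _unique_sorted(th), self.objective)
        return ThresholdResults(model=self, method=method,
                                thresholds=tuple(int(t) for t in th),
                                fitness=float(fitness), detail=detail,
                                trace=trace, seed=seed)


def _unique_sorted(th) -> tuple:
    return tuple(sorted(set(int(t) for t in th)))


@dataclass
class ThresholdResults:
    """Fitted thresholds plus diagnostics.

    ``thresholds`` is the decoded (sorted) integer vector; duplicates from
    the continuous search, if any, are collapsed for segmentation.
    """

    model: MultilevelThreshold
    method: str
    thresholds: tuple
    fitness: float
    detail: ObjectiveResult
    trace: Optional[ConvergenceTrace] = None
    seed: Optional[int] = None
    _quality: Optional[_metrics.QualityReport] = field(default=None, repr=False)

    def segmented(self, mode: str = "class-mean") -> np.ndarray:
        """Segment the model image with the fitted thresholds."""
        if self.model.image is None:
            raise ValidationError("model was built from a histogram; no image to segment")
        return apply_thresholds(self.model.image, _unique_sorted(self.thresholds),
                                mode=mode)

    def quality(self, mode: str = "class-mean") -> _metrics.QualityReport:
        """RMSE/PSNR/SSIM/FSIM of the reconstruction vs. the original."""
        if self._quality is None or mode != "class-mean":
            report = _metrics.quality_report(self.model.image, self.segmented(mode))
            if mode != "class-mean":
                return report
            self._quality = report
        return self._quality

    def summary(self) -> str:
        """Plain-text summary table."""
        m = self.model
        lines = [
            "Multilevel Threshold Results",
            "=" * 44,
            f"{'Objective:':<22}{m.objective}",
            f"{'Method:':<22}{self.method}",
            f"{'Thresholds (k):':<22}{m.n_thresholds}",
            f"{'Fitted thresholds:':<22}{list(self.thresholds)}",
            f"{'Fitness:':<22}{self.fitness:.6f}",
        ]
        if self.seed is not None:
            lines.append(f"{'Seed:':<22}{self.seed}")
        if self.trace is not None:
            lines.append(f"{'Iterations:':<22}{len(self.trace)}")
        lines.append("-" * 44)
        stat = "mean" if m.objective == "otsu" else "entropy"
        lines.append(f"{'class':>6}{'mass':>12}{stat:>12}")
        for j, (w, v) in enumerate(self.detail.per_class):
            flag = "  (empty)" if self.detail.empty[j] else ""
            lines.append(f"{j:>6}{w:>12.4f}{v:>12.4f}{flag}")
        if m.image is not None:
            q = self.quality()
            lines.append("-" * 44)
            psnr_s = "inf" if np.isinf(q.psnr) else f"{q.psnr:.4f}"
            lines.append(f"{'RMSE:':<22}{q.rmse:.4f}")
            lines.append(f"{'PSNR (dB):':<22}{psnr_s}")
            lines.append(f"{'SSIM:':<22}{q.ssim:.4f}")
            lines.append(f"{'FSIM:':<22}{q.fsim:.4f}")
        return "\n".join(lines)
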