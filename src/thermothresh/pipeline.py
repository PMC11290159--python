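"""Experiment runner: single segmentations and repeated-seed studies.

A *study* executes ``runs`` independent fits with seeds ``seed + 0 ...
seed + runs - 1`` (documented so paired comparisons between algorithms are
honest: run i of each algorithm shares a seed), aggregates mean/std of
fitness and quality metrics, and — for k <= 3 — flags whether each run hit
the exhaustive-oracle optimum (|fitness difference| <= 1e-9).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bwoa import BWOAConfig
from .ibwoa import DEFAULT_QOBL_JUMP_RATE, LevyConfig
from .image import ValidationError, save_gray_image
from .model import METHODS, MultilevelThreshold
from .objectives import exhaustive_optimal
from .synthetic import FixtureCase

logger = logging.getLogger("thermothresh")

ORACLE_TOL = 1e-9


@dataclass
class RunConfig:
    """Configuration of a segmentation run or study."""

    image: np.ndarray | None = None
    image_path: str | None = None
    objective: str = "otsu"
    k: int = 2
    algorithm: str = "ibwoa"
    runs: int = 35
    seed: int = 0
    n_pop: int = 50
    max_iter: int = 350
    procreate_rate: float = 0.8
    cannibalism_rate: float = 0.5
    mutation_rate: float = 0.4
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    qobl_jump_rate: float = DEFAULT_QOBL_JUMP_RATE
    output_dir: str | None = None

    def model(self) -> MultilevelThreshold:
        if self.image is not None:
            return MultilevelThreshold(self.image, n_thresholds=self.k,
                                       objective=self.objective)
        if self.image_path is not None:
            return MultilevelThreshold.from_image_file(
                self.image_path, n_thresholds=self.k, objective=self.objective)
        raise ValidationError("run config needs an image or an image path")

    def bwoa_config(self, seed: int) -> BWOAConfig:
        return BWOAConfig(dim=self.k, lower=0.0, upper=254.0, n_pop=self.n_pop,
                          max_iter=self.max_iter,
                          procreate_rate=self.procreate_rate,
                          cannibalism_rate=self.cannibalism_rate,
                          mutation_rate=self.mutation_rate, seed=seed)

    def levy(self) -> LevyConfig:
        return LevyConfig(beta=self.levy_beta, scale=self.levy_scale)


def _fit_once(cfg: RunConfig, model: MultilevelThreshold, seed: int):
    if cfg.algorithm not in METHODS:
        raise ValidationError(f"algorithm must be one of {METHODS}")
    if cfg.algorithm == "exhaustive":
        return model.fit(method="exhaustive")
    return model.fit(method=cfg.algorithm, config=cfg.bwoa_config(seed),
                     seed=seed, levy=cfg.levy(),
                     qobl_jump_rate=cfg.qobl_jump_rate)


def run_segment(cfg: RunConfig):
    """One segmentation; optionally writes PNG + JSON report + CSV trace.

    Returns ``(results, quality_report)``.
    """
    model = cfg.model()
    res = _fit_once(cfg, model, cfg.seed)
    quality = res.quality() if model.image is not None else None
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{cfg.objective}_k{cfg.k}_{cfg.algorithm}"
        save_gray_image(res.segmented("class-mean"), out / f"{stem}.png")
        report = {
            "objective": cfg.objective,
            "k": cfg.k,
            "algorithm": cfg.algorithm,
            "seed": cfg.seed,
            "thresholds": list(res.thresholds),
            "fitness": res.fitness,
        }
        if quality is not None:
            report.update(quality.as_row())
        (out / f"{stem}.json").write_text(json.dumps(report, indent=1, default=float))
        if res.trace is not None:
            res.trace.to_csv(out / f"{stem}_trace.csv")
    logger.info("segment %s k=%d %s: thresholds=%s fitness=%.6f",
                cfg.objective, cfg.k, cfg.algorithm, res.thresholds, res.fitness)
    return res, quality


@dataclass
class StudyReport:
    """Per-run rows plus the mean/std aggregate of a repeated-seed study."""

    per_run: pd.DataFrame
    summary: pd.Series
    oracle_fitness: Optional[float] = None
    traces: list = field(default_factory=list, repr=False)

    @property
    def hit_rate(self) -> Optional[float]:
        if "oracle_hit" not in self.per_run:
            return None
        return float(self.per_run["oracle_hit"].mean())


def run_study(cfg: RunConfig, with_quality: bool = True) -> StudyReport:
    """``cfg.runs`` independent fits with seeds ``seed..seed+runs-1``."""
    if cfg.runs < 1:
        raise ValidationError("need at least one run")
    model = cfg.model()
    oracle_fitness = None
    if cfg.k <= 3:
        _, oracle_fitness = exhaustive_optimal(model.histogram, cfg.k, cfg.objective)
    rows, traces = [], []
    for i in range(cfg.runs):
        seed = cfg.seed + i
        res = _fit_once(cfg, model, seed)
        row = {"run": i, "seed": seed, "fitness": res.fitness,
               "thresholds": list(res.thresholds)}
        if oracle_fitness is not None:
            row["oracle_hit"] = bool(abs(res.fitness - oracle_fitness) <= ORACLE_TOL)
        if with_quality and model.image is not None:
            row.update(res.quality().as_row())
        rows.append(row)
        traces.append(res.trace)
    per_run = pd.DataFrame(rows)
    numeric = per_run.select_dtypes(include=[np.number, bool]).drop(columns=["run", "seed"])
    summary = pd.concat({"mean": numeric.mean(), "std": numeric.std(ddof=0)})
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"study_{cfg.objective}_k{cfg.k}_{cfg.algorithm}"
        per_run.to_csv(out / f"{stem}.csv", index=False)
        summary.to_csv(out / f"{stem}_summary.csv")
    return StudyReport(per_run=per_run, summary=summary,
                       oracle_fitness=oracle_fitness, traces=traces)


def suite_hit_rates(cases: Sequence[FixtureCase], k: int, objective: str,
                    algorithm: str, seeds: Sequence[int],
                    n_pop: int = 50, max_iter: int = 350,
                    collect_traces: bool = False) -> dict:
    """Oracle hit rates of a metaheuristic over a fixture suite.

    For every fixture and every seed, fits k thresholds and tests
    ``|fitness - oracle| <= 1e-9`` against the suite's cached exhaustive
    optimum. Returns per-case hit fractions, the pooled rate, and
    (optionally) all convergence traces for elitism audits.
    """
    per_case = []
    traces = []
    for case in cases:
        oracle_fit = case.oracle[(objective, k)][1]
        cfg = RunConfig(image=case.image, objective=objective, k=k,
                        algorithm=algorithm, n_pop=n_pop, max_iter=max_iter)
        model = MultilevelThreshold(histogram=case.histogram, n_thresholds=k,
                                    objective=objective)
        hits = 0
        for seed in seeds:
            res = _fit_once(cfg, model, int(seed))
            hits += abs(res.fitness - oracle_fit) <= ORACLE_TOL
            if collect_traces:
                traces.append(res.trace)
        per_case.append(hits / len(seeds))
    out = {"per_case": per_case, "rate": float(np.mean(per_case)),
           "n_runs": len(per_case) * len(seeds)}
    if collect_traces:
        out["traces"] = traces
    return out
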