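import numpy as np
import pytest
from scipy.special import gamma as sp_gamma
from scipy.stats import kurtosis

from thermothresh import (BWOAConfig, LevyConfig, SearchBounds, bwoa_optimize,
                          ibwoa_optimize, levy_procreate, levy_sigma,
                          levy_step, obl, procreate, qobl)
from thermothresh.ibwoa import _levy_steps
from thermothresh.image import ValidationError

from test_bwoa import sphere


def mantegna_sigma_reference(beta: float) -> float:
    """Independent evaluation of the Mantegna scale via scipy's gamma."""
    num = sp_gamma(1 + beta) * np.sin(np.pi * beta / 2)
    den = sp_gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return float((num / den) ** (1 / beta))


class TestLevy:
    def test_sigma_at_default_beta(self):
        assert levy_sigma(1.5) == pytest.approx(0.6966, abs=1e-4)

    @pytest.mark.parametrize("beta", [1.1, 1.3, 1.5, 1.7, 1.9])
    def test_sigma_matches_independent_evaluation(self, beta):
        assert levy_sigma(beta) == pytest.approx(
            mantegna_sigma_reference(beta), abs=1e-12)

    def test_sigma_zero_at_beta_two(self):
        # sin(pi) evaluates to ~1e-16, so the 1/beta root leaves ~1e-8
        assert levy_sigma(2.0) == pytest.approx(0.0, abs=1e-6)

    def test_sigma_finite_positive_on_domain(self):
        for beta in np.linspace(1.0, 1.99, 25):
            s = levy_sigma(beta)
            assert np.isfinite(s) and s > 0

    def test_sigma_outside_domain_rejected(self):
        with pytest.raises(ValidationError):
            levy_sigma(0.9)
        with pytest.raises(ValidationError):
            LevyConfig(beta=2.5)

    def test_zero_scale_gives_zero_step(self):
        assert levy_step(LevyConfig(scale=0.0), np.random.default_rng(0)) == 0.0

    def test_steps_are_heavy_tailed(self):
        rng = np.random.default_rng(42)
        steps = _levy_steps((100_000,), LevyConfig(), rng)
        # excess kurtosis far above the Gaussian's 0
        assert kurtosis(steps) > 10


class TestLevyProcreate:
    def test_zero_scale_identical_to_plain_procreate(self):
        x1, x2 = np.array([1.0, 5.0]), np.array([4.0, 2.0])
        kids_a = procreate(x1, x2, 4, np.random.default_rng(8))
        kids_b = levy_procreate(x1, x2, LevyConfig(scale=0.0), 4,
                                np.random.default_rng(8))
        for a, b in zip(kids_a, kids_b):
            assert np.array_equal(a, b)

    def test_pair_sum_conserved_before_clipping(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=4), rng.normal(size=4)
        kids = levy_procreate(x1, x2, LevyConfig(), 6, rng)
        for a, b in zip(kids[:3], kids[3:]):
            assert np.allclose(a + b, x1 + x2, atol=1e-12)

    def test_bounded_offspring_stay_in_box(self):
        bounds = SearchBounds(np.zeros(3), np.full(3, 10.0))
        rng = np.random.default_rng(5)
        x1 = rng.uniform(0, 10, 3)
        x2 = rng.uniform(0, 10, 3)
        kids = levy_procreate(x1, x2, LevyConfig(scale=0.5), 8, rng, bounds)
        for kid in kids:
            assert np.all(kid >= 0) and np.all(kid <= 10)


class TestOpposition:
    def test_obl_arithmetic(self):
        b = SearchBounds(np.array([0.0]), np.array([10.0]))
        assert obl(np.array([3.0]), b)[0] == 7.0

    def test_obl_involution_and_midpoint_fixed_point(self):
        rng = np.random.default_rng(1)
        lo, hi = rng.uniform(-5, 0, 6), rng.uniform(1, 5, 6)
        b = SearchBounds(lo, hi)
        for _ in range(100):
            x = rng.uniform(lo, hi)
            assert np.allclose(obl(obl(x, b), b), x, atol=1e-12)
        mid = (lo + hi) / 2
        assert np.allclose(obl(mid, b), mid, atol=1e-12)

    def test_qobl_lies_between_midpoint_and_opposite(self):
        rng = np.random.default_rng(2)
        lo, hi = np.zeros(4), np.full(4, 10.0)
        b = SearchBounds(lo, hi)
        mid = (lo + hi) / 2
        for _ in range(500):
            x = rng.uniform(lo, hi)
            q = qobl(x, b, rng)
            xo = obl(x, b)
            assert np.all(q >= np.minimum(mid, xo) - 1e-12)
            assert np.all(q <= np.maximum(mid, xo) + 1e-12)

    def test_qobl_of_midpoint_is_midpoint(self):
        b = SearchBounds(np.zeros(3), np.full(3, 8.0))
        mid = np.full(3, 4.0)
        assert np.allclose(qobl(mid, b, np.random.default_rng(0)), mid)

    def test_qobl_reproducible_from_seed(self):
        b = SearchBounds(np.zeros(2), np.ones(2))
        x = np.array([0.2, 0.9])
        a = qobl(x, b, np.random.default_rng(77))
        c = qobl(x, b, np.random.default_rng(77))
        assert np.array_equal(a, c)


class TestIBWOAOptimize:
    def test_disabled_improvements_reduce_to_bwoa(self):
        cfg = BWOAConfig(dim=3, lower=-5, upper=5, seed=13, max_iter=60)
        fn = sphere([1, -2, 0.5])
        best_b, trace_b = bwoa_optimize(cfg, fn)
        best_i, trace_i = ibwoa_optimize(cfg, fn, levy=LevyConfig(scale=0.0),
                                         qobl_jump_rate=0.0)
        assert np.array_equal(trace_b.best_fitness, trace_i.best_fitness)
        assert np.array_equal(trace_b.mean_fitness, trace_i.mean_fitness)
        assert np.array_equal(best_b.position, best_i.position)

    def test_sphere_optimum_recovered(self):
        target = [2.5, -3.5]
        for seed in range(5):
            cfg = BWOAConfig(dim=2, lower=-10, upper=10, seed=seed, max_iter=200)
            best, _ = ibwoa_optimize(cfg, sphere(target))
            assert np.allclose(best.position, target, atol=1e-1)

    def test_not_worse_than_bwoa_on_thresholding_paired(self, two_mode_case):
        """Paired over seeds on a Kapur thresholding problem, the improved
        variant's final fitness is at least the baseline's (median)."""
        from thermothresh.objectives import make_batch_evaluator

        _, _, hist = two_mode_case
        fn = make_batch_evaluator(hist, "kapur")
        deltas = []
        for seed in range(20):
            cfg = BWOAConfig(dim=3, lower=0, upper=254, seed=seed, max_iter=150)
            best_b, _ = bwoa_optimize(cfg, fn)
            best_i, _ = ibwoa_optimize(cfg, fn)
            deltas.append(best_i.fitness - best_b.fitness)
        assert np.median(deltas) >= 0

    def test_injected_optimum_survives(self):
        target = np.array([0.5, 0.5])
        cfg = BWOAConfig(dim=2, lower=0, upper=1, seed=0, max_iter=10)
        best, _ = ibwoa_optimize(cfg, sphere(target), initial_positions=target)
        assert best.fitness == 0.0

    def test_trace_monotone(self):
        cfg = BWOAConfig(dim=2, lower=-5, upper=5, seed=6, max_iter=80)
        _, trace = ibwoa_optimize(cfg, sphere([0, 0]))
        assert np.all(np.diff(trace.best_fitness) >= 0)

    def test_bad_jump_rate_rejected(self):
        cfg = BWOAConfig(dim=2, lower=0, upper=1)
        with pytest.raises(ValidationError):
            ibwoa_optimize(cfg, sphere([0, 0]), qobl_jump_rate=1.5)


def test_config_loading_from_toml(tmp_path):
    from thermothresh.ibwoa import load_config

    path = tmp_path / "run.toml"
    path.write_text(
        "dim = 3\nlower = 0.0\nupper = 254.0\nn_pop = 24\nmax_iter = 99\n"
        "[levy]\nbeta = 1.3\nscale = 0.02\n"
        "[qobl]\njump_rate = 0.4\n")
    cfg, levy, rate = load_config(path)
    assert (cfg.dim, cfg.n_pop, cfg.max_iter) == (3, 24, 99)
    assert (levy.beta, levy.scale) == (1.3, 0.02)
    assert rate == 0.4


def test_config_defaults_when_sections_missing(tmp_path):
    from thermothresh.ibwoa import load_config

    path = tmp_path / "run.toml"
    path.write_text("dim = 2\nlower = 0.0\nupper = 10.0\n")
    cfg, levy, rate = load_config(path)
    assert cfg.n_pop == 50 and cfg.max_iter == 350
    assert levy.beta == 1.5 and levy.scale == 0.01
    assert rate == 0.3
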