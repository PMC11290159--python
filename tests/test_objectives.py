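import itertools

import numpy as np
import pytest
from scipy.stats import entropy as shannon_entropy

from thermothresh import (Histogram, class_statistics, exhaustive_optimal,
                          kapur_fitness, otsu_fitness)
from thermothresh.objectives import (CapabilityError, decode_positions,
                                     make_batch_evaluator)

from conftest import random_histogram


def point_masses(levels_and_weights, levels=256):
    p = np.zeros(levels)
    for level, w in levels_and_weights:
        p[level] = w
    return Histogram.from_probabilities(p)


class TestClassStatistics:
    def test_two_point_masses(self):
        h = point_masses([(0, 0.5), (255, 0.5)])
        stats = class_statistics(h, [128])
        assert stats[0] == pytest.approx((0.5, 0.0))
        assert stats[1] == pytest.approx((0.5, 255.0))

    def test_uniform_split(self):
        h = Histogram.from_probabilities(np.ones(256))
        stats = class_statistics(h, [127])
        assert stats[0][0] == pytest.approx(0.5, abs=1e-12)
        assert stats[0][1] == pytest.approx(63.5, abs=1e-9)
        assert stats[1][1] == pytest.approx(191.5, abs=1e-9)

    def test_empty_class_flagged(self):
        h = point_masses([(10, 1.0)])
        res = otsu_fitness(h, [200])
        assert res.per_class[0][0] == pytest.approx(1.0)
        assert res.empty == (False, True)


class TestOtsu:
    def test_single_point_mass_is_zero(self):
        h = point_masses([(42, 1.0)])
        assert otsu_fitness(h, [100]).fitness == pytest.approx(0.0, abs=1e-12)

    def test_two_point_masses_hand_value(self):
        h = point_masses([(0, 0.5), (255, 0.5)])
        # 0.5*(0-127.5)^2 + 0.5*(255-127.5)^2
        assert otsu_fitness(h, [128]).fitness == pytest.approx(16256.25, abs=1e-9)

    def test_uniform_hand_value(self):
        h = Histogram.from_probabilities(np.ones(256))
        # 0.5*64^2 + 0.5*64^2
        assert otsu_fitness(h, [127]).fitness == pytest.approx(4096.0, rel=1e-12)

    def test_variance_decomposition(self):
        """sigma_B^2 + pooled within-class variance == total variance."""
        rng = np.random.default_rng(12345)
        levels = np.arange(256)
        for _ in range(300):
            h = random_histogram(rng)
            k = int(rng.integers(1, 5))
            th = np.sort(rng.choice(255, size=k, replace=False))
            res = otsu_fitness(h, th)
            mu_t = float(levels @ h.p)
            total = float(((levels - mu_t) ** 2) @ h.p)
            edges = np.concatenate(([0], th + 1, [256]))
            within = 0.0
            for lo, hi in zip(edges[:-1], edges[1:]):
                w = h.p[lo:hi].sum()
                if w > 0:
                    mu = (levels[lo:hi] @ h.p[lo:hi]) / w
                    within += ((levels[lo:hi] - mu) ** 2) @ h.p[lo:hi]
            assert res.fitness + within == pytest.approx(total, abs=1e-9)

    def test_invariant_to_zero_probability_levels(self):
        h_small = point_masses([(10, 0.3), (20, 0.7)], levels=64)
        h_big = point_masses([(10, 0.3), (20, 0.7)], levels=256)
        assert otsu_fitness(h_small, [15]).fitness == pytest.approx(
            otsu_fitness(h_big, [15]).fitness, rel=1e-12)


class TestKapur:
    def test_point_mass_classes_have_zero_entropy(self):
        h = point_masses([(0, 0.5), (255, 0.5)])
        assert kapur_fitness(h, [0]).fitness == pytest.approx(0.0, abs=1e-12)

    def test_uniform_four_levels_hand_value(self):
        h = Histogram.from_probabilities(np.full(4, 0.25))
        # each class uniform over 2 levels: ln2 + ln2
        assert kapur_fitness(h, [1]).fitness == pytest.approx(
            2 * np.log(2), rel=1e-12)

    def test_empty_class_contributes_zero(self):
        h = point_masses([(10, 0.4), (20, 0.6)])
        with_empty = kapur_fitness(h, [30, 200]).fitness
        without = kapur_fitness(h, [30]).fitness
        assert with_empty == pytest.approx(without, rel=1e-12)

    def test_no_thresholds_equals_shannon_entropy(self):
        rng = np.random.default_rng(7)
        h = random_histogram(rng)
        assert kapur_fitness(h, []).fitness == pytest.approx(
            float(shannon_entropy(h.p)), rel=1e-10)

    def test_fitness_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            h = random_histogram(rng)
            th = np.sort(rng.choice(255, size=3, replace=False))
            assert kapur_fitness(h, th).fitness >= -1e-12


class TestExhaustiveOracle:
    def test_k1_matches_naive_scan(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            h = random_histogram(rng)
            th, fit = exhaustive_optimal(h, 1, "otsu")
            naive = max(range(255), key=lambda t: otsu_fitness(h, [t]).fitness)
            assert fit == otsu_fitness(h, [naive]).fitness
            assert otsu_fitness(h, th).fitness == fit

    @pytest.mark.parametrize("objective", ["otsu", "kapur"])
    @pytest.mark.parametrize("k", [2, 3])
    def test_small_alphabet_matches_brute_force(self, objective, k):
        """Full enumeration on a 24-level histogram, both objectives."""
        rng = np.random.default_rng(5)
        h = random_histogram(rng, levels=24)
        fn = otsu_fitness if objective == "otsu" else kapur_fitness
        best_th, best_fit = None, -np.inf
        for th in itertools.combinations(range(23), k):
            f = fn(h, th).fitness
            if f > best_fit:
                best_th, best_fit = th, f
        th, fit = exhaustive_optimal(h, k, objective)
        assert fit == pytest.approx(best_fit, abs=1e-12)
        assert th == best_th

    def test_lexicographic_tie_break(self):
        # all single thresholds separate {0} from {255} equally; pick 0
        h = point_masses([(0, 0.5), (255, 0.5)])
        th, fit = exhaustive_optimal(h, 1, "otsu")
        assert th == (0,)
        assert fit == pytest.approx(16256.25, abs=1e-9)

    def test_two_mode_threshold_lies_in_the_valley(self, two_mode_case):
        _, _, hist = two_mode_case
        th, _ = exhaustive_optimal(hist, 1, "otsu")
        assert 80 < th[0] < 180

    def test_cross_check_against_skimage_multiotsu(self, two_mode_case):
        from skimage.filters import threshold_multiotsu

        _, img, hist = two_mode_case
        sk = threshold_multiotsu(img.astype(np.uint8), classes=3,
                                 hist=(hist.counts, np.arange(256)))
        # skimage returns the last gray level of each lower class, which is
        # exactly the inclusive-upper threshold used here
        sk_fit = otsu_fitness(hist, tuple(int(t) for t in sk)).fitness
        _, fit = exhaustive_optimal(hist, 2, "otsu")
        assert sk_fit == pytest.approx(fit, rel=1e-9)

    def test_k4_raises_capability_error(self):
        h = point_masses([(0, 0.5), (255, 0.5)])
        with pytest.raises(CapabilityError):
            exhaustive_optimal(h, 4, "otsu")


class TestBatchEvaluator:
    def test_decode_clamps_rounds_sorts(self):
        out = decode_positions(np.array([[300.0, -5.2, 10.6]]))
        assert out.tolist() == [[0, 11, 254]]

    def test_matches_scalar_objectives_exactly(self):
        rng = np.random.default_rng(21)
        h = random_histogram(rng)
        for objective, fn in (("otsu", otsu_fitness), ("kapur", kapur_fitness)):
            batch = make_batch_evaluator(h, objective)
            pos = rng.uniform(0, 254, size=(40, 3))
            vals = batch(pos)
            for row, v in zip(pos, vals):
                th = np.unique(decode_positions(row[None, :])[0])
                assert fn(h, th).fitness == pytest.approx(v, abs=1e-10)
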