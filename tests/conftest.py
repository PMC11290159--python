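import numpy as np
import pytest

from thermothresh import Histogram, compute_histogram, synthetic


@pytest.fixture(scope="session")
def suite20():
    """The canonical 20-image synthetic corpus with cached oracle optima."""
    return synthetic.fixture_suite(20, seed=0)


@pytest.fixture(scope="session")
def two_mode_case():
    """Well-separated two-mode fixture (means 80/180, sd 12, equal weight)."""
    spec = synthetic.MixtureSpec(modes=((80.0, 12.0, 0.5), (180.0, 12.0, 0.5)),
                                 seed=7)
    img = synthetic.generate_image(spec)
    return spec, img, compute_histogram(img)


@pytest.fixture(scope="session")
def three_mode_case():
    spec = synthetic.MixtureSpec(
        modes=((60.0, 10.0, 1 / 3), (130.0, 10.0, 1 / 3), (200.0, 10.0, 1 / 3)),
        seed=11)
    img = synthetic.generate_image(spec)
    return spec, img, compute_histogram(img)


def random_histogram(rng, levels: int = 256, sparsity: float = 3.0) -> Histogram:
    """Random histogram with uneven mass (cubed uniforms concentrate it)."""
    p = rng.random(levels) ** sparsity
    return Histogram.from_probabilities(p)
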