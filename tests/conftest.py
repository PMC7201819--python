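import numpy as np
import pytest

from mieaclust import LabeledDataset, MixtureSpec, generate_mixture

TRUE_MEANS_3 = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 5.0]])


@pytest.fixture(scope="session")
def three_gaussians() -> LabeledDataset:
    """The seeded 3-cluster recovery fixture: tight, well-separated clusters."""
    spec = MixtureSpec(means=TRUE_MEANS_3, spreads=0.2, seed=42)
    return generate_mixture(spec, 300)


@pytest.fixture(scope="session")
def separable_toy() -> LabeledDataset:
    """Zero-spread 3-cluster mixture: every point sits exactly on its mean."""
    spec = MixtureSpec(means=TRUE_MEANS_3, spreads=0.0, seed=1)
    return generate_mixture(spec, 30)


@pytest.fixture(scope="session")
def overlapping_four() -> LabeledDataset:
    """4 overlapping clusters at the corners of a 6x6 square, sigma = 1."""
    spec = MixtureSpec(
        means=[[0, 0], [6, 0], [0, 6], [6, 6]], spreads=1.0, seed=7
    )
    return generate_mixture(spec, 400)
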