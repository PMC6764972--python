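import numpy as np
import pytest

from mgmix.dataset import MixedDataset, VariableSpec
from mgmix.simulate import gibbs_sample, make_ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_mixed():
    """Handmade 4-row dataset: two continuous, one binary, one 3-level."""
    specs = [
        VariableSpec("a", "continuous"),
        VariableSpec("b", "continuous"),
        VariableSpec("c", "categorical", ("no", "yes")),
        VariableSpec("d", "categorical", ("low", "mid", "high")),
    ]
    X = np.array([[0.1, 1.0], [-0.5, 2.0], [1.2, -1.0], [0.0, 0.5]])
    Y = np.array([[0, 0], [1, 2], [0, 1], [1, 0]])
    return MixedDataset(specs, X, Y, ["s1", "s2", "s3", "s4"])


def simulated_dataset(p=4, q=2, n=300, density=0.4, seed=0, standardize=False):
    truth = make_ground_truth(p, q, None, density, (0.2, 0.5), seed)
    d = gibbs_sample(truth, n, burn_in=200, thin=1, seed=seed + 1)
    if standardize:
        from mgmix.dataset import apply_transforms

        d = apply_transforms(d)
    return truth, d


@pytest.fixture
def small_sim():
    return simulated_dataset()
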