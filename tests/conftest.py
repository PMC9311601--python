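import numpy as np
import pytest

from morphsym.io import ModulePartition, load_analysis_config
from morphsym.procrustes import ShapeComponents, decompose_symmetry
from morphsym.synthetic import SyntheticParams, generate_dataset, make_scheme


@pytest.fixture(scope="session")
def fixture_config():
    """The shipped 33-landmark cephalothorax scheme + 7 hypotheses."""
    return load_analysis_config()


@pytest.fixture(scope="session")
def small_scheme():
    """12-landmark scheme: 5 bilateral pairs + 2 midline points."""
    return make_scheme(5, 2)


@pytest.fixture(scope="session")
def small_partition(small_scheme):
    """Two-module partition on the small scheme, pairs kept intact."""
    assign = {}
    for i, (left, right) in enumerate(small_scheme.pairs, start=1):
        label = "A" if i <= 2 else "B"
        assign[left] = label
        assign[right] = label
    assign[1] = "A"
    assign[2] = "B"
    return ModulePartition("developmental", assign)


@pytest.fixture(scope="session")
def small_components(small_scheme, small_partition):
    """Decomposed components of a small two-sex synthetic dataset."""
    params = SyntheticParams(n_female=14, n_male=12, seed=11)
    dataset, _ = generate_dataset(params, small_scheme, small_partition)
    return decompose_symmetry(dataset, small_scheme)


def bare_components(asymmetric, scheme, sex=None, symmetric=None):
    """A minimal ShapeComponents wrapper around given component arrays."""
    n = asymmetric.shape[0]
    k = scheme.n_landmarks
    return ShapeComponents(
        specimen_ids=[f"s{i}" for i in range(n)],
        sex=list(sex) if sex is not None else [None] * n,
        symmetric=symmetric if symmetric is not None else np.zeros((n, k, 2)),
        asymmetric=asymmetric,
        centroid_sizes=np.ones(n),
        grand_mean=np.zeros((k, 2)),
        scheme=scheme,
    )
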