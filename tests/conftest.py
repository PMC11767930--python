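import numpy as np
import pytest

from cmtfomics import CoupledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_dataset(tensor, matrix):
    """Wrap raw arrays in a labelled CoupledDataset."""
    ns, nb, nc = tensor.shape
    nv = matrix.shape[1]
    return CoupledDataset(
        tensor=tensor,
        matrix=matrix,
        sample_ids=[f"S{i}" for i in range(ns)],
        microbe_ids=[f"m{i}" for i in range(nb)],
        pathway_ids=[f"p{i}" for i in range(nc)],
        metabolite_ids=[f"v{i}" for i in range(nv)],
    )


@pytest.fixture
def small_random_data(rng):
    """A small unstructured coupled dataset."""
    return make_dataset(rng.standard_normal((4, 3, 2)), rng.standard_normal((4, 2)))


@pytest.fixture
def rank2_data(rng):
    """Noiseless rank-2 coupled data built from known standard-normal factors."""
    from cmtfomics import cp_reconstruct, matrix_reconstruct

    a, b, c, d = (rng.standard_normal((n, 2)) for n in (6, 5, 4, 3))
    return make_dataset(cp_reconstruct(a, b, c), matrix_reconstruct(a, d)), (a, b, c, d)
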