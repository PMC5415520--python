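import numpy as np
import pytest

from islepop import GenotypeDataset


@pytest.fixture
def toy_dataset():
    """Two populations, three loci (one candidate), one missing call."""
    calls = np.array([
        [[1, 1], [2, 3], [5, 5]],
        [[1, 2], [3, 3], [5, 6]],
        [[2, 2], [2, 3], [0, 0]],
        [[1, 1], [2, 2], [6, 6]],
        [[1, 2], [3, 2], [5, 6]],
        [[2, 2], [2, 2], [6, 5]],
    ], dtype=int)
    return GenotypeDataset(
        individuals=[f"i{k}" for k in range(6)],
        populations=["A", "A", "A", "B", "B", "B"],
        loci=["L1", "L2", "IGF1"],
        calls=calls,
        candidate_locus="IGF1",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n_per_pop=(8, 8), n_loci=4, n_alleles=5,
                   missing_rate=0.0, candidate=None):
    """Random multiallelic dataset for oracle comparisons."""
    pops, individuals, blocks = [], [], []
    for pi, n in enumerate(n_per_pop):
        calls = rng.integers(1, n_alleles + 1, size=(n, n_loci, 2))
        if missing_rate:
            miss = rng.random((n, n_loci)) < missing_rate
            calls[miss] = 0
        blocks.append(calls)
        pops += [f"P{pi + 1}"] * n
        individuals += [f"P{pi + 1}_{j}" for j in range(n)]
    loci = [f"L{k + 1}" for k in range(n_loci)]
    if candidate:
        loci[-1] = candidate
    return GenotypeDataset(
        individuals, pops, loci, np.concatenate(blocks), candidate
    )
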