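import numpy as np
import pytest
from hypothesis import settings

from scseg.depth_matrix import NORMALIZED, RAW, BinAnnotation, ReadDepthMatrix
from scseg.synthetic import SimParams, generate_truth, simulate_counts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_bins(m: int, chrom: str = "chr1", width: int = 100, offset: int = 0):
    return [
        BinAnnotation(chrom, i * width + 1, (i + 1) * width, offset + i)
        for i in range(m)
    ]


def make_matrix(values, kind: str = RAW, chrom: str = "chr1"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ReadDepthMatrix(values, make_bins(m, chrom), [f"c{j}" for j in range(n)], kind)


def make_pair(cn, depth: float = 100.0, chrom: str = "chr1"):
    """Noise-free raw/norm matrices realizing an exact integer CN matrix."""
    cn = np.asarray(cn, dtype=float)
    raw = make_matrix(cn / 2.0 * depth, RAW, chrom)
    norm = make_matrix(np.full_like(cn, depth), NORMALIZED, chrom)
    return raw, norm


def random_pair(rng: np.random.Generator, m: int, n: int):
    """Arbitrary positive matrices for oracle comparisons."""
    raw = make_matrix(rng.integers(0, 30, size=(m, n)).astype(float))
    norm = make_matrix(rng.uniform(0.5, 15.0, size=(m, n)), NORMALIZED)
    return raw, norm


@pytest.fixture(scope="session")
def default_truth():
    return generate_truth(SimParams(seed=1))


@pytest.fixture(scope="session")
def default_counts(default_truth):
    return simulate_counts(default_truth)
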