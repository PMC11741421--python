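import numpy as np
import pytest

from strainepi.containers import GeneMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_gene_matrix():
    """4 genes x 5 samples with a mix of zeros and positive abundances."""
    abd = np.array(
        [
            [0.0, 1.0, 2.0, 0.0, 3.0],
            [1.0, 0.0, 0.5, 0.2, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0],
            [2.0, 2.0, 2.0, 2.0, 2.0],
        ]
    )
    return GeneMatrix("sp", ["g1", "g2", "g3", "g4"], ["s1", "s2", "s3", "s4", "s5"], abd)


@pytest.fixture
def binary_metadata():
    return SampleMetadata(
        ["s1", "s2", "s3", "s4", "s5"],
        np.array([0.0, 1.0, 1.0, 0.0, 1.0]),
        None,
        "bernoulli",
    )


def separated_cloud_stats(rng, n_well=30, n_poor=10):
    """Two well-separated clouds of coverage statistics."""
    from strainepi.coverage import SampleCoverageStats

    stats = []
    for i in range(n_well):
        stats.append(
            SampleCoverageStats(f"w{i}", int(900 + rng.integers(-30, 30)), 5 + rng.normal(0, 0.2))
        )
    for i in range(n_poor):
        stats.append(
            SampleCoverageStats(f"p{i}", int(50 + rng.integers(-20, 20)), 1 + rng.normal(0, 0.2))
        )
    return stats
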