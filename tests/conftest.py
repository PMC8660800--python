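import numpy as np
import pandas as pd
import pytest

from decaykit import ChaseCountMatrix, ChaseSimConfig, simulate_chase


@pytest.fixture(scope="session")
def small_chase():
    """A small but realistic simulated chase: 200 genes, two conditions."""
    cfg = ChaseSimConfig(n_genes=200, library_depth=3e5, n_spikeins=20, seed=11)
    return simulate_chase(cfg)


@pytest.fixture()
def tiny_matrix():
    """Hand-built 3-gene / 1-spike-in matrix with exact expected ratios."""
    samples = pd.DataFrame(
        {
            "condition": ["c"] * 4,
            "replicate": [1] * 4,
            "time_h": [0.0, 1.0, 2.0, 3.0],
        },
        index=["s0", "s1", "s2", "s3"],
    )
    counts = pd.DataFrame(
        {
            "s0": [800, 100, 1000],
            "s1": [400, 100, 1000],
            "s2": [200, 100, 1000],
            "s3": [100, 100, 1000],
        },
        index=["fast", "flat", "ERCC-1"],
        dtype=np.int64,
    )
    return ChaseCountMatrix(counts=counts, samples=samples,
                            spikein_ids={"ERCC-1"})
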