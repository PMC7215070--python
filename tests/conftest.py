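import os

# small-matrix workload: BLAS thread pools only add spin overhead
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from ppistack import SimConfig, sample_negatives, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset shared by I/O, ensemble and pipeline tests."""
    cfg = SimConfig(
        n_proteins=60,
        length_range=(60, 150),
        n_positive_pairs=40,
        seed=7,
    )
    proteome, positives, annotations = simulate_dataset(cfg)
    negatives = sample_negatives(proteome, positives, ratio=1.0, rng_seed=7)
    return cfg, proteome, positives, negatives, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
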