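import numpy as np
import pytest

from fmriatt.benchmark import (
    interpretability_statistic,
    run_decoding_benchmark,
    run_transfer_benchmark,
)
from fmriatt.synth import SynthConfig, generate_dataset

REPLICATE_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def decoding_replicates():
    """Three full decoding-benchmark replicates (dataset, split, weights and
    batching all re-drawn per seed)."""
    return [run_decoding_benchmark(seed) for seed in REPLICATE_SEEDS]


@pytest.fixture(scope="session")
def median_replicate(decoding_replicates):
    """The replicate whose attention-model accuracy is the median."""
    accs = [r.attention_accuracy for r in decoding_replicates]
    return decoding_replicates[int(np.argsort(accs)[len(accs) // 2])]


@pytest.fixture(scope="session")
def transfer_replicates(decoding_replicates):
    return [
        run_transfer_benchmark(r.attention_model, r.plan, r.seed)
        for r in decoding_replicates
    ]


@pytest.fixture(scope="session")
def contrast_statistics(median_replicate):
    return interpretability_statistic(median_replicate)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 2-class dataset on an 8^3 grid for fast protocol tests."""
    cfg = SynthConfig(grid_shape=(8, 8, 8), n_classes=2, n_subjects=4,
                      noise_sd=0.0, amplitude=3.0, seed=11)
    instances, truth = generate_dataset(cfg)
    return cfg, instances, truth
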