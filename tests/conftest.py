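import numpy as np
import pytest

from sutpred import (
    LabeledFeatureMatrix,
    SynthConfig,
    encode_dataset,
    generate_pssms,
    generate_sequences,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small imbalanced synthetic sequence set with moderate signal."""
    cfg = SynthConfig(n_pos=40, n_neg=90, length_range=(50, 80),
                      signal=0.5, seed=101)
    seqs, labels = generate_sequences(cfg)
    profiles = generate_pssms(seqs, labels, cfg.signal, cfg.seed + 1)
    return seqs, labels, profiles


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    seqs, labels, profiles = small_dataset
    return encode_dataset(seqs, labels, ("d188",))


@pytest.fixture
def toy_matrix():
    """Hand-laid 2-D geometry: a tight majority cloud and a minority
    pair near it, so neighbour classifications are predictable."""
    X = np.array([
        [0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1], [0.05, 0.05],  # maj
        [0.06, 0.04],   # minority inside the cloud -> all-majority nbrs
        [5.0, 5.0], [5.1, 5.0], [5.0, 5.1],  # minority cluster, far away
    ])
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1])
    ids = [f"s{i}" for i in range(len(y))]
    return LabeledFeatureMatrix(X, y, ids, ["f1", "f2"])
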