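import numpy as np
import pytest

from mirhairpin import (
    FoldConfig,
    extract_features,
    generate_shuffled_negatives,
    generate_synthetic_hairpins,
)


@pytest.fixture(scope="session")
def fold_config():
    return FoldConfig()


def random_rna(rng, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The synthetic study conditions: 200 mutated hairpins (stem 12, loop 6,
    5% mutation) against 200 dinucleotide-shuffled negatives, with the full
    54-feature matrix (100-shuffle z-scores).

    Session-scoped: extraction is the expensive step and several tests share
    it read-only.
    """
    positives = generate_synthetic_hairpins(
        200, stem_length=12, loop_length=6, mutation_rate=0.05, seed=11
    )
    negatives = generate_shuffled_negatives(positives, seed=12)
    features = extract_features(positives + negatives, shuffles=100, seed=1)
    y = np.r_[np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    return features, y
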