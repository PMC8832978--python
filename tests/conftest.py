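import numpy as np
import pytest

from snarekit import (
    ClassifierConfig,
    DescriptorConfig,
    FeatureMatrix,
    SyntheticSpec,
    encode_dataset,
    generate_clusters,
    generate_dataset,
)

#: Small-sample learner settings: LightGBM's default min_child_samples=20
#: blocks splits on toy training sets.
SMALL_DATA = (("min_child_samples", 2),)


@pytest.fixture(scope="session")
def toy_dataset():
    """60 positives + 240 negatives, clearly separated composition."""
    return generate_dataset(
        SyntheticSpec(
            n_pos=60, n_neg=240, length_range=(30, 80),
            separation=0.8, seed=42,
        )
    )


@pytest.fixture(scope="session")
def toy_features(toy_dataset):
    return encode_dataset(toy_dataset, DescriptorConfig("ASDC"))


@pytest.fixture(scope="session")
def cluster_features():
    """Two well-separated 2-D Gaussian clouds (30 neg + 30 pos)."""
    matrix, labels = generate_clusters(
        n_per_class=30, dim=2,
        class_means=[[0.0, 0.0], [5.0, 5.0]],
        noise_sd=0.5, seed=7,
    )
    return matrix


@pytest.fixture
def small_classifier():
    return ClassifierConfig(seed=3, extra_params=SMALL_DATA)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    from snarekit.sequence_io import ALPHABET

    return "".join(rng.choice(list(ALPHABET), size=length))
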