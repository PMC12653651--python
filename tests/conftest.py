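import numpy as np
import pytest

from cropclr.data import generate_dataset, split_dataset
from cropclr.synthetic import SyntheticDatasetSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """3-class synthetic dataset spec at the smallest useful size."""
    return SyntheticDatasetSpec(n_classes=3, per_class_count=10,
                                image_size=64, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec, tmp_path_factory):
    """Generated 30-image dataset with a 70/15/15 stratified split."""
    out = tmp_path_factory.mktemp("smallds")
    manifest = generate_dataset(small_spec, out)
    return split_dataset(manifest, (0.70, 0.15, 0.15), seed=0)
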