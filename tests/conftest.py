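import numpy as np
import pytest

from btcnn.archspec import (
    BTCNNSpec,
    DenseSpec,
    GroupKind,
    GroupSpec,
    MergeSpec,
)
from btcnn.preprocess import load_dataset, resize
from btcnn.synthetic_data import PhantomConfig, generate_dataset


def conv(k: int) -> GroupSpec:
    return GroupSpec(GroupKind.CONV, k)


def ds(k: int) -> GroupSpec:
    return GroupSpec(GroupKind.DEPTHWISE_SEPARABLE, k)


def make_tiny_spec(
    input_side: int = 32, width: int = 8, dropout: float = 0.2
) -> BTCNNSpec:
    """Small two-level tree for training tests: conv -> (ds, ds) -> merge."""
    return BTCNNSpec(
        input_shape=(input_side, input_side, 1),
        levels=((conv(width),), (ds(width), ds(width))),
        merge=MergeSpec(group=conv(width)),
        classifier=(
            DenseSpec(32, dropout_rate=dropout),
            DenseSpec(4, activation="softmax"),
        ),
    )


@pytest.fixture(scope="session")
def tiny_spec() -> BTCNNSpec:
    return make_tiny_spec()


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """30 phantoms per class, fixed seed, directory-per-class layout."""
    root = tmp_path_factory.mktemp("phantoms")
    generate_dataset(PhantomConfig(n_per_class=30, seed=0), root)
    return root


@pytest.fixture(scope="session")
def phantom_tensors(phantom_dir):
    """Preprocessed phantoms: (images 200x200 in [0,1], one-hot labels)."""
    images, labels, _ = load_dataset(phantom_dir)
    return images, labels


@pytest.fixture(scope="session")
def phantom_tensors_32(phantom_tensors):
    """The preprocessed phantoms downsampled to the tiny spec's 32x32 input."""
    images, labels = phantom_tensors
    return np.stack([resize(im, (32, 32)) for im in images]), labels
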