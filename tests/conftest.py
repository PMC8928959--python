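import numpy as np
import pytest

from deeplse.cksaap import CksaapConfig, encode_dataset
from deeplse.model import DeepLSE, ModelConfig
from deeplse.synthetic import SyntheticConfig, generate_dataset, make_benchmark_splits

# Small, quickly trainable problem used by most model-level tests: a very
# strongly planted signal on short sequences; a few seconds of training
# recovers it.  (These are correctness fixtures, smaller and stronger than
# the benchmark-shaped conditions exercised in the acceptance tests.)
SMALL_SYNTH = SyntheticConfig(
    n_pos=80,
    n_neg=240,
    length_range=(50, 150),
    effect_size=8.0,
    seed=11,
)

SMALL_MODEL = ModelConfig(
    N=2, k=1, LV=2, seed=11, max_epochs=300, patience=60, validation_fraction=0.15
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_SYNTH)


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    return make_benchmark_splits(small_dataset, n_pos_train=60, n_neg_train=180, seed=11)


@pytest.fixture(scope="session")
def small_features(small_splits):
    train_set, test_set = small_splits
    cc = CksaapConfig(k=SMALL_MODEL.k)
    X_tr, y_tr, _ = encode_dataset(train_set, cc)
    X_te, y_te, _ = encode_dataset(test_set, cc)
    return X_tr, y_tr, X_te, y_te


@pytest.fixture(scope="session")
def small_results(small_features):
    X_tr, y_tr, _, _ = small_features
    return DeepLSE(X_tr, y_tr, SMALL_MODEL).fit()
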