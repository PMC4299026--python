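import numpy as np
import pytest

import ecgtriage as et
from ecgtriage import dimreduce, nfc


@pytest.fixture(scope="session")
def default_dataset():
    """The reference desk-scale dataset: 3,000 beats at the corpus class mix."""
    return et.generate_dataset(et.RecordSpec(n_beats=3000, seed=0), folds=4)


@pytest.fixture(scope="session")
def small_dataset():
    """1,000 beats for cheap classifier-level tests."""
    return et.generate_dataset(et.RecordSpec(n_beats=1000, seed=11), folds=4)


@pytest.fixture(scope="session")
def rp16_features(small_dataset):
    """(features, labels) for a fixed 16-coefficient random projection."""
    P = dimreduce.sample_achlioptas(16, small_dataset.windows.shape[1], seed=21)
    return dimreduce.project_rp(P, small_dataset.windows), small_dataset.labels


@pytest.fixture(scope="session")
def trained_model(rp16_features):
    """An RP16 NFC trained on the first 600 beats, alpha tuned on the rest."""
    U, y = rp16_features
    model = nfc.init_model(U[:600], y[:600], reducer_id="rp16")
    model = nfc.train_model(model, U[:600], y[:600])
    alpha, _ = nfc.tune_alpha(model, U[600:], y[600:], arr_min=0.95)
    model.alpha_train = alpha
    return model


@pytest.fixture(scope="session")
def cv_rp16(default_dataset):
    """Desk-scale 4-fold CV with the GA-optimized RP16 front-end (seed-pinned)."""
    from ecgtriage import evaluate

    return evaluate.cross_validate(default_dataset, reducer="rp16",
                                   arr_min=0.95, seed=0)


def make_gaussian_features(centers, sigma, n_per_class, seed):
    """3-class gaussian feature clouds with known per-class centers.

    ``centers`` is (k, 3); returns (X, labels) stacked class-by-class.
    """
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    k = centers.shape[0]
    X, y = [], []
    for l, cls in enumerate(nfc.CLASSES):
        X.append(centers[:, l] + sigma * rng.standard_normal((n_per_class, k)))
        y.extend([cls] * n_per_class)
    return np.vstack(X), np.asarray(y)
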