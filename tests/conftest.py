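import numpy as np
import pytest

import wfdta as w


@pytest.fixture(scope="session")
def small_spec() -> w.SyntheticSpec:
    """Desk-scale planted-signal benchmark conditions used across tests."""
    return w.SyntheticSpec(seed=7, n_proteins=8, n_drugs=5)


@pytest.fixture(scope="session")
def small_dataset(small_spec) -> w.AffinityDataset:
    return w.make_dataset(small_spec)


@pytest.fixture(scope="session")
def featurized_small(small_dataset):
    """(train, test) featurized pairs for the small benchmark."""
    train_ds, test_ds = w.train_test_split(small_dataset, 0.8, seed=7)
    featurizer = w.PairFeaturizer(n=2).fit(train_ds)
    return featurizer.transform(train_ds), featurizer.transform(test_ds), train_ds, test_ds


def brute_force_ci(truth, pred) -> float:
    """O(n^2) pair-enumeration oracle for the concordance index."""
    truth = np.asarray(truth, float)
    pred = np.asarray(pred, float)
    num = 0.0
    z = 0
    for i in range(len(truth)):
        for j in range(len(truth)):
            if truth[i] > truth[j]:
                z += 1
                if pred[i] > pred[j]:
                    num += 1.0
                elif pred[i] == pred[j]:
                    num += 0.5
    if z == 0:
        raise ValueError("all truths tied")
    return num / z
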