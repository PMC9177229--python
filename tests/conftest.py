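import numpy as np
import pytest

import lmlssrc as lm


def margin_sum_bruteforce(A: np.ndarray, labels: np.ndarray) -> float:
    """Direct double-loop evaluation of the class-margin penalty:
    (1/N) sum_i [ sum_{t in C_k} ||a_i - a_t||^2 / N_k
                 - sum_{j not in C_k} ||a_i - a_j||^2 / (N - N_k) ]."""
    N = labels.size
    total = 0.0
    for i in range(N):
        k = labels[i]
        same = np.flatnonzero(labels == k)
        other = np.flatnonzero(labels != k)
        total += sum(np.sum((A[:, i] - A[:, t]) ** 2) for t in same) / same.size
        if other.size:
            total -= sum(np.sum((A[:, i] - A[:, j]) ** 2) for j in other) / other.size
    return total / N


def locality_sum_bruteforce(A: np.ndarray, P: np.ndarray) -> float:
    """Direct double loop: sum_ij p_ij ||a_i - a_j||^2."""
    N = P.shape[0]
    return sum(
        P[i, j] * np.sum((A[:, i] - A[:, j]) ** 2)
        for i in range(N)
        for j in range(N)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default 4-class dictionary-mode synthetic dataset, seed 7."""
    return lm.generate(lm.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def default_split(default_dataset):
    return lm.split_train_test(default_dataset, 0.25, 7)


@pytest.fixture(scope="session")
def fitted_default(default_split):
    """A model fitted once on the default training split (shared: fits are
    deterministic, so read-only reuse across tests is safe)."""
    train, _ = default_split
    model = lm.LargeMarginLocalSRC(train.X.T, train.labels)
    return model, model.fit()


@pytest.fixture(scope="session")
def small_dataset():
    """A small 3-class dataset for fast fit-based tests."""
    return lm.generate(lm.SyntheticSpec(n_classes=3, n_per_class=30, seed=3))
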