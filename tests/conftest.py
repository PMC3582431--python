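import numpy as np
import pytest

from mcrum import BlobSpec, ap_matrix, gaussian_blobs, ovr_matrix, train_mcrum

THREE_CENTERS = [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]


@pytest.fixture(scope="session")
def blobs_train():
    """Well-separated 3-class blobs (separation 10 sigma), training draw."""
    return gaussian_blobs(BlobSpec(THREE_CENTERS, n_per_class=100, sigma=1.0, seed=11))


@pytest.fixture(scope="session")
def blobs_test():
    """Independent draw from the same blob layout."""
    return gaussian_blobs(BlobSpec(THREE_CENTERS, n_per_class=100, sigma=1.0, seed=12))


@pytest.fixture(scope="session")
def ap_model(blobs_train):
    return train_mcrum(blobs_train, ap_matrix(3), M=4, seed=11)


@pytest.fixture(scope="session")
def ovr_model(blobs_train):
    return train_mcrum(blobs_train, ovr_matrix(3), M=4, seed=11)


def random_valid_code(rng: np.random.Generator, K: int, L: int, sparse: bool):
    """Sample one valid coding matrix for decoder stress tests.

    Columns are drawn individually until each mixes 1 and 0 and is distinct;
    whole matrices failing the row constraints are redrawn.
    """
    from mcrum import CodingMatrix

    for _ in range(1000):
        cols = []
        for _ in range(L):
            for _ in range(1000):
                if sparse:
                    c = rng.choice([-1, 0, 1], size=K, p=[0.5, 0.25, 0.25])
                else:
                    c = rng.integers(0, 2, size=K)
                c = c.astype(np.int8)
                if (c == 1).any() and (c == 0).any() and not any(
                    np.array_equal(c, p) for p in cols
                ):
                    cols.append(c)
                    break
            else:
                raise RuntimeError("no distinct mixed column available")
        try:
            return CodingMatrix(np.column_stack(cols))
        except ValueError:
            continue
    raise RuntimeError("could not sample a valid code")
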