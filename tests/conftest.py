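import itertools

import numpy as np
import pytest

from fairgibbs.datasets import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """Six points, two tight groups, 1:1 protected attribute."""
    points = np.array(
        [[0.0, 0.0], [1.0, 0.0], [5.0, 5.0], [0.0, 0.5], [1.2, 0.3], [5.2, 4.8]]
    )
    labels = np.array([1, 1, 1, 2, 2, 2])
    return LabeledDataset(points, labels)


def enumerate_permutation_matrices(n):
    """All n x n permutation matrices (the t=1, unit-margin polytope)."""
    out = []
    for perm in itertools.permutations(range(n)):
        b = np.zeros((n, n), dtype=np.uint8)
        b[np.arange(n), perm] = 1
        out.append(b)
    return out


def enumerate_two_partitions(m):
    """All partitions of m items into exactly 2 nonempty blocks, canonical labels."""
    parts = []
    for mask in range(1, 2 ** (m - 1)):
        labels = np.ones(m, dtype=int)
        for i in range(1, m):
            if (mask >> (i - 1)) & 1:
                labels[i] = 2
        # item 0 always in block 1 => canonical, no duplicates
        parts.append(labels)
    return parts


def total_variation(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
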