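from __future__ import annotations

import numpy as np
import pytest

from omicsel import (ClassLabels, CriterionParams, SyntheticSpec, discretize,
                     drop_constant_features, generate, zscore_normalize)


@pytest.fixture
def small_synth():
    """A compact planted dataset: 8 informative @ 2 sigma, 4 redundant, 30 noise."""
    spec = SyntheticSpec(n_informative=8, n_redundant=4, n_noise=30,
                         effect_size=2.0, redundancy_r=0.9, seed=11)
    matrix, labels, truth = generate(spec)
    return matrix, labels, truth


@pytest.fixture
def small_normalized(small_synth):
    matrix, labels, truth = small_synth
    norm = zscore_normalize(drop_constant_features(matrix))
    return norm, labels, truth


@pytest.fixture
def small_discretized(small_normalized):
    norm, labels, truth = small_normalized
    return discretize(norm), labels, truth


def random_discrete_instance(rng: np.random.Generator, d: int, n: int,
                             n_classes: int = 3):
    """Random 3-state feature matrix plus class labels, for selector tests."""
    states = rng.integers(-1, 2, size=(d, n))
    y = rng.integers(0, n_classes, size=n)
    while len(np.unique(y)) < 2:  # ClassLabels requires >= 2 classes
        y = rng.integers(0, n_classes, size=n)
    return states, y


def labels_from_codes(y: np.ndarray) -> ClassLabels:
    names = tuple(f"c{c}" for c in sorted(np.unique(y)))
    return ClassLabels(tuple(f"s{i}" for i in range(len(y))),
                       tuple(f"c{c}" for c in y), names)


@pytest.fixture
def default_params():
    return CriterionParams()
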