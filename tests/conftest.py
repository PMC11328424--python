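from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from ataceval import LabelVector, Partition


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_labels(values, prefix="cell") -> LabelVector:
    ids = tuple(f"{prefix}{i}" for i in range(len(values)))
    return LabelVector(ids, tuple(str(v) for v in values))


def make_partition(values, prefix="cell") -> Partition:
    ids = tuple(f"{prefix}{i}" for i in range(len(values)))
    return Partition(ids, tuple(str(v) for v in values))


@pytest.fixture
def labels_factory():
    return make_labels


@pytest.fixture
def partition_factory():
    return make_partition
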