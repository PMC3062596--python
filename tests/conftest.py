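from pathlib import Path

import numpy as np
import pytest

from disprok.synthetic import GeneratorConfig, generate, small_fixture

DATA_DIR = Path(__file__).parent / "data" / "small"


@pytest.fixture(scope="session")
def small_dataset():
    dataset, meta = small_fixture()
    return dataset, meta


@pytest.fixture(scope="session")
def tiny_generated():
    """A small but random synthetic dataset, shared across tests."""
    cfg = GeneratorConfig(seed=42, n_bacteria=6, n_archaea=3, proteins_per_organism=30)
    return generate(cfg)


def naive_segment(labels):
    """Position-scan segmentation oracle: (start, end, kind) triples."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, "disordered" if labels[start] else "ordered"))
            start = i
    return out
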