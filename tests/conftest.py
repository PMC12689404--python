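import dataclasses

import numpy as np
import pandas as pd
import pytest

from mirsig import ExpressionMatrix, MouseSimSpec, generate_mouse_experiment
from mirsig.matrix import make_mouse_annotation


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_mouse_spec():
    """Mouse spec with a modest background, where day-0 recovery is feasible."""
    return dataclasses.replace(MouseSimSpec(), n_features=60, rng_seed=7)


@pytest.fixture
def small_mouse(small_mouse_spec):
    return generate_mouse_experiment(small_mouse_spec)


@pytest.fixture
def tiny_matrix():
    """Deterministic 12-feature × 16-sample matrix in the 2×2 design."""
    gen = np.random.default_rng(0)
    sample_ids, groups, times = [], [], []
    for group in ("Control", "MPTP"):
        for time in ("D0", "D5"):
            for r in range(1, 5):
                sample_ids.append(f"{group}_{time}_{r}")
                groups.append(group)
                times.append(time)
    data = pd.DataFrame(
        gen.normal(8, 1, size=(12, 16)),
        index=[f"mmu-miR-f{i:02d}" for i in range(12)],
        columns=sample_ids,
    )
    ann = make_mouse_annotation(sample_ids, groups, times)
    return ExpressionMatrix(data), ann
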