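import numpy as np
import pytest

from antplantnet import InteractionMatrix


def make_matrix(weights) -> InteractionMatrix:
    w = np.asarray(weights)
    return InteractionMatrix(
        plant_labels=tuple(f"P{i+1}" for i in range(w.shape[0])),
        ant_labels=tuple(f"A{j+1}" for j in range(w.shape[1])),
        weights=w,
    )


def random_matrix(rng: np.random.Generator, n_rows: int, n_cols: int,
                  max_count: int = 6) -> InteractionMatrix:
    """Random valid count matrix: no empty rows/columns, positive total."""
    while True:
        w = rng.integers(0, max_count + 1, size=(n_rows, n_cols))
        if w.sum(axis=1).all() and w.sum(axis=0).all():
            return make_matrix(w)


@pytest.fixture
def tiny():
    """The 2x2 worked example [[2,1],[0,3]]: L=3, F=6."""
    return make_matrix([[2, 1], [0, 3]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
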