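"""Shared fixtures: small trees, matrices and cohort tables."""

import numpy as np
import pandas as pd
import pytest

from mstnet.mst import SpanningTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def star_tree(n: int, weight: float = 0.5) -> SpanningTree:
    """Hub node 0 joined to n-1 leaves."""
    return SpanningTree.from_edges(
        [f"n{i}" for i in range(n)], [(0, i, weight) for i in range(1, n)]
    )


def path_tree(n: int, weight: float = 0.5) -> SpanningTree:
    return SpanningTree.from_edges(
        [f"n{i}" for i in range(n)], [(i, i + 1, weight) for i in range(n - 1)]
    )


@pytest.fixture
def star5():
    return star_tree(5)


@pytest.fixture
def path5():
    return path_tree(5)


def random_symmetric_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fully connected weight matrix with distinct positive off-diagonals."""
    w = rng.uniform(0.05, 0.95, size=(n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    return w


def make_cohort_table(
    rng: np.random.Generator,
    group_sizes: dict[str, int],
    effects: dict[str, float] | None = None,
    noise: float = 1.0,
) -> pd.DataFrame:
    """Synthetic metrics table for inference tests: one measure ('y') with an
    optional additive group effect, plus age/sex/education covariates."""
    effects = effects or {}
    rows = []
    i = 0
    for g, n in group_sizes.items():
        for _ in range(n):
            age = rng.normal(40, 12)
            sex = "male" if rng.random() < 0.5 else "female"
            edu = rng.normal(13, 3)
            y = effects.get(g, 0.0) + noise * rng.normal()
            rows.append(
                {"subject_id": f"s{i:03d}", "group": g, "age": age,
                 "sex": sex, "education": edu, "y": y}
            )
            i += 1
    return pd.DataFrame(rows)
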