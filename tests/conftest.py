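import numpy as np
import pytest

from qpmsi import (
    RelationshipMatrix,
    SelectionSpec,
    StandardizedTraits,
    TraitTable,
    build_problem,
)


def random_psd_grm(rng: np.random.Generator, n: int) -> RelationshipMatrix:
    """Random Gram matrix (PSD by construction) with generic ids."""
    A = rng.standard_normal((n, max(n, 3)))
    G = A @ A.T / A.shape[1]
    return RelationshipMatrix(tuple(f"g{i}" for i in range(n)), G)


def random_scores(rng: np.random.Generator, n: int, p0: int) -> StandardizedTraits:
    y = rng.standard_normal((n, p0))
    y = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    return StandardizedTraits(
        tuple(f"g{i}" for i in range(n)), y, tuple(f"T{j}" for j in range(p0))
    )


def random_instance(rng: np.random.Generator, *, n=None, s=None, k=None, p0=None, R=None):
    """One random selection problem at brute-forceable size."""
    n = n if n is not None else int(rng.integers(6, 16))
    s = s if s is not None else int(rng.integers(2, 6))
    p0 = p0 if p0 is not None else int(rng.integers(1, 4))
    k = k if k is not None else float(rng.choice([0.0, 0.5, 1.0, 1.5]))
    R = R if R is not None else tuple(rng.choice([0.0, 25.0], size=p0).tolist())
    y = random_scores(rng, n, p0)
    G = random_psd_grm(rng, n)
    return build_problem(y, G, SelectionSpec(s=s, k=k, R=R))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_traits():
    values = np.array(
        [[10.0, 3.0], [12.0, 1.0], [14.0, 2.0], [16.0, 4.0]]
    )
    return TraitTable(
        ("a", "b", "c", "d"), values, ("yield", "disease"),
        ("higher_is_better", "lower_is_better"),
    )
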