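import numpy as np
import pytest
import sympy

from linfw.fixtures import (
    FixtureConfig,
    cascade_graph,
    three_cycle,
    two_cycle,
)
from linfw.enzymes import michaelis_menten_mechanism


@pytest.fixture
def two_cycle_graph():
    """1 <-> 2 with symbolic labels a, b."""
    return two_cycle()


@pytest.fixture
def three_cycle_graph():
    return three_cycle()


@pytest.fixture
def cascade():
    """1 <-> 2 -> 3: terminal SCC {3} absorbs everything."""
    return cascade_graph()


@pytest.fixture
def mm_mechanism():
    """E + S <-> ES -> E + P with rate constants k1, k2, k3."""
    return michaelis_menten_mechanism()


def numeric_nullspace(L: np.ndarray, tol: float = 1e-9):
    """SVD nullspace of a numeric Laplacian (independent oracle)."""
    _, s, vt = np.linalg.svd(L)
    null_mask = np.concatenate([s, np.zeros(L.shape[0] - len(s))]) <= tol * max(
        s.max(), 1.0
    )
    return vt[null_mask.nonzero()[0], :].T


def exact_nullspace(G):
    """Kernel of the Laplacian in exact rational arithmetic (floats are
    binary fractions, so the lift is lossless) -- the conditioning-proof
    linear-algebra oracle."""
    from linfw.graph import laplacian
    from linfw.matrix_tree import _rationalized

    return laplacian(_rationalized(G)).nullspace()


def assert_sym_zero(expr):
    assert sympy.expand(sympy.sympify(expr)) == 0, f"not symbolically zero: {expr}"
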