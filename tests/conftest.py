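import numpy as np
import pytest

from lpsvm.data import Dataset
from lpsvm.model import FitOptions


@pytest.fixture
def toy1d():
    """Two points on the line: x=+1 labelled +1, x=-1 labelled -1.

    Hand-solved: the hard-margin dual is maximized at alpha = (1/2, 1/2),
    giving w = 1, b = 0, objective -1/2.
    """
    return Dataset(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]))


@pytest.fixture
def sep2d():
    """Four separable points in the plane (margin along the first axis)."""
    x = np.array([[2.0, 1.0], [1.5, -1.0], [-2.0, 0.5], [-1.2, -0.7]])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    return Dataset(x, y)


@pytest.fixture
def hard_margin_opts():
    return FitOptions(p=2.0, box_c=np.inf, smo_tol=1e-8)


def random_tiny_problem(rng, m_max=6, n_max=4, box_c=5.0):
    """Random tiny weighted dual instance with both classes present."""
    m = int(rng.integers(3, m_max + 1))
    n = int(rng.integers(2, n_max + 1))
    x = rng.normal(size=(m, n))
    y = np.where(rng.random(m) < 0.5, 1.0, -1.0)
    if np.all(y == y[0]):
        y[0] = -y[0]
    v = rng.uniform(0.2, 3.0, size=n)
    return x, y, v
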