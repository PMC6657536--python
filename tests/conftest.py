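import numpy as np
import pytest

from plateletfda.basis import SplineSpec, truncated_basis


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def dense_ridge_solution(t, y, spec: SplineSpec, lam: float) -> np.ndarray:
    """Brute-force generalized-ridge oracle: argmin ||y - C theta||^2 + lam ||u||^2.

    The minimizer of the penalized criterion, (C'C + lam D)^-1 C'y with D
    penalizing the truncated block only, computed as a stacked least-squares
    problem [C; sqrt(lam) D_rows] theta = [y; 0] via QR (raw degree-5 normal
    equations are too ill-conditioned for a meaningful 1e-8 comparison).
    Independent of the package's Woodbury/scaled-axis fitting path.
    """
    P, T = truncated_basis(t, spec, 0, check_range=False)
    C = np.hstack([P, T])
    K = spec.n_knots
    pen = np.zeros((K, C.shape[1]))
    pen[:, spec.degree + 1 :] = np.sqrt(lam) * np.eye(K)
    A = np.vstack([C, pen])
    b = np.concatenate([y, np.zeros(K)])
    return np.linalg.lstsq(A, b, rcond=None)[0]


def random_spline_instance(rng, n_max=100, k_max=5, degrees=(2, 3, 5)):
    """A random small penalized-spline problem for oracle comparisons."""
    p = int(rng.choice(degrees))
    K = int(rng.integers(1, k_max + 1))
    n = int(rng.integers(p + K + 5, n_max + 1))
    t = np.sort(rng.uniform(0.0, 7.0, n))
    knots = np.sort(rng.uniform(t[1], t[-2], K))
    while np.any(np.diff(knots) <= 1e-3):
        knots = np.sort(rng.uniform(t[1], t[-2], K))
    spec = SplineSpec(degree=p, knots=knots)
    y = (
        10.0 * np.sin(t)
        + rng.normal(0.0, 1.0, n)
        + rng.uniform(-2, 2) * t
    )
    lam = float(10.0 ** rng.uniform(-4, 4))
    return t, y, spec, lam
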