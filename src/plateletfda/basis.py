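"""Truncated power spline basis.

The basis for a degree-``p`` spline with knots ``k_1 < ... < k_K`` is

    {1, t, ..., t^p, (t - k_1)_+^p, ..., (t - k_K)_+^p}

where ``(x)_+^p = x^p`` for ``x > 0`` and ``0`` otherwise (the value at
``x = 0`` is taken as the continuous limit, 0).  Derivatives of basis
columns are the exact calculus derivatives, so a fitted curve and its
velocity/acceleration share one coefficient vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "truncated_basis", "default_knots"]

#: Largest number of knots chosen automatically.
MAX_AUTO_KNOTS = 35


@dataclass(frozen=True)
class SplineSpec:
    """Degree and knot layout of a truncated power basis.

    Parameters
    ----------
    degree : int
        Degree ``p`` of the piecewise polynomials (default 5, which keeps
        the estimated curve and its first two derivatives smooth).
    knots : numpy.ndarray
        Strictly increasing interior knot locations, in the units of the
        predictor (minutes for time-domain fits, percent aggregation for
        phase-law fits).
    knot_rule : str
        How the knots were chosen: ``"quantile"``, ``"equal_spaced"`` or
        ``"explicit"``.  Informational only.
    """

    degree: int = 5
    knots: np.ndarray = field(default_factory=lambda: np.empty(0))
    knot_rule: str = "explicit"

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 1 or k.size < 1:
            raise ValueError("at least one knot is required")
        if np.any(~np.isfinite(k)):
            raise ValueError("knots must be finite")
        if np.any(np.diff(k) <= 0):
            raise ValueError(f"knots must be strictly increasing, got {k.tolist()}")
        object.__setattr__(self, "knots", k)

    @property
    def n_knots(self) -> int:
        return int(self.knots.size)

    @property
    def n_basis(self) -> int:
        """Total number of basis columns, p + 1 + K."""
        return self.degree + 1 + self.n_knots


def _falling_factorial(j: int, m: int) -> float:
    """j! / (j - m)! — the coefficient produced by differentiating t^j m times."""
    return math.factorial(j) / math.factorial(j - m) if j >= m else 0.0


def truncated_basis(
    times: np.ndarray,
    spec: SplineSpec,
    deriv_order: int = 0,
    *,
    check_range: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the basis (or its derivative) at ``times``.

    Returns the pair ``(P, T)``:

    * ``P`` — polynomial block, shape ``(n, p + 1)``; column ``j`` holds the
      ``deriv_order``-th derivative of ``t^j`` (zero columns for
      ``j < deriv_order`` keep the coefficient layout fixed across orders).
    * ``T`` — truncated block, shape ``(n, K)``; column ``k`` holds the
      exact derivative of ``(t - k_k)_+^p``, i.e.
      ``p!/(p - m)! * (t - k_k)_+^(p - m)``, zero for ``t <= k_k``.

    deriv_order up to 2 is supported (velocity and acceleration).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(~np.isfinite(t)):
        raise ValueError("times must be finite")
    m = int(deriv_order)
    if m not in (0, 1, 2):
        raise ValueError(f"deriv_order must be 0, 1 or 2, got {deriv_order}")
    p = spec.degree
    if m > p - 1:
        raise ValueError(
            f"deriv_order {m} needs degree >= {m + 1} for a continuous result"
        )
    if check_range and t.size and spec.knots.size:
        lo, hi = t.min(), t.max()
        outside = (spec.knots <= lo) | (spec.knots >= hi)
        if np.any(outside):
            warnings.warn(
                f"{int(outside.sum())} knot(s) fall outside the open data range "
                f"({lo:g}, {hi:g}); the corresponding basis columns are "
                "degenerate on this grid",
                stacklevel=2,
            )

    poly = np.zeros((t.size, p + 1))
    for j in range(m, p + 1):
        poly[:, j] = _falling_factorial(j, m) * t ** (j - m)

    diff = t[:, None] - spec.knots[None, :]
    scale = _falling_factorial(p, m)
    trunc = scale * np.where(diff > 0, diff, 0.0) ** (p - m)
    return poly, trunc


def default_knots(times: np.ndarray, K: int | str = "auto", degree: int = 5) -> SplineSpec:
    """Place ``K`` knots at interior quantiles of the distinct times.

    ``K="auto"`` uses ``min(floor(n_distinct / 4), 35)``, a conventional
    penalized-spline default that over-provisions knots and lets the
    smoothing variance do the work.  Knots sit at the ``k/(K+1)`` quantiles
    of the distinct observed values, ``k = 1..K``; duplicates are collapsed.
    """
    t = np.unique(np.asarray(times, dtype=float))
    if K == "auto":
        K = min(t.size // 4, MAX_AUTO_KNOTS)
    K = int(K)
    if K < 1:
        raise ValueError(
            f"need at least 8 distinct times for automatic knots, got {t.size}"
        )
    if t.size < K + 2:
        raise ValueError(
            f"need at least K + 2 = {K + 2} distinct times for {K} knots, got {t.size}"
        )
    probs = np.arange(1, K + 1) / (K + 1)
    knots = np.unique(np.quantile(t, probs))
    # interior only: quantiles can hit the extremes when K is large
    knots = knots[(knots > t[0]) & (knots < t[-1])]
    return SplineSpec(degree=degree, knots=knots, knot_rule="quantile")
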