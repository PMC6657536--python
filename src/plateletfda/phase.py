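"""Phase-plane reconstruction of the aggregation kinetics.

Once the mean curve and its first derivative are estimated, plotting the
predicted velocity against the predicted aggregation level reads off an
empirical one-dimensional law dy/dt = F(y).  Two forms are fitted:

* linear, ``dy/dt = gamma0 + gamma1 y + e`` — ordinary least squares of
  velocity on aggregation, the first-order-kinetics model whose fit
  quality (adjusted R^2) indicates where linear kinetics hold;
* smooth, ``dy/dt = gamma0 + g(y) + e`` with ``g`` a penalized spline over
  the aggregation axis — a model-free law that can expose multiple
  steady states (bistability).

Steady states are the roots of the fitted law; a root is stable when the
law's slope there is negative (small perturbations decay).  Because the
velocity points are themselves smoothed estimates evaluated on a grid,
their errors are serially correlated; the OLS standard errors reported
here ignore that and are labeled naive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .basis import SplineSpec, default_knots
from .splines import PenalizedFit, fit_penalized_spline, predict_curve

__all__ = [
    "PhaseLinearFit",
    "PhaseSmoothFit",
    "phase_points",
    "fit_linear_phase",
    "fit_smooth_phase",
    "find_steady_states",
]

#: Fraction of the time grid trimmed at each end before phase fitting;
#: spline derivative estimates are least reliable near the range ends.
DEFAULT_TRIM = 0.05


def trimmed_grid(fit: PenalizedFit, n: int = 200, trim: float = DEFAULT_TRIM) -> np.ndarray:
    """Equally spaced times over the training range with end fractions cut."""
    lo, hi = float(fit.times.min()), float(fit.times.max())
    span = hi - lo
    return np.linspace(lo + trim * span, hi - trim * span, n)


def phase_points(fit: PenalizedFit, grid: np.ndarray) -> pd.DataFrame:
    """Pair the predicted aggregation and velocity at identical times.

    Returns a frame with columns ``time, aggregation, velocity`` — the raw
    material for the phase-plane regressions.
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("phase grid is empty")
    yhat = predict_curve(fit, grid, deriv_order=0).estimate
    vhat = predict_curve(fit, grid, deriv_order=1).estimate
    return pd.DataFrame({"time": grid, "aggregation": yhat, "velocity": vhat})


@dataclass
class PhaseLinearFit:
    """OLS fit of velocity on aggregation: dy/dt = gamma0 + gamma1 y."""

    gamma0: float                   # intercept, %/min
    gamma1: float                   # slope, 1/min
    se_gamma0: float
    se_gamma1: float
    tau2: float                     # residual variance of e_t (naive)
    adj_r2_raw: float
    n: int

    @property
    def adj_r2(self) -> float:
        """Adjusted R^2 clipped below at 0 (reporting convention)."""
        return max(0.0, self.adj_r2_raw)

    def law(self, y) -> np.ndarray:
        return self.gamma0 + self.gamma1 * np.asarray(y, float)


def _point_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return points["aggregation"].to_numpy(float), points["velocity"].to_numpy(float)
    y, v = points
    return np.asarray(y, float).ravel(), np.asarray(v, float).ravel()


def fit_linear_phase(points) -> PhaseLinearFit:
    """Fit the linear phase law by ordinary least squares.

    ``points`` is the frame from :func:`phase_points` (or a ``(y, v)``
    pair).  Adjusted R^2 uses the one-predictor formula
    ``1 - (1 - R^2)(n - 1)/(n - 2)``; the raw value can be negative and is
    clipped at zero in the reported ``adj_r2``.
    """
    yhat, vhat = _point_arrays(points)
    n = yhat.size
    if n < 3:
        raise ValueError(f"need at least 3 phase points, got {n}")
    if np.ptp(yhat) == 0 or np.var(yhat) == 0:
        raise ValueError("aggregation values are constant; the slope is unidentifiable")
    X = sm.add_constant(yhat)
    res = sm.OLS(vhat, X).fit()
    return PhaseLinearFit(
        gamma0=float(res.params[0]),
        gamma1=float(res.params[1]),
        se_gamma0=float(res.bse[0]),
        se_gamma1=float(res.bse[1]),
        tau2=float(res.mse_resid),
        adj_r2_raw=float(res.rsquared_adj),
        n=n,
    )


@dataclass
class PhaseSmoothFit:
    """Penalized-spline fit of the smooth phase law dy/dt = gamma0 + g(y)."""

    spline: PenalizedFit            # velocity regressed on aggregation
    y_range: tuple[float, float]    # observed aggregation range
    gamma0: float                   # raw intercept of the fitted law
    fixed_points: list[tuple[float, str]]
    n: int

    def law(self, y, level: float = 0.95):
        """Evaluate gamma0 + g at aggregation levels y (a CurveEstimate)."""
        return predict_curve(self.spline, np.asarray(y, float), 0, level=level)

    def law_values(self, y) -> np.ndarray:
        return self.law(y).estimate

    def law_slope(self, y) -> np.ndarray:
        return predict_curve(self.spline, np.asarray(y, float), 1).estimate


def fit_smooth_phase(
    points,
    spec: SplineSpec | None = None,
    *,
    smoothing: float | str = "reml",
    tolerance: float = 1e-6,
) -> PhaseSmoothFit:
    """Fit the smooth phase law with a penalized spline over aggregation.

    Knots default to quantiles of the observed aggregation values with
    ``K = min(n // 4, 20)``, degree 5 — the same machinery as the
    time-domain curve fit, applied on the aggregation axis.  Fixed points
    and their stability are located immediately via
    :func:`find_steady_states`.
    """
    yhat, vhat = _point_arrays(points)
    order = np.argsort(yhat, kind="stable")
    yhat, vhat = yhat[order], vhat[order]
    if spec is None:
        n_distinct = np.unique(yhat).size
        K = min(max(n_distinct // 4, 1), 20)
        spec = default_knots(yhat, K=K, degree=5)
    if yhat.size < spec.n_basis + 2:
        raise ValueError(
            f"need at least {spec.n_basis + 2} phase points for this basis, got {yhat.size}"
        )
    spline = fit_penalized_spline((yhat, vhat), spec, smoothing=smoothing)
    fit = PhaseSmoothFit(
        spline=spline,
        y_range=(float(yhat.min()), float(yhat.max())),
        gamma0=float(spline.beta[0]),
        fixed_points=[],
        n=yhat.size,
    )
    fit.fixed_points = find_steady_states(fit, tolerance=tolerance)
    return fit


def _stability_from_slope(slope: float, slope_tol: float) -> str:
    if abs(slope) < slope_tol:
        return "indeterminate"
    return "stable" if slope < 0 else "unstable"


def find_steady_states(
    law: PhaseLinearFit | PhaseSmoothFit,
    tolerance: float = 1e-6,
    *,
    n_scan: int = 2001,
    slope_tol: float = 1e-6,
) -> list[tuple[float, str]]:
    """Roots of the fitted phase law with a local stability flag.

    Linear law: the single root ``-gamma0/gamma1``, stable iff
    ``gamma1 < 0`` (``gamma1 = 0`` has no finite fixed point: an empty
    list is returned with a warning).  Smooth law: a sign-change scan on a
    dense grid over the observed aggregation range, refined by bisection
    until ``|law(y*)| < tolerance``; stability comes from the sign of the
    numerically differentiated law at the root, flagged indeterminate when
    the slope magnitude is below ``slope_tol``.
    """
    if isinstance(law, PhaseLinearFit):
        if law.gamma1 == 0.0:
            warnings.warn(
                "gamma1 = 0: the linear law has no finite fixed point", stacklevel=2
            )
            return []
        ystar = -law.gamma0 / law.gamma1
        return [(float(ystar), _stability_from_slope(law.gamma1, slope_tol))]

    lo, hi = law.y_range
    ygrid = np.linspace(lo, hi, n_scan)
    vals = law.law_values(ygrid)
    roots: list[float] = []
    for i in range(n_scan - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(ygrid[i]))
        elif a * b < 0.0:
            r = optimize.brentq(
                lambda y: float(law.law_values(np.array([y]))[0]),
                ygrid[i],
                ygrid[i + 1],
                xtol=min(tolerance, 1e-10) ,
            )
            roots.append(float(r))
    if vals[-1] == 0.0:
        roots.append(float(ygrid[-1]))

    # dedupe near-coincident roots
    out: list[tuple[float, str]] = []
    h = (hi - lo) * 1e-6 if hi > lo else 1e-6
    for r in roots:
        if out and abs(r - out[-1][0]) < 10 * h:
            continue
        if abs(float(law.law_values(np.array([r]))[0])) >= tolerance:
            continue
        a = max(r - h, lo)
        b = min(r + h, hi)
        slope = float(
            (law.law_values(np.array([b]))[0] - law.law_values(np.array([a]))[0])
            / (b - a)
        )
        out.append((r, _stability_from_slope(slope, slope_tol)))
    return out
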