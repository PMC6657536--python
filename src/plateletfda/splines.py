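"""Penalized-spline smoothing in the linear-mixed-model formulation.

The aggregation trace is modeled as ``y(t) = f(t) + eps`` with a smooth
signal ``f`` written in a truncated power basis,

    f(t) = sum_j beta_j t^j + sum_k u_k (t - k_k)_+^p .

Treating the truncated-block coefficients ``u_k`` as i.i.d. normal random
effects with variance ``sigma_u^2`` turns ridge-penalized spline fitting
into a variance-component problem: the implied penalty is
``lambda = sigma_eps^2 / sigma_u^2``, estimable by (RE)ML, and the fitted
curve is the BLUP of ``f``.  Because derivatives of the basis are again a
linear map of the same coefficients, velocity and acceleration curves and
their pointwise standard errors come for free from the joint covariance of
``(beta, u)``.

Numerics: raw degree-5 powers of minutes are badly conditioned, so fitting
happens on an affinely rescaled axis ``s = (t - a)/c`` with ``s`` spanning
[0, 1]; coefficients are mapped back to the raw parameterization exactly
(binomial expansion for the polynomial block, ``c^-p`` scaling for the
truncated block) before reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .basis import SplineSpec, default_knots, truncated_basis

__all__ = [
    "PenalizedFit",
    "CurveEstimate",
    "fit_penalized_spline",
    "predict_curve",
]


# ---------------------------------------------------------------------------
# variance-component machinery (shared with the dose model)
# ---------------------------------------------------------------------------

_LOGLAM_LO = -25.0
_LOGLAM_HI = 25.0


@dataclass
class MixedFitResult:
    """Solution of y = X b + Z u + eps with u ~ N(0, sigma_u^2 I)."""

    theta: np.ndarray          # stacked (b, u)
    cov: np.ndarray            # sigma_eps^2 * (C'C + lam D)^-1, C = [X Z]
    lam: float                 # sigma_eps^2 / sigma_u^2
    sigma2_eps: float
    sigma2_u: float
    at_boundary: bool          # lambda pinned at the search boundary
    n_fixed: int
    n_random: int
    n_obs: int

    @property
    def fixed(self) -> np.ndarray:
        return self.theta[: self.n_fixed]

    @property
    def random(self) -> np.ndarray:
        return self.theta[self.n_fixed :]


def _neg2_loglik(loglam, args, reml):
    """-2 profile (restricted) log-likelihood at log-lambda, up to a constant.

    Woodbury identities keep every solve K x K:
    V = I + ZZ'/lam, A = Z'Z + lam I,
    V^-1 = I - Z A^-1 Z',  log|V| = log|A| - K log lam.
    """
    n, n_fixed, XtX, XtZ, ZtZ, Xty, Zty, yty = args
    lam = math.exp(loglam)
    K = ZtZ.shape[0]
    A = ZtZ + lam * np.eye(K)
    cA = linalg.cho_factor(A, lower=True)
    logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
    AiZty = linalg.cho_solve(cA, Zty)
    AiZtX = linalg.cho_solve(cA, XtZ.T)
    XtVX = XtX - XtZ @ AiZtX
    XtVy = Xty - XtZ @ AiZty
    yVy = yty - Zty @ AiZty
    cX = linalg.cho_factor(XtVX, lower=True)
    b = linalg.cho_solve(cX, XtVy)
    yPy = max(yVy - XtVy @ b, 1e-300)
    logdetV = logdetA - K * loglam
    if reml:
        df = n - n_fixed
        logdetXVX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        return df * math.log(yPy / df) + logdetV + logdetXVX
    return n * math.log(yPy / n) + logdetV


def solve_mixed_model(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    smoothing: float | str = "reml",
) -> MixedFitResult:
    """Estimate lambda (unless fixed) and solve the mixed-model equations.

    ``smoothing`` is ``"reml"`` (default), ``"ml"``, or a positive float
    fixing ``lambda`` directly.  The coefficient solve and joint covariance
    are the ridge system ``(C'C + lam D) theta = C'y`` with the penalty
    ``D`` acting on the random block only — the BLUP solution.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    n, n_fixed = X.shape
    n_random = Z.shape[1]
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if n <= n_fixed:
        raise ValueError(f"need more than {n_fixed} observations, got {n}")

    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)
    args = (n, n_fixed, XtX, XtZ, ZtZ, Xty, Zty, yty)

    at_boundary = False
    if isinstance(smoothing, str):
        method = smoothing.lower()
        if method not in ("reml", "ml"):
            raise ValueError(f"smoothing must be 'reml', 'ml' or a float, got {smoothing!r}")
        reml = method == "reml"
        res = optimize.minimize_scalar(
            _neg2_loglik,
            bounds=(_LOGLAM_LO, _LOGLAM_HI),
            method="bounded",
            args=(args, reml),
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(
                f"(RE)ML optimization of the smoothing parameter failed: {res.message}"
            )
        loglam = float(res.x)
        at_boundary = loglam > _LOGLAM_HI - 1.0 or loglam < _LOGLAM_LO + 1.0
        lam = math.exp(loglam)
        reml_for_sigma = reml
    else:
        lam = float(smoothing)
        if not lam > 0:
            raise ValueError(f"fixed smoothing parameter must be > 0, got {lam}")
        reml_for_sigma = True

    # mixed-model (ridge) solve at lambda-hat: QR on the augmented system
    # [C; sqrt(lam) D] theta = [y; 0] avoids squaring the condition number
    aug = np.zeros((n + n_random, n_fixed + n_random))
    aug[:n, :n_fixed] = X
    aug[:n, n_fixed:] = Z
    aug[n:, n_fixed:] = math.sqrt(lam) * np.eye(n_random)
    rhs_aug = np.concatenate([y, np.zeros(n_random)])
    theta = linalg.lstsq(aug, rhs_aug, lapack_driver="gelsd")[0]

    M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + lam * np.eye(n_random)]])
    cM = linalg.cho_factor(M, lower=True)
    Minv = linalg.cho_solve(cM, np.eye(M.shape[0]))

    # profiled sigma_eps^2 at lambda-hat: y'Py / df  (df = n for ML)
    A = ZtZ + lam * np.eye(n_random)
    cA = linalg.cho_factor(A, lower=True)
    XtVX = XtX - XtZ @ linalg.cho_solve(cA, XtZ.T)
    XtVy = Xty - XtZ @ linalg.cho_solve(cA, Zty)
    yVy = yty - Zty @ linalg.cho_solve(cA, Zty)
    b = linalg.solve(XtVX, XtVy, assume_a="pos")
    yPy = max(yVy - XtVy @ b, 0.0)
    df = n - n_fixed if reml_for_sigma else n
    sigma2_eps = max(yPy / df, 1e-300)
    sigma2_u = sigma2_eps / lam

    return MixedFitResult(
        theta=theta,
        cov=sigma2_eps * Minv,
        lam=lam,
        sigma2_eps=sigma2_eps,
        sigma2_u=sigma2_u,
        at_boundary=at_boundary,
        n_fixed=n_fixed,
        n_random=n_random,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# axis rescaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisScale:
    """Affine map s = (t - shift) / scale used for conditioning."""

    shift: float
    scale: float

    @classmethod
    def from_data(cls, t: np.ndarray) -> "AxisScale":
        lo, hi = float(np.min(t)), float(np.max(t))
        scale = hi - lo
        if scale <= 0:
            scale = 1.0
        return cls(shift=lo, scale=scale)

    def forward(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, float) - self.shift) / self.scale

    def scale_spec(self, spec: SplineSpec) -> SplineSpec:
        return SplineSpec(
            degree=spec.degree,
            knots=self.forward(spec.knots),
            knot_rule=spec.knot_rule,
        )


def _poly_backmap(p: int, shift: float, scale: float) -> np.ndarray:
    """Matrix B with beta_raw = B @ beta_scaled for f = sum beta_s ((t-a)/c)^j."""
    B = np.zeros((p + 1, p + 1))
    for j in range(p + 1):
        for m_ in range(j + 1):
            B[m_, j] = math.comb(j, m_) * (-shift) ** (j - m_) / scale**j
    return B


# ---------------------------------------------------------------------------
# public fit / predict
# ---------------------------------------------------------------------------

@dataclass
class PenalizedFit:
    """A fitted penalized spline for a single condition's trace(s).

    Coefficients ``beta`` and ``u`` are reported in the raw time
    parameterization (minutes); the internal scaled representation used for
    prediction is kept alongside for numerical stability.
    """

    spec: SplineSpec
    beta: np.ndarray
    u: np.ndarray
    sigma2_u: float
    sigma2_eps: float
    lam: float
    fitted: np.ndarray
    times: np.ndarray
    n_obs: int
    polynomial_limit: bool      # sigma_u^2 effectively 0: degree-p polynomial
    axis: AxisScale
    _scaled_spec: SplineSpec
    _theta: np.ndarray          # coefficients on the scaled axis
    _cov: np.ndarray            # joint covariance of scaled (beta, u)

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([self.beta, self.u])

    def design_matrix(self, times: np.ndarray, deriv_order: int = 0) -> np.ndarray:
        """Raw-parameterization design (polynomial block | truncated block)."""
        P, T = truncated_basis(times, self.spec, deriv_order, check_range=False)
        return np.hstack([P, T])


@dataclass
class CurveEstimate:
    """A curve (or derivative) on a grid with pointwise confidence bands."""

    grid: np.ndarray
    deriv_order: int
    estimate: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.grid,
                "estimate": self.estimate,
                "se": self.se,
                "lo": self.lower,
                "hi": self.upper,
            }
        )


def _extract_xy(data) -> tuple[np.ndarray, np.ndarray]:
    """Pull (times, response) from arrays, a DataFrame, or a dataset."""
    import pandas as pd

    if isinstance(data, tuple) and len(data) == 2:
        t, y = (np.asarray(v, float).ravel() for v in data)
        return t, y
    df = getattr(data, "df", data)
    if isinstance(df, pd.DataFrame):
        for cond_col in ("dose", "group"):
            if cond_col in df.columns and df[cond_col].nunique() > 1:
                raise ValueError(
                    f"fit_penalized_spline expects a single condition; column "
                    f"{cond_col!r} has {df[cond_col].nunique()} levels — use "
                    "fit_dose_model for multi-condition data"
                )
        tcol = "time_min" if "time_min" in df.columns else "time"
        ycol = "aggregation_pct" if "aggregation_pct" in df.columns else "aggregation"
        return df[tcol].to_numpy(float), df[ycol].to_numpy(float)
    raise TypeError(f"unsupported data type {type(data)!r}")


def fit_penalized_spline(
    data,
    spec: SplineSpec | None = None,
    *,
    knots: int | str = "auto",
    degree: int = 5,
    smoothing: float | str = "reml",
) -> PenalizedFit:
    """Fit a penalized truncated power spline to one condition's trace(s).

    ``data`` is ``(times, values)`` arrays or a long-format DataFrame
    restricted to a single dose x group condition (replicate traces are
    pooled; duplicate time points are treated as replicate observations).
    With ``spec=None`` a degree-``degree`` spline with ``knots`` quantile
    knots is used.  ``smoothing`` selects REML (default), ML, or a fixed
    penalty ``lambda``.
    """
    t, y = _extract_xy(data)
    if t.size != y.size:
        raise ValueError("times and responses differ in length")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if spec is None:
        spec = default_knots(t, K=knots, degree=degree)
    if t.size < spec.n_basis + 2:
        raise ValueError(
            f"need at least {spec.n_basis + 2} observations for this basis, got {t.size}"
        )

    axis = AxisScale.from_data(t)
    sspec = axis.scale_spec(spec)
    s = axis.forward(t)
    P, T = truncated_basis(s, sspec, 0, check_range=False)
    # a fixed lambda refers to the raw parameterization; the internal
    # scaled basis has u_scaled = u_raw * scale^p, so the equivalent
    # internal penalty is lambda / scale^(2p)
    lam_factor = axis.scale ** (2 * spec.degree)
    internal_smoothing = (
        smoothing if isinstance(smoothing, str) else float(smoothing) / lam_factor
    )
    res = solve_mixed_model(P, T, y, smoothing=internal_smoothing)

    if res.at_boundary and res.lam > 1.0:
        warnings.warn(
            "sigma_u^2 estimated at (numerically) zero; the fit is a degree-"
            f"{spec.degree} polynomial",
            stacklevel=2,
        )

    p = spec.degree
    B = _poly_backmap(p, axis.shift, axis.scale)
    beta_raw = B @ res.fixed
    u_raw = res.random / axis.scale**p
    fitted = np.hstack([P, T]) @ res.theta  # same evaluation path as predict_curve

    return PenalizedFit(
        spec=spec,
        beta=beta_raw,
        u=u_raw,
        sigma2_u=res.sigma2_u / lam_factor,
        sigma2_eps=res.sigma2_eps,
        lam=res.lam * lam_factor,
        fitted=fitted,
        times=t,
        n_obs=res.n_obs,
        polynomial_limit=bool(res.at_boundary and res.lam > 1.0),
        axis=axis,
        _scaled_spec=sspec,
        _theta=res.theta,
        _cov=res.cov,
    )


def predict_curve(
    fit: PenalizedFit,
    grid: np.ndarray,
    deriv_order: int = 0,
    level: float = 0.95,
) -> CurveEstimate:
    """Evaluate the fitted curve or a derivative with pointwise bands.

    ``deriv_order`` 0/1/2 gives the mean curve, the velocity (first
    derivative) and the acceleration (second derivative).  Bands are
    symmetric normal-quantile intervals from the joint covariance of the
    coefficients, conditional on the estimated variance components.
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("prediction grid is empty")
    m = int(deriv_order)
    if m not in (0, 1, 2):
        raise ValueError(f"deriv_order must be 0, 1 or 2, got {deriv_order}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    lo, hi = fit.times.min(), fit.times.max()
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        warnings.warn(
            f"grid extends outside the training range [{lo:g}, {hi:g}]; "
            "extrapolated spline values are unreliable",
            stacklevel=2,
        )

    s = fit.axis.forward(grid)
    P, T = truncated_basis(s, fit._scaled_spec, m, check_range=False)
    C = np.hstack([P, T])
    scale = fit.axis.scale ** (-m)
    est = scale * (C @ fit._theta)
    var = np.einsum("ij,jk,ik->i", C, fit._cov, C)
    se = scale * np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return CurveEstimate(
        grid=grid,
        deriv_order=m,
        estimate=est,
        se=se,
        lower=est - z * se,
        upper=est + z * se,
        level=level,
    )
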