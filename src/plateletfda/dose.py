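"""Multi-condition functional dose model and the nanoparticle contrast.

All conditions (dose x group cells) are fitted jointly: the mean response
of condition ``d`` at time ``t`` is

    l_d(t) = f_1(t) + f_d(t),   d = 2..D,   l_1 = f_1,

where ``f_1`` is the curve of the reference condition (the lowest
agonist-only dose) and each deviation curve ``f_d`` is a penalized spline
sharing the reference's degree and knots.  Indicator covariates select
which deviation applies to an observation; a single residual variance and
a single smoothing variance are shared across conditions.

Sharing the knots makes every condition curve, and hence every contrast
between conditions, a linear map of one coefficient vector, so pointwise
standard errors of the nanoparticle contrast

    h_s(t) = l_{NP pair of s}(t) - l_{agonist pair of s}(t)

propagate directly from the joint coefficient covariance.  The overall
nanoparticle effect is the arithmetic mean of the per-dose contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .basis import SplineSpec, default_knots, truncated_basis
from .simulate import AGONIST_ONLY, AGONIST_PLUS_NP
from .splines import AxisScale, CurveEstimate, solve_mixed_model

__all__ = [
    "DoseModelFit",
    "NanoEffect",
    "fit_dose_model",
    "estimate_nano_effect",
    "default_pairing",
    "nano_effect_plot",
]

Condition = tuple[float, str]


def _condition_order(conditions: list[Condition]) -> list[Condition]:
    """Agonist-only doses ascending, then nanoparticle doses ascending."""
    rank = {AGONIST_ONLY: 0, AGONIST_PLUS_NP: 1}
    return sorted(conditions, key=lambda c: (rank.get(c[1], 2), c[0]))


@dataclass
class DoseModelFit:
    """Joint penalized-spline fit of all dose x group condition curves."""

    conditions: list[Condition]     # ordered; conditions[0] is the reference
    spec: SplineSpec
    axis: AxisScale
    theta: np.ndarray               # stacked (all beta blocks, all u blocks)
    cov: np.ndarray                 # joint covariance of theta
    sigma2_eps: float
    sigma2_u: float
    lam: float
    n_obs: int
    train_range: tuple[float, float]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def _dims(self) -> tuple[int, int]:
        return self.spec.degree + 1, self.spec.n_knots

    def _index(self, condition: Condition | int) -> int:
        if isinstance(condition, int):
            if not 0 <= condition < self.n_conditions:
                raise KeyError(f"condition index {condition} out of range")
            return condition
        cond = (float(condition[0]), str(condition[1]))
        try:
            return self.conditions.index(cond)
        except ValueError:
            raise KeyError(
                f"condition {cond!r} not in fit; available: {self.conditions}"
            ) from None

    def _rows(self, grid: np.ndarray, deriv_order: int = 0) -> tuple[np.ndarray, np.ndarray]:
        s = self.axis.forward(grid)
        sspec = self.axis.scale_spec(self.spec)
        return truncated_basis(s, sspec, deriv_order, check_range=False)

    def _condition_design(self, condition, grid, deriv_order=0) -> np.ndarray:
        """Full design rows of l_d on the grid (baseline block + block d)."""
        d = self._index(condition)
        P, T = self._rows(grid, deriv_order)
        nb, K = self._dims
        D = self.n_conditions
        C = np.zeros((len(P), D * nb + D * K))
        C[:, :nb] = P
        C[:, D * nb : D * nb + K] = T
        if d > 0:
            C[:, d * nb : (d + 1) * nb] += P
            C[:, D * nb + d * K : D * nb + (d + 1) * K] += T
        return C

    def predict_condition(
        self, condition, grid, deriv_order: int = 0, level: float = 0.95
    ) -> CurveEstimate:
        """Total curve l_d (or its derivative) with pointwise bands."""
        grid = np.atleast_1d(np.asarray(grid, float))
        C = self._condition_design(condition, grid, deriv_order)
        return self._linear_estimate(C, grid, deriv_order, level)

    def contrast(
        self, minuend, subtrahend, grid, deriv_order: int = 0, level: float = 0.95
    ) -> CurveEstimate:
        """l_minuend - l_subtrahend with propagated pointwise SEs."""
        grid = np.atleast_1d(np.asarray(grid, float))
        C = self._condition_design(minuend, grid, deriv_order) - self._condition_design(
            subtrahend, grid, deriv_order
        )
        return self._linear_estimate(C, grid, deriv_order, level)

    def _linear_estimate(self, C, grid, deriv_order, level) -> CurveEstimate:
        scale = self.axis.scale ** (-deriv_order)
        est = scale * (C @ self.theta)
        var = np.einsum("ij,jk,ik->i", C, self.cov, C)
        se = scale * np.sqrt(np.maximum(var, 0.0))
        z = stats.norm.ppf(0.5 + level / 2.0)
        return CurveEstimate(
            grid=grid,
            deriv_order=deriv_order,
            estimate=est,
            se=se,
            lower=est - z * se,
            upper=est + z * se,
            level=level,
        )


def fit_dose_model(
    dataset,
    spec: SplineSpec | None = None,
    *,
    knots: int | str = "auto",
    degree: int = 5,
    smoothing: float | str = "reml",
) -> DoseModelFit:
    """Fit the indicator dose model jointly over all conditions.

    The reference condition (no indicator) is the lowest dose of the
    agonist-only group; each other condition contributes a deviation curve
    with the same shared knots.  A single condition degenerates to an
    ordinary penalized-spline fit with no deviation curves.
    """
    df = dataset.df if hasattr(dataset, "df") else dataset
    conditions = _condition_order(
        [
            (float(d), str(g))
            for d, g in df[["dose", "group"]].drop_duplicates().to_numpy()
        ]
    )
    D = len(conditions)
    t_all = df["time_min"].to_numpy(float)
    if spec is None:
        spec = default_knots(t_all, K=knots, degree=degree)
    nb, K = spec.degree + 1, spec.n_knots

    axis = AxisScale.from_data(t_all)
    sspec = axis.scale_spec(spec)

    # per-condition time coverage check
    min_needed = nb + K + 2
    for cond in conditions:
        n_c = int(((df["dose"] == cond[0]) & (df["group"] == cond[1])).sum())
        if n_c < min_needed:
            raise ValueError(
                f"condition {cond!r} has {n_c} observations, fewer than the "
                f"basis dimension + 2 = {min_needed}"
            )

    n = len(df)
    X = np.zeros((n, D * nb))
    Z = np.zeros((n, D * K))
    y = df["aggregation_pct"].to_numpy(float)
    for d, cond in enumerate(conditions):
        sel = ((df["dose"] == cond[0]) & (df["group"] == cond[1])).to_numpy()
        P, T = truncated_basis(axis.forward(t_all[sel]), sspec, 0, check_range=False)
        X[sel, :nb] = P
        Z[sel, :K] = T
        if d > 0:
            X[sel, d * nb : (d + 1) * nb] = P
            Z[sel, d * K : (d + 1) * K] = T

    lam_factor = axis.scale ** (2 * spec.degree)
    internal_smoothing = (
        smoothing if isinstance(smoothing, str) else float(smoothing) / lam_factor
    )
    res = solve_mixed_model(X, Z, y, smoothing=internal_smoothing)
    return DoseModelFit(
        conditions=conditions,
        spec=spec,
        axis=axis,
        theta=res.theta,
        cov=res.cov,
        sigma2_eps=res.sigma2_eps,
        sigma2_u=res.sigma2_u / lam_factor,
        lam=res.lam * lam_factor,
        n_obs=n,
        train_range=(float(t_all.min()), float(t_all.max())),
    )


@dataclass
class NanoEffect:
    """Per-dose nanoparticle contrast curves and their overall mean."""

    grid: np.ndarray
    labels: list[str]               # one per pair, e.g. "dose 0.8"
    curves: np.ndarray              # shape (S, G)
    ses: np.ndarray | None          # same shape, or None
    overall: np.ndarray             # mean over S at each grid point (exact)
    overall_se: np.ndarray | None
    pairing: dict
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.grid}
        for lab, row in zip(self.labels, self.curves):
            data[lab] = row
        data["overall"] = self.overall
        if self.ses is not None:
            for lab, row in zip(self.labels, self.ses):
                data[f"se[{lab}]"] = row
            data["se[overall]"] = self.overall_se
        return pd.DataFrame(data)


def default_pairing(fit: DoseModelFit) -> dict:
    """Pair each dose's agonist-only condition with its nanoparticle twin."""
    ag = {c[0] for c in fit.conditions if c[1] == AGONIST_ONLY}
    np_ = {c[0] for c in fit.conditions if c[1] == AGONIST_PLUS_NP}
    shared = sorted(ag & np_)
    if not shared:
        raise ValueError(
            "no dose occurs in both groups; supply an explicit pairing"
        )
    return {
        s + 1: ((d, AGONIST_ONLY), (d, AGONIST_PLUS_NP))
        for s, d in enumerate(shared)
    }


def estimate_nano_effect(
    fit: DoseModelFit,
    pairing: dict | None = None,
    grid: np.ndarray | None = None,
    *,
    compute_se: bool = True,
    level: float = 0.95,
) -> NanoEffect:
    """Contrast curves h_s = l_NP - l_agonist and their overall mean.

    ``pairing`` maps an arbitrary key per dose level to a pair
    ``(agonist condition, NP condition)``; by default equal doses across
    the two groups are paired.  The overall curve is the exact arithmetic
    mean of the per-pair contrasts; SEs are propagated from the joint
    coefficient covariance (contrasts do not involve the baseline block,
    so they are invariant to the choice of reference condition).
    """
    if pairing is None:
        pairing = default_pairing(fit)
    if not pairing:
        raise ValueError("pairing must cover at least one dose level")
    if grid is None:
        grid = np.linspace(*fit.train_range, 200)
    grid = np.atleast_1d(np.asarray(grid, float))

    labels, rows, se_rows = [], [], []
    design_rows = []
    for key, (cond_ag, cond_np) in sorted(pairing.items(), key=lambda kv: str(kv[0])):
        est = fit.contrast(cond_np, cond_ag, grid, level=level)
        labels.append(f"dose {key}" if not isinstance(key, str) else key)
        rows.append(est.estimate)
        se_rows.append(est.se)
        design_rows.append(
            fit._condition_design(cond_np, grid) - fit._condition_design(cond_ag, grid)
        )
    curves = np.vstack(rows)
    overall = curves.mean(axis=0)
    overall_se = None
    ses = np.vstack(se_rows) if compute_se else None
    if compute_se:
        Cbar = np.mean(design_rows, axis=0)
        var = np.einsum("ij,jk,ik->i", Cbar, fit.cov, Cbar)
        overall_se = np.sqrt(np.maximum(var, 0.0))
    return NanoEffect(
        grid=grid,
        labels=labels,
        curves=curves,
        ses=ses,
        overall=overall,
        overall_se=overall_se,
        pairing=dict(pairing),
        level=level,
    )


def nano_effect_plot(
    effect: NanoEffect,
    baseline_label: str,
    csv_path: str | Path | None = None,
    png_path: str | Path | None = None,
):
    """Plot the per-dose contrasts (dotted), their mean (solid) and a zero line.

    ``baseline_label`` names the reference condition the contrasts are read
    against and must match one of the effect's labels or ``"overall"``.
    Returns ``(figure, frame)``; the frame is the CSV twin of the plotted
    values and is written to ``csv_path`` when given.
    """
    known = set(effect.labels) | {"overall"}
    if baseline_label not in known:
        raise ValueError(
            f"unknown baseline label {baseline_label!r}; expected one of {sorted(known)}"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for lab, row in zip(effect.labels, effect.curves):
        ax.plot(effect.grid, row, linestyle=":", label=lab)
    ax.plot(effect.grid, effect.overall, color="black", lw=2, label="overall mean")
    ax.axhline(0.0, color="gray", lw=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"excess aggregation vs {baseline_label} (%)")
    ax.set_title("Nanoparticle effect")
    ax.legend(fontsize=8)
    frame = effect.to_frame()
    if csv_path is not None:
        Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(csv_path, index=False)
    if png_path is not None:
        Path(png_path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return fig, frame
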