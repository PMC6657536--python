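"""Synthetic aggregometry traces.

Optical aggregometry of platelet-rich plasma records percent aggregation
over roughly 6-7 minutes after agonist (ADP) addition.  Real traces rise
steeply (more steeply, and higher, at higher ADP dose), then either decay
back (de-aggregation of unstable micro-aggregates at low dose), plateau,
or climb in staircase-like steps with small fluctuations.  This module
generates curve families with those shapes plus i.i.d. Gaussian
observation noise — the additive signal-plus-noise structure the smoothing
model assumes — and closed-form ODE solutions used as oracles by the
phase-plane module.

The noiseless signals are infinitely differentiable within each family's
smooth segments (the staircase is built from logistic steps and a damped
sinusoid rather than hard switches), matching the smoothness assumption of
the functional model.  Percent values are deliberately not clipped to
[0, 100] after noise addition: clipping would break the additive-noise
model the estimators rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurveFamilyParams",
    "NPEffect",
    "DoseDesign",
    "simulate_curve",
    "simulate_dataset",
    "simulate_from_phase_law",
    "adp_dose_presets",
    "FAMILIES",
]

#: Recognized curve families.
FAMILIES = ("saturating", "rise_decay", "staircase", "linear_ode", "logistic_ode")

#: Default grid: 400 samples over 7 minutes (the assay length; instrument
#: sampling rates vary, so the density is a package choice).
DEFAULT_DURATION = 7.0
DEFAULT_N_POINTS = 400

AGONIST_ONLY = "agonist_only"
AGONIST_PLUS_NP = "agonist_plus_np"


@dataclass(frozen=True)
class CurveFamilyParams:
    """Parameters of one noiseless signal family plus observation noise.

    Families
    --------
    saturating
        ``A (1 - e^{-k t})`` — monotone rise to a plateau ``A`` (percent),
        the high-dose shape.
    rise_decay
        Biexponential ``(e^{-lam2 t} - e^{-lam1 t})`` scaled to peak height
        ``A`` — rise then de-aggregation decay (low dose); needs
        ``lam1 > lam2``.
    staircase
        Logistic steps up to the levels in ``plateau_levels`` at
        ``transition_times`` (steepness ``k``), plus a damped sinusoidal
        fluctuation of amplitude ``A``, frequency ``lam1`` cycles/min and
        damping ``lam2`` per min.  Smooth everywhere.
    linear_ode
        Solution of ``dy/dt = k (A - y)`` from ``y0``: exponential
        relaxation to ``A``.
    logistic_ode
        Solution of ``dy/dt = k y (1 - y/A)`` from ``y0 > 0``.

    ``noise_sd`` is the standard deviation of the additive Gaussian
    observation noise (percent aggregation).  ``ar1`` optionally gives the
    noise lag-1 autocorrelation (marginal SD still ``noise_sd``); it is 0
    by default because the signal-plus-noise model assumes independent
    errors.
    """

    family: str
    amplitude: float = 50.0
    k: float = 1.5
    lam1: float = 3.0
    lam2: float = 0.4
    plateau_levels: tuple[float, ...] = ()
    transition_times: tuple[float, ...] = ()
    y0: float = 0.0
    noise_sd: float = 1.0
    ar1: float = 0.0
    duration: float = DEFAULT_DURATION
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown curve family {self.family!r}; expected one of {FAMILIES}"
            )
        if not 0.0 <= self.amplitude <= 100.0:
            raise ValueError(f"amplitude must be in [0, 100], got {self.amplitude}")
        for name in ("k", "lam1", "lam2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be > 0")
        if self.family == "rise_decay" and self.lam1 <= self.lam2:
            raise ValueError(
                f"rise_decay needs lam1 > lam2, got lam1={self.lam1}, lam2={self.lam2}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError(f"ar1 must be in (-1, 1), got {self.ar1}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.family == "staircase":
            if len(self.plateau_levels) != len(self.transition_times):
                raise ValueError("plateau_levels and transition_times must pair up")
            if not self.plateau_levels:
                raise ValueError("staircase needs at least one plateau level")
            tt = np.asarray(self.transition_times, float)
            if np.any(tt <= 0) or np.any(tt >= self.duration):
                raise ValueError(
                    f"transition times must lie strictly inside (0, {self.duration})"
                )
            if np.any(np.diff(tt) <= 0):
                raise ValueError("transition times must be strictly increasing")
        if self.family == "logistic_ode" and self.y0 <= 0:
            raise ValueError("logistic_ode needs y0 > 0")


def signal(params: CurveFamilyParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the noiseless signal of a family on arbitrary times."""
    t = np.asarray(t, float)
    A, k = params.amplitude, params.k
    if params.family == "saturating":
        return A * (1.0 - np.exp(-k * t))
    if params.family == "rise_decay":
        l1, l2 = params.lam1, params.lam2
        raw = np.exp(-l2 * t) - np.exp(-l1 * t)
        t_peak = math.log(l1 / l2) / (l1 - l2)
        peak = math.exp(-l2 * t_peak) - math.exp(-l1 * t_peak)
        return A * raw / peak
    if params.family == "staircase":
        levels = np.asarray(params.plateau_levels, float)
        increments = np.diff(np.concatenate([[0.0], levels]))
        out = np.zeros_like(t)
        for inc, c in zip(increments, params.transition_times):
            out = out + inc / (1.0 + np.exp(-k * (t - c)))
        ripple = A * np.exp(-params.lam2 * t) * np.sin(2.0 * np.pi * params.lam1 * t)
        return out + ripple
    if params.family == "linear_ode":
        return A + (params.y0 - A) * np.exp(-k * t)
    if params.family == "logistic_ode":
        y0 = params.y0
        return A / (1.0 + (A - y0) / y0 * np.exp(-k * t))
    raise ValueError(f"unknown curve family {params.family!r}")  # pragma: no cover


def _noise(rng: np.random.Generator, sd: float, ar1: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    if ar1 == 0.0:
        return rng.normal(0.0, sd, n)
    # AR(1) with stationary marginal SD = sd
    innov_sd = sd * math.sqrt(1.0 - ar1 * ar1)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        eps[i] = ar1 * eps[i - 1] + shocks[i - 1]
    return eps


def simulate_curve(params: CurveFamilyParams, seed: int | None = None) -> pd.DataFrame:
    """Simulate one trace: equally spaced grid over [0, duration] plus noise.

    Identical ``(params, seed)`` reproduce the table bit-for-bit; with
    ``noise_sd=0`` the output does not depend on the seed at all.
    """
    t = np.linspace(0.0, params.duration, params.n_points)
    f = signal(params, t)
    rng = np.random.default_rng(seed)
    y = f + _noise(rng, params.noise_sd, params.ar1, t.size)
    return pd.DataFrame({"time_min": t, "aggregation_pct": y})


@dataclass(frozen=True)
class NPEffect:
    """Additive smooth nanoparticle enhancement of the aggregation signal.

    ``shape="exp"``: ``amplitude * (1 - e^{-rate t})`` (onset ignored,
    smooth everywhere).  ``shape="logistic"``: ``amplitude / (1 +
    e^{-rate (t - onset)})`` — a smooth delayed switch-on near ``onset``
    minutes.
    """

    amplitude: float = 0.0
    rate: float = 2.0
    onset: float = 0.0
    shape: str = "exp"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"np_effect amplitude must be >= 0, got {self.amplitude}")
        if self.rate <= 0:
            raise ValueError("np_effect rate must be > 0")
        if self.shape not in ("exp", "logistic"):
            raise ValueError(f"np_effect shape must be 'exp' or 'logistic', got {self.shape!r}")

    def offset(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if self.amplitude == 0.0:
            return np.zeros_like(t)
        if self.shape == "exp":
            return self.amplitude * (1.0 - np.exp(-self.rate * t))
        return self.amplitude / (1.0 + np.exp(-self.rate * (t - self.onset)))


@dataclass(frozen=True)
class DoseDesign:
    """Dose x group x replicate layout of a simulated experiment.

    ``dose_labels`` are strictly increasing dose values (treated as ordered
    labels; the assay's dose units are left to the caller).  ``groups`` is
    any subset of {agonist_only, agonist_plus_np}; traces in the
    nanoparticle group receive the ``np_effect`` offset additively on the
    noiseless signal.
    """

    dose_labels: tuple[float, ...]
    groups: tuple[str, ...] = (AGONIST_ONLY,)
    np_effect: NPEffect = field(default_factory=NPEffect)
    replicates: int = 1

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_labels, float)
        if d.size < 1:
            raise ValueError("at least one dose label is required")
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"dose labels must be strictly increasing, got {list(d)}")
        for g in self.groups:
            if g not in (AGONIST_ONLY, AGONIST_PLUS_NP):
                raise ValueError(f"unknown group {g!r}")
        if len(set(self.groups)) != len(self.groups) or not self.groups:
            raise ValueError("groups must be a non-empty set of distinct labels")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


def simulate_dataset(
    design: DoseDesign,
    base_params_by_dose: dict[float, CurveFamilyParams],
    seed: int | None = None,
):
    """Simulate a full dose x group x replicate experiment.

    Returns an :class:`~plateletfda.datasets.AggregationDataset` in the
    long format (subject_id, dose, group, time_min, aggregation_pct), one
    trace per cell.  The nanoparticle group's noiseless signal is the
    agonist-only signal plus the design's smooth offset; noise is then
    added independently per trace.
    """
    from .datasets import AggregationDataset

    for dose in design.dose_labels:
        if dose not in base_params_by_dose:
            raise KeyError(f"no curve parameters supplied for dose {dose!r}")

    ss = np.random.SeedSequence(seed)
    n_cells = len(design.dose_labels) * len(design.groups) * design.replicates
    children = ss.spawn(n_cells)
    frames = []
    idx = 0
    for dose in design.dose_labels:
        params = base_params_by_dose[dose]
        t = np.linspace(0.0, params.duration, params.n_points)
        base = signal(params, t)
        for group in design.groups:
            f = base + design.np_effect.offset(t) if group == AGONIST_PLUS_NP else base
            for rep in range(design.replicates):
                rng = np.random.default_rng(children[idx])
                idx += 1
                y = f + _noise(rng, params.noise_sd, params.ar1, t.size)
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": f"d{dose:g}_{group}_r{rep + 1}",
                            "dose": dose,
                            "group": group,
                            "time_min": t,
                            "aggregation_pct": y,
                        }
                    )
                )
    return AggregationDataset(pd.concat(frames, ignore_index=True))


def simulate_from_phase_law(
    gamma0: float,
    gamma1: float,
    y0: float = 0.0,
    duration: float = DEFAULT_DURATION,
    n_points: int = DEFAULT_N_POINTS,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a trace whose signal solves ``dy/dt = gamma0 + gamma1 y``.

    The noiseless signal is the exact solution

        y(t) = -gamma0/gamma1 + (y0 + gamma0/gamma1) e^{gamma1 t},

    the oracle for linear phase-plane reconstruction (fixed point at
    ``-gamma0/gamma1``, stable iff ``gamma1 < 0``).
    """
    if gamma1 == 0.0:
        raise ValueError(
            "gamma1 must be nonzero (a gamma1=0 law is a linear ramp; use the "
            "saturating or linear_ode families instead)"
        )
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    t = np.linspace(0.0, duration, n_points)
    ystar = -gamma0 / gamma1
    f = ystar + (y0 - ystar) * np.exp(gamma1 * t)
    rng = np.random.default_rng(seed)
    y = f + _noise(rng, noise_sd, 0.0, t.size)
    return pd.DataFrame({"time_min": t, "aggregation_pct": y})


def adp_dose_presets(
    dose_labels=(0.2, 0.4, 0.8, 1.2, 1.32, 1.36),
    noise_sd: float = 1.0,
    duration: float = DEFAULT_DURATION,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[float, CurveFamilyParams]:
    """Dose-indexed parameters emulating an ADP titration.

    Low doses give rise-then-decay (de-aggregation) shapes of modest
    height; amplitude and initial steepness grow with dose; the top doses
    saturate monotonically — the qualitative dose trend seen in optical
    aggregometry.
    """
    doses = np.asarray(dose_labels, float)
    n = doses.size
    out: dict[float, CurveFamilyParams] = {}
    for i, d in enumerate(doses):
        frac = i / max(n - 1, 1)
        amp = 10.0 + 70.0 * frac
        rate = 0.8 + 1.2 * frac
        common = dict(
            amplitude=amp, noise_sd=noise_sd, duration=duration, n_points=n_points
        )
        if frac < 0.5:
            out[float(d)] = CurveFamilyParams(
                family="rise_decay", lam1=2.0 + 2.0 * frac, lam2=0.3, k=rate, **common
            )
        else:
            out[float(d)] = CurveFamilyParams(family="saturating", k=rate, **common)
    return out
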