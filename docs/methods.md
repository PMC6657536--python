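# Methods

## Signal model and smoothing

A trace is modeled as `y(t_i) = f(t_i) + ε_i` with `f` twice continuously
differentiable and `ε_i` i.i.d. `N(0, σ²_ε)`. `f` is expanded in a
truncated power basis of degree p with K interior knots,

    f(t) = Σ_{j=0..p} β_j t^j + Σ_{k=1..K} u_k (t − κ_k)₊^p,

where `(x)₊^p = x^p` for x > 0 and 0 otherwise; the value at x = 0 is
defined as the continuous limit 0. The default degree is p = 5 so that the
fitted curve and its first two derivatives are themselves smooth splines
(degree 4 and 3 across knots).

The truncated-block coefficients are treated as random effects,
`u_k ~ N(0, σ²_u)` — the standard mixed-model formulation of penalized
splines. The implied smoothing parameter is λ = σ²_ε/σ²_u; both variance
components are estimated by REML (profiled over log λ; an ML option
exists), and (β, û) solve the mixed-model/generalized-ridge equations at
the estimated λ, i.e. they are the BLUP. A fixed numeric λ can be supplied
instead, and it always refers to the raw time parameterization.

Derivatives of order m ∈ {1, 2} replace each basis column by its exact
calculus derivative: `t^j → j!/(j−m)! · t^(j−m)` and
`(t−κ)₊^p → p!/(p−m)! · (t−κ)₊^(p−m)`. Because the coefficient vector is
unchanged, velocity and acceleration estimates and their standard errors
are linear maps of the same fit.

### Knots and defaults

Knots sit at the k/(K+1) quantiles of the distinct observed predictor
values, with `K = min(⌊n_distinct/4⌋, 35)` by default — deliberately
over-provisioned, with λ doing the actual smoothing. Duplicate time points
are allowed and treated as replicate observations. Traces of multiple
replicates within one condition are pooled into a single fit.

### Numerics

Raw degree-5 powers of minutes are badly conditioned, so fitting happens on
an affinely rescaled axis s = (t − t_min)/range ∈ [0, 1]; the REML search
uses Woodbury identities (all solves K×K), and the final coefficient solve
uses QR on the augmented system [C; √λ·D] to avoid squaring the condition
number. Coefficients are mapped back to the raw parameterization exactly
(binomial expansion for the polynomial block, range^−p scaling for the
truncated block). The λ search runs over log λ ∈ [−25, 25]; hitting the
upper boundary means σ²_u ≈ 0 and the fit degenerates to a degree-p
polynomial, which is flagged, not an error.

### Confidence bands

Bands are pointwise, symmetric normal-quantile intervals using the joint
"Bayesian" covariance `σ²_ε (CᵀC + λD)⁻¹`, conditional on the estimated
variance components. Smoothing-parameter uncertainty is ignored, so
coverage is expected to sit somewhat below nominal, particularly near the
range ends; the acceptance suite measures interior coverage of roughly 93%
for nominal 95% bands in the simulation conditions used there.

## Dose model and nanoparticle contrast

With conditions d = 1..D (agonist-only doses ascending, then
agonist+nanoparticle doses ascending), the joint model is

    y_d(t) = f₁(t) + Σ_{d≥2} I_d f_d(t) + ε,

with f₁ the curve of the reference condition (lowest agonist-only dose) and
f_d deviation splines sharing the reference's degree and knots. Design
choices: a single shared residual variance σ²_ε and a single shared
smoothing variance σ²_u across all curves. One smoothing variance keeps the
REML search one-dimensional and treats every deviation curve with equal
prior roughness; per-curve smoothing would add D−1 variance parameters that
the modest per-condition sample sizes here do not support.

The nanoparticle contrast pairs each dose's two groups:
`ĥ_s(t) = l̂_NP(s)(t) − l̂_ADP(s)(t)` with `l_d = f₁ + f_d`. Since shared
knots make each `l_d` a linear map of one coefficient vector, contrast
standard errors propagate directly from the joint covariance. The baseline
block cancels in every contrast, so contrasts are invariant to the choice
of reference condition at fixed coefficients; refitting under a different
reference changes the penalty's parameterization slightly, so invariance
under refitting is approximate (asserted within 0.5% aggregation on dense
low-noise data). The overall effect is the exact arithmetic mean of the
per-dose contrasts.

## Phase-plane reconstruction

Phase points pair the deriv-0 and deriv-1 predictions at identical times,
taken on the training-time grid with 5% of the time range trimmed at each
end (spline derivative estimates are least reliable at the boundaries; the
trim fraction is a parameter).

The linear law `dy/dt = γ₀ + γ₁y + e` is ordinary least squares of
velocity on aggregation (γ₀ intercept, %/min; γ₁ slope, 1/min). Reported
statistics: coefficient SEs, residual variance τ², and adjusted R² via the
one-predictor formula `1 − (1−R²)(n−1)/(n−2)`, reported both raw and
clipped below at 0 (the reporting convention for poorly fitting low-dose
conditions). Because the regressors are themselves smoothed estimates on a
grid, their errors are serially correlated; the OLS standard errors ignore
this and should be read as naive.

The smooth law `dy/dt = γ₀ + g(y) + e` reuses the penalized-spline
machinery with aggregation as the predictor (degree 5, knots at quantiles
of fitted aggregation, K = min(⌊n/4⌋, 20)). Steady states are located by a
sign-change scan of the fitted law on a 2001-point grid over the observed
aggregation range, refined by bisection until |law(y*)| < tolerance
(default 1e−6); stability comes from the sign of the numerically
differentiated law at the root (negative → stable), with roots whose slope
magnitude falls below 1e−6 flagged indeterminate. The linear law's fixed
point is −γ₀/γ₁ in closed form; γ₁ = 0 yields no finite fixed point and an
empty list with a warning. Roots outside the observed aggregation range are
never reported — the law is not trusted beyond the data.

## Synthetic data

The generator emulates the qualitative features of ADP aggregometry:

- **saturating** `A(1−e^(−kt))` — monotone high-dose aggregation;
- **rise_decay** — biexponential rise then de-aggregation decay (low dose),
  peak normalized to A at `t* = ln(λ₁/λ₂)/(λ₁−λ₂)`;
- **staircase** — logistic steps to successive plateaus plus an
  exponentially damped sinusoid, an infinitely differentiable stand-in for
  plateau/fluctuation shapes (hard switches would violate the smoothness
  the estimators assume);
- **linear_ode / logistic_ode** — exact ODE solutions used as oracles, plus
  `simulate_from_phase_law(γ₀, γ₁, y0)` for the linear law.

Noise is additive i.i.d. Gaussian on top of the noiseless signal, per the
signal-plus-noise model; an AR(1) option exists but is off by default since
the model assumes independent errors. Percent values are not clipped to
[0, 100] after noise addition — clipping would break additivity. Dose
designs put one trace per dose×group×replicate cell; the nanoparticle
group's signal is the agonist-only signal plus a smooth additive offset
(default `amp·(1−e^(−2t))`; a logistic shape with an onset parameter models
delayed effects). The default grid is 400 equally spaced samples over 7
minutes: assay duration is 6–7 minutes in this field, while instrument
sampling rates vary, so the density is a package choice, not a measured
constant.

What the generator does **not** emulate: within-trace autocorrelated noise
(by default), subject-level random effects and inter-individual variance
heterogeneity, receptor-level (P2Y1/P2Y12) mechanisms, platelet-count
dynamics, or raw optical-transmission artefacts. Passing tests therefore
demonstrate correctness of the estimators under the stated signal-plus-
noise model, not robustness to every feature of real aggregometer output.

## Problem sizes

The test suite and `scripts/acceptance.py` use trace lengths of 120–400
points, 2–10 conditions, 20 replicates for linear-ODE recovery, 100–200
replicates for calibration/coverage summaries (40 null replicates in the
acceptance script), and 20 random instances for the ridge-oracle
comparison — sizes at which the Monte-Carlo summaries are stable to well
within the asserted margins.

## Known limitations

- Bands are plug-in and pointwise; no simultaneous bands, no smoothing-
  parameter uncertainty.
- The dose model assumes a common residual variance across conditions
  (a per-condition option is provided through separate fits, not jointly).
- Phase-law inference treats smoothed values as data; SEs and R² inherit
  that optimism.
- No shape constraints (monotonicity, positivity) are imposed on any curve.
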