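# plateletfda

Functional data analysis of platelet aggregometry curves.

Optical (light-transmission) aggregometry records percent platelet
aggregation over ~6–7 minutes after an agonist such as ADP is added to
platelet-rich plasma. The traces are kinetically rich — a dose-dependent
initial rise, de-aggregation decay at low dose, plateaus and staircase-like
fluctuations — and single summary numbers (final aggregation, peak slope,
lag time) discard most of that structure. `plateletfda` treats the whole
trace as the response: it smooths curves nonparametrically, estimates their
velocity and acceleration with confidence bands, quantifies dose and
nanoparticle effects as contrasts between fitted curves, and reconstructs
the empirical kinetic law dy/dt = F(y) from the phase plane, including
steady states and their stability. It is aimed at platelet biologists and
biostatisticians analysing aggregometry time courses, and at
nanoparticle-safety studies that need to quantify how a perturbation shifts
an entire aggregation profile.

## Model

Each trace is `y(t) = f(t) + ε`, with `f` smooth and `ε ~ N(0, σ²_ε)`
i.i.d. The signal is written in a degree-p truncated power basis
(default p = 5),

```
f(t) = β₀ + β₁t + … + β_p t^p + Σ_k u_k (t − κ_k)₊^p ,
```

with knots κ₁ < … < κ_K at quantiles of the observed times. Treating the
u_k as random effects, `u_k ~ N(0, σ²_u)`, makes this a linear mixed model:
the implied ridge penalty λ = σ²_ε/σ²_u is estimated by REML and the fitted
curve is the BLUP of f. Velocity f′ and acceleration f″ are linear maps of
the same coefficients, so derivative estimates and their pointwise standard
errors come directly from the joint covariance of (β, u).

Multi-condition experiments (doses d = 1..D, with or without nanoparticles)
are fitted jointly as `y_d(t) = f₁(t) + Σ_{d≥2} I_d f_d(t)` with shared
knots, where f₁ is the lowest-dose reference curve and the f_d are
deviation splines. The nanoparticle effect at dose s is the contrast
`ĥ_s(t) = l̂_NP(s)(t) − l̂_ADP(s)(t)` between the paired fitted curves, and
the overall effect is the mean of the ĥ_s — the "nano effect plot".

For kinetics, the predicted velocity is regressed on the predicted
aggregation level: linearly (`dy/dt = γ₀ + γ₁y`, first-order kinetics;
fixed point −γ₀/γ₁, stable iff γ₁ < 0) or through a penalized spline in y
(`dy/dt = γ₀ + g(y)`), which can reveal multiple steady states
(bistability).

## Worked example

Simulate a high-dose-like trace whose true law is dy/dt = 120 − 1.5y
(so y(t) = 80(1 − e^(−1.5t))), smooth it, and recover the kinetics:

```python
import numpy as np
from plateletfda import (
    simulate_from_phase_law, fit_penalized_spline, predict_curve,
    phase_points, fit_linear_phase, find_steady_states,
)
from plateletfda.phase import trimmed_grid

trace = simulate_from_phase_law(120.0, -1.5, y0=0.0, noise_sd=0.5, seed=42)
fit = fit_penalized_spline(trace)
print(f"residual SD estimate: {fit.sigma2_eps ** 0.5:.3f} (true 0.5)")

vel = predict_curve(fit, np.array([0.5, 1.0, 2.0]), deriv_order=1)
for t, v, s in zip(vel.grid, vel.estimate, vel.se):
    print(f"velocity at t={t:.1f} min: {v:6.2f} +/- {s:.2f} %/min")

lin = fit_linear_phase(phase_points(fit, trimmed_grid(fit)))
print(f"gamma0 = {lin.gamma0:.2f} %/min   (true 120)")
print(f"gamma1 = {lin.gamma1:.3f} /min    (true -1.5)")
print(f"adjusted R^2 = {lin.adj_r2:.4f}")
(ystar, stability), = find_steady_states(lin)
print(f"steady state: {ystar:.2f} % aggregation ({stability}; true 80)")
```

Output:

```
residual SD estimate: 0.479 (true 0.5)
velocity at t=0.5 min:  57.04 +/- 0.21 %/min
velocity at t=1.0 min:  26.44 +/- 0.16 %/min
velocity at t=2.0 min:   6.15 +/- 0.12 %/min
gamma0 = 120.28 %/min   (true 120)
gamma1 = -1.504 /min    (true -1.5)
adjusted R^2 = 0.9998
steady state: 79.99 % aggregation (stable; true 80)
```

The velocity is the instantaneous aggregation rate; its decline toward zero
as y approaches the plateau is exactly the first-order relaxation the
linear phase law describes, and the OLS of velocity on aggregation recovers
the generating coefficients to well under 1%.

## Command line

```bash
plateletfda simulate -c design.yaml --seed 1 -o data.csv
plateletfda fit data.csv --dose 1.32 -o out/          # curve + derivatives
plateletfda dose-model data.csv -o out/
plateletfda nano-effect data.csv -o out/
plateletfda phase data.csv --dose 1.32 --law both -o out/
plateletfda run -c run.yaml                            # full pipeline
```

The `run` subcommand writes per-condition curve/velocity/acceleration CSVs,
the joint dose model, the nano-effect table and plot, phase-law
coefficients and fixed points, and a `manifest.json` recording inputs,
settings, seed and completed stages. Reruns with the same config and seed
produce byte-identical CSVs.

## Layout

- `plateletfda.simulate` — synthetic trace families, dose×group designs,
  phase-law oracles
- `plateletfda.basis` / `splines` — truncated power basis, REML/BLUP
  penalized-spline fit, derivative prediction with bands
- `plateletfda.dose` — joint indicator dose model, nanoparticle contrasts
- `plateletfda.phase` — phase points, linear/smooth laws, steady states
- `plateletfda.datasets` / `pipeline` / `cli` — CSV I/O, orchestration,
  command line
- `docs/methods.md` — modelling assumptions, defaults and limitations
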