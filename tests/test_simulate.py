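"""Generator: shapes, noise structure, determinism, and ODE oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from plateletfda.simulate import (
    AGONIST_ONLY,
    AGONIST_PLUS_NP,
    CurveFamilyParams,
    DoseDesign,
    NPEffect,
    adp_dose_presets,
    signal,
    simulate_curve,
    simulate_dataset,
    simulate_from_phase_law,
)


def make_params(family, **kw):
    base = dict(noise_sd=0.0, n_points=100)
    if family == "staircase":
        base.update(plateau_levels=(30.0, 60.0), transition_times=(1.5, 4.0), amplitude=2.0)
    base.update(kw)
    return CurveFamilyParams(family=family, **base)


class TestCurveFamilies:
    def test_unknown_family_rejected_with_name(self):
        with pytest.raises(ValueError, match="sigmoid"):
            CurveFamilyParams(family="sigmoid")

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            CurveFamilyParams(family="saturating", noise_sd=-1.0)

    @pytest.mark.parametrize(
        "kw, msg",
        [
            (dict(amplitude=150.0), "amplitude"),
            (dict(k=-1.0), "rate"),
            (dict(n_points=1), "n_points"),
        ],
    )
    def test_invalid_params_rejected(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            make_params("saturating", **kw)

    def test_rise_decay_needs_separated_rates(self):
        with pytest.raises(ValueError, match="lam1 > lam2"):
            make_params("rise_decay", lam1=0.3, lam2=0.4)

    def test_saturating_asymptote(self):
        p = make_params("saturating", amplitude=80.0, k=1.5)
        assert signal(p, np.array([1e3]))[0] == pytest.approx(80.0)

    def test_noiseless_output_seed_independent(self):
        for family in ("saturating", "rise_decay", "staircase", "linear_ode"):
            p = make_params(family)
            a = simulate_curve(p, seed=1)
            b = simulate_curve(p, seed=999)
            pd.testing.assert_frame_equal(a, b)

    def test_seed_determinism_bitwise(self):
        p = make_params("rise_decay", noise_sd=2.0)
        a = simulate_curve(p, seed=42)
        b = simulate_curve(p, seed=42)
        assert (a.to_numpy() == b.to_numpy()).all()
        c = simulate_curve(p, seed=43)
        assert not (a["aggregation_pct"].to_numpy() == c["aggregation_pct"].to_numpy()).all()

    def test_rise_decay_peak_location_matches_closed_form(self):
        lam1, lam2 = 3.0, 0.4
        p = make_params("rise_decay", amplitude=30.0, lam1=lam1, lam2=lam2)
        t = np.linspace(0.0, 7.0, 200_001)  # grid-search oracle
        f = signal(p, t)
        t_star = np.log(lam1 / lam2) / (lam1 - lam2)
        assert t[np.argmax(f)] == pytest.approx(t_star, abs=1e-4)
        assert f.max() == pytest.approx(30.0, rel=1e-9)  # peak normalized to A
        assert f[-1] < f.max()  # de-aggregation decay after the peak

    def test_staircase_is_smooth_and_reaches_levels(self):
        p = make_params("staircase", k=6.0)
        t = np.linspace(0.0, 7.0, 4001)
        f = signal(p, t)
        # second differences bounded -> no jumps in value or slope
        d2 = np.diff(f, 2) / np.diff(t)[0] ** 2
        assert np.all(np.isfinite(d2))
        assert np.abs(np.diff(f)).max() < 0.5  # no single-step jump
        assert f[-1] == pytest.approx(60.0, abs=3.0)

    def test_noise_conformity(self):
        sd = 2.5
        p = make_params("saturating", noise_sd=sd, n_points=20_000)
        df = simulate_curve(p, seed=7)
        resid = df["aggregation_pct"].to_numpy() - signal(p, df["time_min"].to_numpy())
        assert np.std(resid) == pytest.approx(sd, rel=0.05)

    def test_ar1_noise_keeps_marginal_sd(self):
        p = make_params("saturating", noise_sd=2.0, ar1=0.6, n_points=20_000)
        df = simulate_curve(p, seed=11)
        resid = df["aggregation_pct"].to_numpy() - signal(p, df["time_min"].to_numpy())
        assert np.std(resid) == pytest.approx(2.0, rel=0.05)
        r = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)


class TestDoseDesign:
    def test_row_count(self):
        doses = tuple(np.linspace(0.2, 1.4, 7))
        design = DoseDesign(dose_labels=doses)
        params = {d: make_params("saturating", amplitude=10 + 10 * i) for i, d in enumerate(doses)}
        ds = simulate_dataset(design, params, seed=0)
        assert len(ds) == 700

    def test_missing_dose_parameters_named(self):
        design = DoseDesign(dose_labels=(0.2, 0.4))
        with pytest.raises(KeyError, match="0.4"):
            simulate_dataset(design, {0.2: make_params("saturating")}, seed=0)

    def test_dose_labels_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DoseDesign(dose_labels=(0.4, 0.2))

    def test_zero_np_offset_gives_identical_groups(self):
        doses = (0.5, 1.0)
        design = DoseDesign(
            dose_labels=doses,
            groups=(AGONIST_ONLY, AGONIST_PLUS_NP),
            np_effect=NPEffect(amplitude=0.0),
        )
        params = {d: make_params("saturating", amplitude=40.0) for d in doses}
        ds = simulate_dataset(design, params, seed=0)
        for d in doses:
            a = ds.condition(d, AGONIST_ONLY)["aggregation_pct"].to_numpy()
            b = ds.condition(d, AGONIST_PLUS_NP)["aggregation_pct"].to_numpy()
            np.testing.assert_allclose(a, b)

    def test_np_offset_added_before_noise(self):
        design = DoseDesign(
            dose_labels=(1.0,),
            groups=(AGONIST_ONLY, AGONIST_PLUS_NP),
            np_effect=NPEffect(amplitude=15.0, rate=2.0),
        )
        params = {1.0: make_params("saturating", amplitude=40.0)}
        ds = simulate_dataset(design, params, seed=0)
        t = ds.condition(1.0, AGONIST_ONLY)["time_min"].to_numpy()
        diff = (
            ds.condition(1.0, AGONIST_PLUS_NP)["aggregation_pct"].to_numpy()
            - ds.condition(1.0, AGONIST_ONLY)["aggregation_pct"].to_numpy()
        )
        np.testing.assert_allclose(diff, 15.0 * (1 - np.exp(-2.0 * t)), atol=1e-12)

    def test_monotone_amplitudes_give_monotone_final_values(self):
        doses = tuple(np.linspace(0.2, 1.4, 7))
        amps = np.linspace(10.0, 80.0, 7)
        design = DoseDesign(dose_labels=doses)
        params = {d: make_params("saturating", amplitude=a, k=2.0) for d, a in zip(doses, amps)}
        ds = simulate_dataset(design, params, seed=0)
        finals = [
            ds.condition(d, AGONIST_ONLY)["aggregation_pct"].to_numpy()[-1] for d in doses
        ]
        assert np.all(np.diff(finals) > 0)

    def test_adp_presets_cover_all_doses_and_trend(self):
        doses = (0.2, 0.4, 0.8, 1.2, 1.32, 1.36)
        params = adp_dose_presets(doses, noise_sd=0.0)
        assert set(params) == set(doses)
        t = np.linspace(0.0, 7.0, 200)
        finals = [signal(params[d], t)[-1] for d in doses]
        assert finals[-1] > finals[0]  # height grows with dose
        assert params[0.2].family == "rise_decay"  # low dose de-aggregates
        assert params[1.36].family == "saturating"


class TestPhaseLawOracle:
    def test_closed_form_examples(self):
        df = simulate_from_phase_law(120.0, -1.5, y0=0.0, n_points=50)
        t = df["time_min"].to_numpy()
        np.testing.assert_allclose(
            df["aggregation_pct"].to_numpy(), 80.0 * (1 - np.exp(-1.5 * t)), rtol=1e-12
        )
        far = simulate_from_phase_law(120.0, -1.5, duration=40.0, n_points=10)
        assert far["aggregation_pct"].to_numpy()[-1] == pytest.approx(80.0, abs=1e-6)

    def test_matches_brute_force_integration(self):
        g0, g1, y0 = 50.0, -0.8, 5.0
        df = simulate_from_phase_law(g0, g1, y0=y0, n_points=200)
        sol = solve_ivp(
            lambda _, y: g0 + g1 * y,
            (0.0, 7.0),
            [y0],
            t_eval=df["time_min"].to_numpy(),
            rtol=1e-11,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            df["aggregation_pct"].to_numpy(), sol.y[0], atol=1e-6
        )

    def test_gamma1_zero_rejected(self):
        with pytest.raises(ValueError, match="gamma1"):
            simulate_from_phase_law(10.0, 0.0)

    def test_logistic_family_solves_its_ode(self):
        p = make_params("logistic_ode", amplitude=70.0, k=0.8, y0=2.0, n_points=300)
        df = simulate_curve(p, seed=0)
        sol = solve_ivp(
            lambda _, y: 0.8 * y * (1 - y / 70.0),
            (0.0, 7.0),
            [2.0],
            t_eval=df["time_min"].to_numpy(),
            rtol=1e-11,
            atol=1e-12,
        )
        np.testing.assert_allclose(df["aggregation_pct"].to_numpy(), sol.y[0], atol=1e-6)
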