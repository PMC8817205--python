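"""Transit-compartment delayed tumor-kill model: simulation and fitting."""

import numpy as np
import pytest

import tcequant as tq


def rk4_full_system(params, tcb, times, h=0.02):
    """Independent oracle: classic fixed-step RK4 on the full 4-state ODE
    (three transit compartments integrated numerically, no closed forms).
    """
    kel = params.emax * tcb / (params.ec50 + tcb)
    tau, kg, K = params.tau, params.kg, params.capacity

    def f(state):
        k1, k2, k3, T = state
        return np.array([
            (kel - k1) / tau,
            (k1 - k2) / tau,
            (k2 - k3) / tau,
            kg * (1.0 - T / K) - k3 * T,
        ])

    out = []
    state = np.array([0.0, 0.0, 0.0, params.tumor0])
    t = 0.0
    for target in times:
        while t < target - 1e-12:
            step = min(h, target - t)
            s1 = f(state)
            s2 = f(state + 0.5 * step * s1)
            s3 = f(state + 0.5 * step * s2)
            s4 = f(state + step * s3)
            state = state + step / 6.0 * (s1 + 2 * s2 + 2 * s3 + s4)
            t += step
        out.append(state.copy())
    return np.array(out)


@pytest.fixture(scope="module")
def params():
    return tq.KillModelParams(kg=1000.0, capacity=100_000.0, emax=0.08,
                              ec50=20.0, tau=30.0, tumor0=30_000.0)


class TestSimulateKill:
    def test_no_drug_at_capacity_is_fixed_point(self, params):
        p = tq.KillModelParams(kg=params.kg, capacity=params.capacity,
                               emax=params.emax, ec50=params.ec50,
                               tau=params.tau, tumor0=params.capacity)
        states = tq.simulate_kill(p, 0.0, [24.0, 96.0, 168.0])
        for s in states:
            assert s.tumor == pytest.approx(p.capacity, rel=1e-8)
            assert s.k1 == s.k2 == s.k3 == 0.0

    def test_approaches_closed_form_steady_state(self, params):
        tcb = 800.0
        kel = params.emax * tcb / (params.ec50 + tcb)
        expected = params.kg / (params.kg / params.capacity + kel)
        (s,) = tq.simulate_kill(params, tcb, [3000.0])
        assert s.tumor == pytest.approx(expected, rel=1e-4)
        assert s.k3 == pytest.approx(kel, rel=1e-6)

    def test_tiny_tau_matches_no_delay_model(self, params):
        # oracle: k3 replaced by k_el directly (no transit delay)
        from scipy.integrate import solve_ivp
        tcb = 4000.0
        kel = params.emax * tcb / (params.ec50 + tcb)
        p = tq.KillModelParams(kg=params.kg, capacity=params.capacity,
                               emax=params.emax, ec50=params.ec50,
                               tau=0.01, tumor0=params.tumor0)
        times = [24.0, 48.0, 96.0, 168.0]
        sol = solve_ivp(
            lambda t, T: params.kg * (1 - T / params.capacity) - kel * T,
            (0.0, 168.0), [params.tumor0], t_eval=times, rtol=1e-10,
            atol=1e-6, method="LSODA",
        )
        sim = [s.tumor for s in tq.simulate_kill(p, tcb, times)]
        assert np.allclose(sim, sol.y[0], rtol=1e-3)

    def test_agrees_with_independent_rk4(self, params):
        times = [18.0, 44.0, 68.0, 94.0, 168.0]
        for tcb in (0.0, 6.0, 800.0, 100_000.0):
            oracle = rk4_full_system(params, tcb, times)
            sim = tq.simulate_kill(params, tcb, times)
            got = np.array([[s.k1, s.k2, s.k3, s.tumor] for s in sim])
            assert np.allclose(got, oracle, rtol=1e-6, atol=1e-10)

    def test_transit_rates_monotone_below_kel(self, params):
        tcb = 800.0
        kel = float(params.kel(tcb))
        states = tq.simulate_kill(params, tcb, list(np.linspace(1, 400, 60)))
        for key in ("k1", "k2", "k3"):
            vals = np.array([getattr(s, key) for s in states])
            assert np.all(np.diff(vals) >= -1e-12)
            assert np.all(vals <= kel * (1 + 1e-9))

    def test_tumor_monotone_decreasing_in_dose(self, params):
        times = [24.0, 72.0, 168.0]
        doses = [0.0, 6.0, 32.0, 160.0, 800.0, 4000.0]
        grid = np.array([[s.tumor for s in tq.simulate_kill(params, d, times)]
                         for d in doses])
        assert np.all(np.diff(grid, axis=0) <= 1e-9)

    def test_logistic_growth_switch_changes_dynamics(self, params):
        t = [96.0]
        (a,) = tq.simulate_kill(params, 0.0, t)
        (b,) = tq.simulate_kill(params, 0.0, t, logistic_growth=True)
        assert a.tumor != pytest.approx(b.tumor, rel=1e-3)

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            tq.simulate_kill(params, -1.0, [24.0])
        with pytest.raises(ValueError):
            tq.simulate_kill(params, 10.0, [48.0, 24.0])
        with pytest.raises(ValueError):
            tq.KillModelParams(kg=np.nan, capacity=1, emax=1, ec50=1, tau=1,
                               tumor0=1)


class TestFitKillModel:
    def test_noiseless_recovery(self, params, noiseless_tdcc):
        fit = tq.fit_kill_model(noiseless_tdcc, "tumor_count",
                                error_model="additive")
        for name in ("kg", "capacity", "emax", "ec50", "tau", "tumor0"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(params, name), rel=1e-3), name
        assert fit.converged and fit.drug_params_identifiable

    def test_noisy_recovery_single_seed(self, params):
        noise = tq.NoiseModel(proportional_cv=0.10, additive_sd=50.0)
        ds = tq.generate_tdcc(tq.CIBISATAMAB_DESIGN, params, noise, seed=12)
        fit = tq.fit_kill_model(ds, "tumor_count")
        assert 0.75 <= fit.params.ec50 / params.ec50 <= 1.25
        assert np.isfinite(fit.rse_percent["ec50"])

    def test_drug_free_wells_only_flagged(self, params):
        design = tq.AssayDesign(doses=(0.0, 0.0 + 1e-12), times=(24.0, 48.0, 96.0))
        # build a control-only dataset directly
        ds = tq.generate_tdcc(
            tq.AssayDesign(doses=(0.0, 5.0), times=(24.0, 48.0, 96.0)),
            params, tq.NoiseModel(), seed=0)
        ctrl = ds.with_data(ds.data[ds.data["concentration_pm"] == 0.0])
        fit = tq.fit_kill_model(ctrl, "tumor_count", error_model="additive")
        assert not fit.drug_params_identifiable
        assert np.isnan(fit.se["ec50"]) and np.isnan(fit.se["emax"])
        # growth side still recovered from the control trajectory
        assert fit.params.capacity == pytest.approx(params.capacity, rel=0.05)

    def test_no_control_warns_but_fits(self, params):
        ds = tq.generate_tdcc(tq.CIBISATAMAB_DESIGN, params, tq.NoiseModel(),
                              seed=0)
        nz = ds.with_data(ds.data[ds.data["concentration_pm"] > 0.0])
        with pytest.warns(UserWarning, match="control"):
            fit = tq.fit_kill_model(nz, "tumor_count", error_model="additive")
        assert fit.params.ec50 == pytest.approx(params.ec50, rel=0.05)


class TestReferencePotencyComparison:
    def test_all_three_estimates_agree_for_fast_effect(self):
        # near-instantaneous effect: static ~ AUCE ~ model potency
        # mild total kill over a short window, so the effect has no time
        # to saturate across doses
        p = tq.KillModelParams(kg=1000.0, capacity=100_000.0, emax=0.02,
                               ec50=50.0, tau=0.5, tumor0=30_000.0)
        design = tq.AssayDesign(doses=tq.CIBISATAMAB_DESIGN.doses,
                                times=(24.0, 48.0, 72.0))
        ds = tq.generate_tdcc(design, p, tq.NoiseModel(), seed=0)
        cmp = tq.reference_potency_comparison(ds, "tumor_count")
        assert cmp["model_ec50"] == pytest.approx(50.0, rel=0.05)
        assert cmp["auce_fold_deviation"] < 2.0
        assert max(cmp["static_fold_deviation_by_time"].values()) < 2.0

    def test_slow_kill_biases_static_not_auce(self, slow_kill_truth):
        noise = tq.NoiseModel(proportional_cv=0.05, additive_sd=20.0)
        ds = tq.generate_tdcc(tq.CIBISATAMAB_DESIGN, slow_kill_truth, noise,
                              seed=2)
        cmp = tq.reference_potency_comparison(ds, "tumor_count")
        assert cmp["auce_fold_deviation"] < 2.0
        assert max(cmp["static_fold_deviation_by_time"].values()) > 5.0
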