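"""Sigmoid / hockey-stick fitting, derived potencies, fold comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcequant as tq
from tcequant.dose_response import hill

CONC8 = np.geomspace(1.0, 1e5, 8)


def make_table(conc, vals, name="AUCE"):
    return tq.DoseResponseTable(name, conc, vals)


def grid_search_sse(conc, y, n=200):
    """Exhaustive oracle: log-grid over (EC50, gamma), linear params profiled.

    For fixed (EC50, gamma) the model is linear in (E0, Emax); solve the
    2x2 normal equations in closed form on every grid node.
    """
    ec50s = np.geomspace(conc[conc > 0].min() / 10, conc.max() * 10, n)
    gammas = np.geomspace(0.1, 10.0, n)
    best = np.inf
    ones = np.ones_like(conc)
    for g in gammas:
        with np.errstate(divide="ignore"):
            cg = np.where(conc > 0, conc, np.nan) ** g
        for e in ec50s:
            h = np.where(conc > 0, cg / (e ** g + cg), 0.0)
            A = np.column_stack([ones, h])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(np.sum((A @ coef - y) ** 2))
            best = min(best, sse)
    return best


class TestSigmoidFit:
    def test_noiseless_recovery(self):
        y = hill(CONC8, 0.0, 100.0, 50.0, 1.5)
        fit = tq.fit_sigmoid(make_table(CONC8, y))
        assert fit.converged
        assert fit.e0 == pytest.approx(0.0, abs=1e-6)
        assert fit.emax == pytest.approx(100.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(50.0, rel=1e-6)
        assert fit.gamma == pytest.approx(1.5, rel=1e-6)

    def test_objective_beats_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        y = hill(CONC8, 5.0, 80.0, 300.0, 0.9) + rng.normal(0, 4.0, CONC8.size)
        fit = tq.fit_sigmoid(make_table(CONC8, y))
        sse_fit = float(np.sum((fit.predict(CONC8) - y) ** 2))
        sse_grid = grid_search_sse(CONC8, y, n=100)
        assert sse_fit <= sse_grid * (1.0 + 1e-6)

    def test_inhibitory_data_gives_negative_emax(self):
        y = hill(CONC8, 100.0, -100.0, 30.0, 1.2)
        fit = tq.fit_sigmoid(make_table(CONC8, y), direction="auto")
        assert fit.emax < 0
        assert fit.ec50 == pytest.approx(30.0, rel=1e-6)

    def test_zero_concentration_control_point_supported(self):
        conc = np.concatenate([[0.0], CONC8])
        y = hill(conc, 10.0, 90.0, 50.0, 1.0)
        fit = tq.fit_sigmoid(make_table(conc, y))
        assert fit.e0 == pytest.approx(10.0, abs=1e-5)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            tq.fit_sigmoid(make_table(np.array([1.0, 10.0, 100.0]),
                                      np.array([0.0, 1.0, 2.0])))

    def test_flat_metric_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            tq.fit_sigmoid(make_table(CONC8, np.full(8, 3.0)))

    def test_rse_definition(self):
        y = hill(CONC8, 0.0, 100.0, 50.0, 1.5)
        rng = np.random.default_rng(0)
        fit = tq.fit_sigmoid(make_table(CONC8, y + rng.normal(0, 2, 8)))
        for name in ("e0", "emax", "ec50", "gamma"):
            est = getattr(fit, name)
            if np.isfinite(fit.se[name]) and est != 0:
                assert fit.rse_percent[name] == pytest.approx(
                    100.0 * fit.se[name] / abs(est), rel=1e-12)

    @given(st.floats(0.3, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_recovery_across_hill_range(self, gamma):
        y = hill(CONC8, 0.0, 100.0, 200.0, gamma)
        fit = tq.fit_sigmoid(make_table(CONC8, y))
        assert fit.ec50 == pytest.approx(200.0, rel=1e-6)
        assert fit.gamma == pytest.approx(gamma, rel=1e-6)

    def test_hill_half_max_identity(self):
        # E(EC50) = E0 + Emax/2, exactly
        assert hill(np.array([50.0]), 7.0, 90.0, 50.0, 2.3)[0] == \
            pytest.approx(7.0 + 45.0, rel=1e-15)


class TestDerivedPotencies:
    def test_pa30_worked_example(self):
        # EC50 1501 pM, Hill 1.28: PA30 ~ 774 pM (~150 ng/mL at 194 kDa)
        fit = tq.SigmoidFit(0.0, 1.0, 1501.0, 1.28)
        pa = tq.derive_pa(fit, 30.0)
        assert pa == pytest.approx(1501.0 * (30.0 / 70.0) ** (1 / 1.28), rel=1e-12)
        assert pa == pytest.approx(774.3, abs=0.5)

    def test_pa50_is_ec50(self):
        fit = tq.SigmoidFit(0.0, 1.0, 123.4, 2.2)
        assert tq.derive_pa(fit, 50.0) == pytest.approx(123.4, rel=1e-12)

    def test_gamma_one_closed_form(self):
        fit = tq.SigmoidFit(0.0, 1.0, 70.0, 1.0)
        assert tq.derive_pa(fit, 30.0) == pytest.approx(70.0 * 3.0 / 7.0, rel=1e-12)
        assert tq.derive_ecx(fit, 20.0) == pytest.approx(70.0 / 4.0, rel=1e-12)

    def test_ic99_closed_form(self):
        fit = tq.SigmoidFit(0.0, -1.0, 15.7, 2.07)
        ic99 = tq.derive_ecx(fit, 99.0)
        assert ic99 == pytest.approx(15.7 * 99.0 ** (1 / 2.07), rel=1e-12)
        assert ic99 == pytest.approx(145.0, abs=1.0)

    @pytest.mark.parametrize("x", [0.0, 100.0, -5.0, 120.0])
    def test_domain_errors(self, x):
        fit = tq.SigmoidFit(0.0, 1.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            tq.derive_pa(fit, x)

    def test_unconverged_fit_rejected(self):
        fit = tq.SigmoidFit(0.0, 1.0, 10.0, 1.0, converged=False)
        with pytest.raises(ValueError, match="converged"):
            tq.derive_pa(fit, 30.0)

    def test_strictly_increasing_in_x_and_symmetry(self):
        fit = tq.SigmoidFit(0.0, 1.0, 55.0, 1.0)
        xs = np.linspace(5, 95, 19)
        pas = [tq.derive_pa(fit, x) for x in xs]
        assert np.all(np.diff(pas) > 0)
        # for gamma=1: PA_x * PA_{100-x} = EC50^2
        for x in (10.0, 30.0, 45.0):
            assert tq.derive_pa(fit, x) * tq.derive_pa(fit, 100 - x) == \
                pytest.approx(55.0 ** 2, rel=1e-12)


class TestHockeyStick:
    def _hinge(self, thr=500.0, e0=10.0, s=0.02):
        conc = np.array([0.0, 10.0, 100.0, 300.0, 500.0, 1000.0, 5000.0, 20000.0])
        return conc, e0 + s * np.clip(conc - thr, 0, None)

    def test_exact_hinge_recovery(self):
        conc, y = self._hinge(thr=500.0)
        fit = tq.fit_hockey_stick(make_table(conc, y))
        assert fit.identifiable
        assert fit.tcb_threshold == pytest.approx(500.0, rel=1e-6)
        assert fit.slope_s == pytest.approx(0.02, rel=1e-6)
        assert fit.e0 == pytest.approx(10.0, rel=1e-6)

    def test_flat_noise_flagged_unidentifiable(self):
        rng = np.random.default_rng(5)
        conc = np.geomspace(1, 1e4, 8)
        fit = tq.fit_hockey_stick(make_table(conc, rng.normal(10.0, 0.1, 8)))
        assert not fit.identifiable

    def test_objective_matches_threshold_grid_oracle(self):
        rng = np.random.default_rng(21)
        conc, y = self._hinge(thr=700.0)
        y = y + rng.normal(0, 0.5, conc.size)
        fit = tq.fit_hockey_stick(make_table(conc, y))
        sse_fit = float(np.sum((fit.predict(conc) - y) ** 2))
        # exhaustive threshold grid, linear params in closed form
        best = np.inf
        for thr in np.linspace(0.0, conc.max(), 20_001):
            x = np.clip(conc - thr, 0, None)
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            best = min(best, float(np.sum((A @ coef - y) ** 2)))
        assert sse_fit <= best * (1.0 + 1e-9)


class TestStaticFit:
    def test_exact_recovery_from_sigmoid_slice(self):
        # a single-time slice lying exactly on a Hill curve is recovered
        from conftest import make_dataset
        conc = np.concatenate([[0.0], CONC8])
        rows = []
        for t, scale in [(24.0, 0.3), (48.0, 1.0)]:
            for c, v in zip(conc, hill(conc, 50.0, scale * 900.0, 120.0, 1.4)):
                rows.append(("il6", c, t, "agg", v))
        ds = make_dataset(rows)
        fit = tq.fit_static(ds, "il6", 48.0)
        assert fit.ec50 == pytest.approx(120.0, rel=1e-6)
        assert fit.gamma == pytest.approx(1.4, rel=1e-6)

    def test_close_fit_of_kill_model_slice(self, noiseless_tdcc):
        # mechanistic single-time dose-response is near-sigmoidal; the
        # static fit should track it closely (not exactly)
        ds = tq.aggregate_replicates(noiseless_tdcc)
        fit = tq.fit_static(ds, "tumor_count", 96.0, direction="inhibitory")
        sub = ds.select("tumor_count")
        slc = sub[np.isclose(sub["time_h"], 96.0)].sort_values("concentration_pm")
        resid = fit.predict(slc["concentration_pm"].to_numpy()) - \
            slc["value"].to_numpy()
        assert fit.converged and fit.emax < 0
        assert np.max(np.abs(resid)) / slc["value"].max() < 0.01

    def test_unobserved_time_rejected(self, noiseless_tdcc):
        with pytest.raises(ValueError, match="not observed"):
            tq.fit_static(noiseless_tdcc, "tumor_count", 36.0)


class TestComparePotencies:
    def test_reported_fold_ratios(self):
        fits = {
            "activation": tq.SigmoidFit(0, 1, 596.0, 0.91),
            "cytotox": tq.SigmoidFit(0, 1, 15.7, 2.07),
            "il2": tq.SigmoidFit(0, 1, 2280.0, 1.19),
        }
        table = tq.compare_potencies(fits)
        get = lambda a, b: table.query(
            "numerator == @a and denominator == @b").iloc[0]
        assert get("activation", "cytotox")["fold_rounded"] == 38
        assert get("il2", "cytotox")["fold_rounded"] == 145

    def test_identical_fits_give_unity(self):
        f = tq.SigmoidFit(0, 1, 100.0, 1.0)
        table = tq.compare_potencies({"a": f, "b": f})
        assert np.allclose(table["fold"], 1.0)

    def test_requires_two_converged_fits(self):
        f = tq.SigmoidFit(0, 1, 100.0, 1.0)
        bad = tq.SigmoidFit(0, 1, 5.0, 1.0, converged=False)
        with pytest.raises(ValueError):
            tq.compare_potencies({"a": f, "b": bad})
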