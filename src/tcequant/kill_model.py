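"""Delayed tumor-kill model: the mechanistic reference for potency.

Tumor cells in a T-cell co-culture grow toward a carrying capacity while
the drug imposes a concentration-dependent kill rate that takes effect
with a delay, described by a chain of three transit compartments:

    k_el      = Emax * TCB / (EC50 + TCB)
    dk1/dt    = (k_el - k1) / tau
    dk2/dt    = (k1 - k2) / tau
    dk3/dt    = (k2 - k3) / tau,      k1(0) = k2(0) = k3(0) = 0
    dTumor/dt = kg * (1 - Tumor/K) - k3 * Tumor

The growth term is kg*(1 - Tumor/K) as printed in the source model (an
input-rate form, not the classical kg*Tumor*(1 - Tumor/K) logistic);
``logistic_growth=True`` switches to the classical form for sensitivity
analysis.  Drug concentration is constant over the assay (in vitro, no
PK, no depletion by binding).

For constant drug the transit chain is linear with the exact solution
k3(t) = k_el * (1 - exp(-x)(1 + x + x^2/2)), x = t/tau, so only the tumor
equation is integrated numerically (vectorized across doses).  Fitting is
pooled fixed-effect nonlinear least squares over all doses simultaneously
with an additive, proportional or combined (sd = a + b*prediction) error
model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator, RegressorMixin

from .auce import auce_table
from .datasets import TimeCourseDataset
from .dose_response import SigmoidFit, fit_sigmoid, fit_static
from .preprocessing import aggregate_replicates, normalize_to_control

__all__ = [
    "KillModelParams",
    "KillModelState",
    "KillModelFit",
    "TransitKillModel",
    "simulate_kill",
    "fit_kill_model",
    "reference_potency_comparison",
]

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("kg", "capacity", "emax", "ec50", "tau", "tumor0")


@dataclass(frozen=True)
class KillModelParams:
    """Parameters of the delayed tumor-kill model.

    kg : cells/h (growth input rate); capacity : cells (carrying capacity K);
    emax : 1/h (maximal kill rate); ec50 : pM; tau : h (transit time
    constant); tumor0 : cells (count at t=0).
    """

    kg: float
    capacity: float
    emax: float
    ec50: float
    tau: float
    tumor0: float

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0 (got {v!r})")

    def kel(self, tcb) -> np.ndarray:
        """Drug-induced kill rate Emax*TCB/(EC50+TCB), 1/h."""
        tcb = np.asarray(tcb, dtype=float)
        return self.emax * tcb / (self.ec50 + tcb)


@dataclass(frozen=True)
class KillModelState:
    """Model state at one time point (transit rates in 1/h, tumor in cells)."""

    time: float
    k1: float
    k2: float
    k3: float
    tumor: float


def _transit_rates(kel: np.ndarray, t: float | np.ndarray, tau: float):
    """Exact transit-chain solution for constant drug; x = t/tau."""
    x = np.asarray(t, dtype=float) / tau
    e = np.exp(-x)
    k1 = kel * (1.0 - e)
    k2 = kel * (1.0 - e * (1.0 + x))
    k3 = kel * (1.0 - e * (1.0 + x + 0.5 * x * x))
    return k1, k2, k3


def _simulate_tumor(
    params: KillModelParams,
    tcb: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    logistic_growth: bool = False,
) -> np.ndarray:
    """Tumor counts, shape (n_doses, n_times); integrates from t=0."""
    tcb = np.atleast_1d(np.asarray(tcb, dtype=float))
    times = np.asarray(times, dtype=float)
    kel = params.kel(tcb)
    kg, K, tau = params.kg, params.capacity, params.tau

    def rhs(t, T):
        _, _, k3 = _transit_rates(kel, t, tau)
        growth = kg * T * (1.0 - T / K) if logistic_growth else kg * (1.0 - T / K)
        return growth - k3 * T

    t_end = float(times.max()) if times.size else 0.0
    if t_end == 0.0:
        return np.tile(params.tumor0, (tcb.size, times.size))
    sol = solve_ivp(
        rhs, (0.0, t_end), np.full(tcb.size, params.tumor0),
        t_eval=np.unique(np.concatenate([[0.0], times])),
        method="LSODA", rtol=rtol, atol=params.tumor0 * 1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"tumor ODE integration failed: {sol.message}")
    lookup = {t: i for i, t in enumerate(sol.t)}
    idx = [lookup[t] for t in times]
    return sol.y[:, idx]


def simulate_kill(
    params: KillModelParams,
    tcb: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    logistic_growth: bool = False,
) -> list[KillModelState]:
    """Simulate the delayed-kill system at a constant drug concentration.

    Returns one :class:`KillModelState` per requested time (times must be
    ascending and nonnegative; initial conditions are at t=0 regardless of
    the first requested time).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be ascending and start at >= 0")
    if not np.isfinite(tcb) or tcb < 0:
        raise ValueError("tcb must be finite and >= 0")
    tumor = _simulate_tumor(params, [tcb], times, rtol=rtol,
                            logistic_growth=logistic_growth)[0]
    kel = float(params.kel(tcb))
    k1, k2, k3 = _transit_rates(kel, times, params.tau)
    return [
        KillModelState(float(t), float(a), float(b), float(c), float(T))
        for t, a, b, c, T in zip(times, k1, k2, k3, tumor)
    ]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class KillModelFit:
    """Pooled kill-model fit with uncertainty and identifiability flags."""

    params: KillModelParams
    se: dict[str, float] = field(default_factory=dict)
    rse_percent: dict[str, float] = field(default_factory=dict)
    error_model: str = "combined"
    error_a: float = np.nan
    error_b: float = np.nan
    converged: bool = True
    drug_params_identifiable: bool = True
    readout: str = ""
    model_name: str = "transit_kill"

    def parameter_rows(self):
        for name in _PARAM_NAMES:
            yield (name, getattr(self.params, name),
                   self.se.get(name, np.nan), self.rse_percent.get(name, np.nan))


class TransitKillModel(RegressorMixin, BaseEstimator):
    """Pooled delayed tumor-kill regressor over (concentration, time).

    ``fit(X, y)`` expects ``X`` with two columns, drug concentration (pM)
    and time (h), and ``y`` the observed tumor cell counts; all doses are
    fitted simultaneously with shared parameters (fixed-effect pooling).

    Parameters
    ----------
    error_model : {"additive", "proportional", "combined"}
        Residual model.  ``combined`` (default) uses sd = a + b*prediction
        with (a, b) estimated from stage-one residuals, followed by one
        weighted refit (iteratively reweighted least squares).
    n_starts : int
        Number of EC50 multi-starts around the geometric-mean dose.
    """

    def __init__(
        self,
        error_model: Literal["additive", "proportional", "combined"] = "combined",
        logistic_growth: bool = False,
        n_starts: int = 3,
        sim_rtol: float = 1e-8,
    ):
        self.error_model = error_model
        self.logistic_growth = logistic_growth
        self.n_starts = n_starts
        self.sim_rtol = sim_rtol

    # -- helpers ------------------------------------------------------------
    def _predict_obs(self, theta: np.ndarray, doses, times, index) -> np.ndarray:
        params = KillModelParams(*np.exp(theta))
        grid = _simulate_tumor(params, doses, times, rtol=self.sim_rtol,
                               logistic_growth=self.logistic_growth)
        return grid.ravel()[index]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (concentration_pm, time_h)")
        conc, t_obs = X[:, 0], X[:, 1]
        if np.any(conc < 0) or np.any(t_obs < 0):
            raise ValueError("negative concentration or time")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite counts")
        doses = np.unique(conc)
        times = np.unique(t_obs)
        if times.size < 3:
            raise ValueError("need counts at >= 3 time points")
        pos = doses[doses > 0]
        self.drug_identifiable_ = pos.size > 0
        if pos.size and doses.size < 4:
            raise ValueError("need >= 4 concentrations (including control)")
        has_control = 0.0 in doses
        if not has_control:
            warnings.warn("no drug-free control series: growth parameters are "
                          "weakly identified", UserWarning, stacklevel=2)

        # map each observation onto the (dose, time) simulation grid
        di = np.searchsorted(doses, conc)
        ti = np.searchsorted(times, t_obs)
        index = di * times.size + ti

        # -- heuristics for starting values ---------------------------------
        first_t = times[0]
        y_first = y[np.isclose(t_obs, first_t)]
        tumor0_0 = max(float(np.median(y_first)), 1e-6)
        k0 = max(float(y.max()) * 1.2, tumor0_0 * 2)
        ref_dose = 0.0 if has_control else doses.min()
        ctrl = y[np.isclose(conc, ref_dose)]
        ctrl_t = t_obs[np.isclose(conc, ref_dose)]
        if ctrl.size >= 2 and ctrl_t.max() > ctrl_t.min():
            slope = (ctrl.max() - tumor0_0) / (ctrl_t.max() - ctrl_t.min())
            kg0 = max(float(slope), k0 / times.max())
        else:
            kg0 = k0 / times.max()
        emax0 = max(3.0 / times.max(), 0.02)
        tau0 = max(times[0] / 2.0, 5.0)
        if pos.size:
            gm = float(np.exp(np.mean(np.log(pos))))
            ec50_starts = np.geomspace(gm / 10, gm * 10, self.n_starts)
        else:
            ec50_starts = np.array([1.0])

        lb = np.log([kg0 / 1e4, k0 / 1e3, 1e-5, 1e-6, 1e-2, tumor0_0 / 1e3])
        ub = np.log([kg0 * 1e4, k0 * 1e3, 10.0, 1e12, 1e4, tumor0_0 * 1e3])

        def resid(theta, w):
            return (self._predict_obs(theta, doses, times, index) - y) * w

        def solve(weights):
            best = None
            for ec50_0 in ec50_starts:
                theta0 = np.log([kg0, k0, emax0, ec50_0, tau0, tumor0_0])
                theta0 = np.clip(theta0, lb, ub)
                try:
                    sol = optimize.least_squares(
                        resid, theta0, args=(weights,), bounds=(lb, ub),
                        method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        max_nfev=400, diff_step=1e-5,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
            return best

        w = np.ones_like(y)
        sol = solve(w)
        if sol is None:
            raise RuntimeError("kill-model optimization failed from all starts")

        a = b = np.nan
        if self.error_model != "additive":
            pred = self._predict_obs(sol.x, doses, times, index)
            r = np.abs(pred - y)
            if self.error_model == "proportional":
                a, b = 0.0, float(np.sqrt(np.mean((r / np.maximum(pred, 1e-12)) ** 2)))
            else:  # combined: sd = a + b*pred via least squares on |residual|
                A = np.column_stack([np.ones_like(pred), pred])
                coef, *_ = np.linalg.lstsq(A, r, rcond=None)
                a = max(float(coef[0]), 1e-8 * max(y.max(), 1.0))
                b = max(float(coef[1]), 1e-6)
            sd = np.maximum(a + b * np.maximum(pred, 0.0), 1e-12)
            sol2 = solve(1.0 / sd)
            if sol2 is not None and np.all(np.isfinite(sol2.x)):
                sol, w = sol2, 1.0 / sd

        theta = sol.x
        params = KillModelParams(*np.exp(theta))
        (self.kg_, self.capacity_, self.emax_, self.ec50_,
         self.tau_, self.tumor0_) = np.exp(theta)
        self.error_a_, self.error_b_ = a, b
        self.converged_ = bool(sol.success)

        # covariance of log-params from the weighted Jacobian, delta-method
        # back to the natural scale (se_nat = se_log * estimate)
        J = sol.jac
        dof = max(y.size - theta.size, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov_log = s2 * np.linalg.pinv(J.T @ J)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            se_log = np.full(theta.size, np.nan)
        est = np.exp(theta)
        self.se_ = dict(zip(_PARAM_NAMES, se_log * est))
        self.rse_percent_ = dict(zip(_PARAM_NAMES, 100.0 * se_log))
        if not self.drug_identifiable_:
            for name in ("emax", "ec50", "tau"):
                self.se_[name] = np.nan
                self.rse_percent_[name] = np.nan
        self.params_ = params
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        conc, t_obs = X[:, 0], X[:, 1]
        doses = np.unique(conc)
        times = np.unique(t_obs)
        di = np.searchsorted(doses, conc)
        ti = np.searchsorted(times, t_obs)
        grid = _simulate_tumor(self.params_, doses, times, rtol=self.sim_rtol,
                               logistic_growth=self.logistic_growth)
        return grid.ravel()[di * times.size + ti]

    def to_result(self, readout: str = "") -> KillModelFit:
        return KillModelFit(
            params=self.params_, se=dict(self.se_),
            rse_percent=dict(self.rse_percent_), error_model=self.error_model,
            error_a=self.error_a_, error_b=self.error_b_,
            converged=self.converged_,
            drug_params_identifiable=self.drug_identifiable_, readout=readout,
        )


def fit_kill_model(
    ds: TimeCourseDataset,
    readout: str,
    error_model: Literal["additive", "proportional", "combined"] = "combined",
    **kwargs,
) -> KillModelFit:
    """Pooled fit of the delayed-kill model to observed cell counts.

    All concentrations are fitted simultaneously with shared parameters.
    Replicates are kept raw (each contributes a residual).  The readout
    must be raw cell counts, not normalized viability.
    """
    sub = ds.select(readout)
    est = TransitKillModel(error_model=error_model, **kwargs)
    est.fit(sub[["concentration_pm", "time_h"]].to_numpy(), sub["value"].to_numpy())
    return est.to_result(readout=readout)


def reference_potency_comparison(
    ds: TimeCourseDataset, readout: str
) -> dict:
    """Benchmark AUCE-based and static potencies against the model-based one.

    Fits the mechanistic kill model on raw counts (the reference EC50),
    the sigmoid on the AUCE of drug-related kill, and static sigmoids per
    time point; reports each estimate and its fold-deviation from the
    reference (fold = max(r, 1/r) >= 1).
    """
    model_fit = fit_kill_model(ds, readout)
    model_ec50 = model_fit.params.ec50

    agg = aggregate_replicates(ds)
    kill = normalize_to_control(agg, readout, mode="drug_related_kill")
    table = auce_table(kill, readout)
    auce_fit = fit_sigmoid(table, direction="stimulatory", readout=readout)

    def fold(x):
        r = x / model_ec50
        return float(max(r, 1.0 / r))

    static: dict[float, SigmoidFit] = {}
    for t in kill.times(readout):
        try:
            static[float(t)] = fit_static(kill, readout, float(t),
                                          direction="stimulatory")
        except ValueError:
            continue

    return {
        "model_fit": model_fit,
        "auce_fit": auce_fit,
        "static_fits": static,
        "model_ec50": model_ec50,
        "auce_ec50": auce_fit.ec50,
        "static_ec50_by_time": {t: f.ec50 for t, f in static.items()
                                if f.converged},
        "auce_fold_deviation": fold(auce_fit.ec50),
        "static_fold_deviation_by_time": {
            t: fold(f.ec50) for t, f in static.items() if f.converged
        },
    }
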