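"""Sigmoidal (Emax/Hill) and hockey-stick dose-response models.

The sigmoid is the standard four-parameter Hill model

    E(C) = E0 + Emax * C^gamma / (EC50^gamma + C^gamma)

fitted by multi-start bounded nonlinear least squares under an additive
residual error.  Emax is signed: a negative Emax describes an inhibitory
(falling-viability) response.  The zero-concentration control point enters
through the model's exact C=0 limit, E(0) = E0.

When no sigmoidal relationship can be established, the hockey-stick
(segmented threshold) model

    E(C) = E0 + S * (C - C_thr) * [C > C_thr]

estimates the lowest concentration with effect above baseline; the
threshold is profiled on a grid (linear parameters solved in closed form
at each candidate) and refined locally.

Both models are exposed as scikit-learn estimators (`EmaxRegressor`,
`HockeyStickRegressor`) so they compose with sklearn tooling; the
module-level `fit_sigmoid` / `fit_hockey_stick` helpers wrap them and
return plain result records with standard errors and %RSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import DoseResponseTable, TimeCourseDataset
from .preprocessing import aggregate_replicates

__all__ = [
    "SigmoidFit",
    "HockeyStickFit",
    "EmaxRegressor",
    "HockeyStickRegressor",
    "hill",
    "fit_sigmoid",
    "fit_hockey_stick",
    "fit_static",
    "derive_pa",
    "derive_ecx",
    "compare_potencies",
]


def hill(conc, e0, emax, ec50, gamma):
    """Hill model E0 + Emax*C^g/(EC50^g + C^g); exact at C=0 (-> E0)."""
    conc = np.asarray(conc, dtype=float)
    out = np.full(conc.shape, float(e0))
    pos = conc > 0
    r = (conc[pos] / ec50) ** gamma
    out[pos] += emax * r / (1.0 + r)
    return out


def _hill_jacobian(conc, e0, emax, ec50, gamma):
    """Analytic Jacobian of the Hill model wrt (e0, emax, ec50, gamma)."""
    conc = np.asarray(conc, dtype=float)
    n = conc.size
    J = np.zeros((n, 4))
    J[:, 0] = 1.0
    pos = conc > 0
    c = conc[pos]
    r = (c / ec50) ** gamma
    h = r / (1.0 + r)          # fractional occupancy
    hp = h * (1.0 - h)
    J[pos, 1] = h
    J[pos, 2] = -emax * gamma / ec50 * hp
    J[pos, 3] = emax * hp * np.log(c / ec50)
    return J


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

_SIGMOID_PARAMS = ("e0", "emax", "ec50", "gamma")
_HOCKEY_PARAMS = ("e0", "slope_s", "tcb_threshold")


def _rse(estimates: Mapping[str, float], se: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for k, est in estimates.items():
        s = se.get(k, np.nan)
        out[k] = 100.0 * s / abs(est) if est != 0 and np.isfinite(s) else np.nan
    return out


@dataclass
class SigmoidFit:
    """Fitted Hill-model parameters with uncertainty.

    ``emax`` is signed (negative = inhibitory response); ``rse_percent``
    is 100*SE/|estimate| per parameter.
    """

    e0: float
    emax: float
    ec50: float
    gamma: float
    se: dict[str, float] = field(default_factory=dict)
    rse_percent: dict[str, float] = field(default_factory=dict)
    residual_sd: float = np.nan
    converged: bool = True
    readout: str = ""
    model_name: str = "sigmoid"

    def predict(self, conc):
        return hill(conc, self.e0, self.emax, self.ec50, self.gamma)

    def parameter_rows(self):
        for name in _SIGMOID_PARAMS:
            est = getattr(self, name)
            yield name, est, self.se.get(name, np.nan), self.rse_percent.get(name, np.nan)


@dataclass
class HockeyStickFit:
    """Fitted hockey-stick (segmented threshold) parameters."""

    e0: float
    slope_s: float
    tcb_threshold: float
    se: dict[str, float] = field(default_factory=dict)
    rse_percent: dict[str, float] = field(default_factory=dict)
    residual_sd: float = np.nan
    converged: bool = True
    identifiable: bool = True
    readout: str = ""
    model_name: str = "hockey_stick"

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.e0 + self.slope_s * np.clip(conc - self.tcb_threshold, 0, None)

    def parameter_rows(self):
        for name in _HOCKEY_PARAMS:
            est = getattr(self, name)
            yield name, est, self.se.get(name, np.nan), self.rse_percent.get(name, np.nan)


# ---------------------------------------------------------------------------
# sigmoid estimator
# ---------------------------------------------------------------------------

class EmaxRegressor(RegressorMixin, BaseEstimator):
    """Four-parameter Hill (sigmoidal Emax) dose-response regressor.

    Parameters
    ----------
    direction : {"auto", "stimulatory", "inhibitory"}
        Sign of the fitted Emax.  ``auto`` decides from the Spearman rank
        correlation of response vs concentration.
    gamma_bounds, ec50_expand : fitting bounds; EC50 is bounded to
        [min positive conc / ec50_expand, max conc * ec50_expand].

    Attributes (after ``fit``)
    --------------------------
    e0_, emax_, ec50_, gamma_ : float
        Parameter estimates.
    se_, rse_percent_ : dict
        Standard errors (Gauss-Newton covariance, additive error) and
        100*SE/|estimate|.
    residual_sd_ : float
    converged_ : bool
        False when optimization fails or EC50 leaves the tested
        concentration range by more than 100-fold; never raises for
        optimizer failure.
    """

    def __init__(
        self,
        direction: Literal["auto", "stimulatory", "inhibitory"] = "auto",
        gamma_bounds: tuple[float, float] = (0.05, 20.0),
        ec50_expand: float = 1000.0,
    ):
        self.direction = direction
        self.gamma_bounds = gamma_bounds
        self.ec50_expand = ec50_expand

    # -- internals ----------------------------------------------------------
    @staticmethod
    def _check_xy(X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y must align")
        if np.any(X < 0):
            raise ValueError("negative concentration")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        return X, y

    def fit(self, X, y):
        conc, y = self._check_xy(X, y)
        if len(np.unique(conc)) < 4:
            raise ValueError("sigmoid fitting needs >= 4 distinct concentrations")
        if np.ptp(y) == 0:
            raise ValueError("degenerate fit: zero variance in the response metric")

        pos = conc[conc > 0]
        lo, hi = pos.min() / self.ec50_expand, pos.max() * self.ec50_expand
        glo, ghi = self.gamma_bounds

        if self.direction == "auto":
            rho = stats.spearmanr(conc, y).statistic
            sign = -1.0 if rho < 0 else 1.0
        else:
            sign = 1.0 if self.direction == "stimulatory" else -1.0

        span = y.max() - y.min()
        e0_init = y[np.argmin(conc)]
        emax_init = sign * span if span > 0 else sign
        # EC50 starts: geometric mean of positive doses and dose nearest half-max
        half = e0_init + emax_init / 2.0
        nearest = pos[np.argmin(np.abs(hill(pos, e0_init, emax_init,
                                            np.exp(np.mean(np.log(pos))), 1.0) - half))]
        starts = {float(np.exp(np.mean(np.log(pos)))), float(nearest)}

        def theta_to_params(theta):
            return theta[0], theta[1], 10.0 ** theta[2], 10.0 ** theta[3]

        def resid(theta):
            e0, emax, ec50, gamma = theta_to_params(theta)
            return hill(conc, e0, emax, ec50, gamma) - y

        def jac(theta):
            e0, emax, ec50, gamma = theta_to_params(theta)
            J = _hill_jacobian(conc, e0, emax, ec50, gamma)
            J[:, 2] *= ec50 * np.log(10.0)   # chain rule for log10 parameters
            J[:, 3] *= gamma * np.log(10.0)
            return J

        bounds = (
            [-np.inf, -np.inf, np.log10(lo), np.log10(glo)],
            [np.inf, np.inf, np.log10(hi), np.log10(ghi)],
        )
        best = None
        for ec50_0 in sorted(starts):
            theta0 = np.array([e0_init, emax_init, np.log10(ec50_0), 0.0])
            theta0[2] = np.clip(theta0[2], bounds[0][2], bounds[1][2])
            try:
                sol = optimize.least_squares(
                    resid, theta0, jac=jac, bounds=bounds,
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        self.n_obs_ = len(y)
        if best is None:
            self._set_failed()
            return self
        e0, emax, ec50, gamma = theta_to_params(best.x)
        self.e0_, self.emax_, self.ec50_, self.gamma_ = e0, emax, ec50, gamma
        in_range = pos.min() / 100.0 <= ec50 <= pos.max() * 100.0
        self.converged_ = bool(best.success or best.cost < np.inf) and in_range

        # Gauss-Newton covariance in the natural parameterization
        dof = max(len(y) - 4, 1)
        rss = 2.0 * best.cost
        s2 = rss / dof
        J = _hill_jacobian(conc, e0, emax, ec50, gamma)
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(4, np.nan)
        self.se_ = dict(zip(_SIGMOID_PARAMS, se))
        est = dict(zip(_SIGMOID_PARAMS, (e0, emax, ec50, gamma)))
        self.rse_percent_ = _rse(est, self.se_)
        self.residual_sd_ = float(np.sqrt(s2))
        return self

    def _set_failed(self):
        self.e0_ = self.emax_ = self.ec50_ = self.gamma_ = np.nan
        self.se_ = {k: np.nan for k in _SIGMOID_PARAMS}
        self.rse_percent_ = {k: np.nan for k in _SIGMOID_PARAMS}
        self.residual_sd_ = np.nan
        self.converged_ = False

    def predict(self, X):
        conc = np.asarray(X, dtype=float)
        if conc.ndim == 2:
            conc = conc[:, 0]
        return hill(conc, self.e0_, self.emax_, self.ec50_, self.gamma_)

    def to_result(self, readout: str = "") -> SigmoidFit:
        return SigmoidFit(
            e0=float(self.e0_), emax=float(self.emax_), ec50=float(self.ec50_),
            gamma=float(self.gamma_), se=dict(self.se_),
            rse_percent=dict(self.rse_percent_),
            residual_sd=float(self.residual_sd_), converged=bool(self.converged_),
            readout=readout,
        )


# ---------------------------------------------------------------------------
# hockey-stick estimator
# ---------------------------------------------------------------------------

class HockeyStickRegressor(RegressorMixin, BaseEstimator):
    """Segmented threshold ("hockey-stick") dose-response regressor.

    E(C) = e0 below the threshold, rising linearly with slope s above it.
    The threshold is profiled: for each candidate on a grid spanning the
    tested concentrations the two linear parameters are solved in closed
    form, and the grid optimum seeds a bounded local refinement.
    """

    def __init__(self, n_grid: int = 256, identifiability_alpha: float = 0.05):
        self.n_grid = n_grid
        self.identifiability_alpha = identifiability_alpha

    @staticmethod
    def _profile_sse(conc, y, thr):
        """Closed-form linear solve of (e0, s) at a fixed threshold."""
        x = np.clip(conc - thr, 0.0, None)
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = A @ coef - y
        return float(r @ r), coef

    def fit(self, X, y):
        conc, y = EmaxRegressor._check_xy(X, y)
        if len(np.unique(conc)) < 4:
            raise ValueError("hockey-stick fitting needs >= 4 distinct concentrations")

        cmax = conc.max()
        grid = np.linspace(0.0, cmax, self.n_grid)
        # candidate thresholds between observed doses matter most; add them
        grid = np.unique(np.concatenate([grid, np.unique(conc)]))
        sse = np.array([self._profile_sse(conc, y, t)[0] for t in grid])
        i = int(np.argmin(sse))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            ref = optimize.minimize_scalar(
                lambda t: self._profile_sse(conc, y, t)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10 * max(cmax, 1.0)},
            )
            thr = float(ref.x) if ref.fun <= sse[i] else float(grid[i])
        else:
            thr = float(grid[i])
        best_sse, (e0, s) = self._profile_sse(conc, y, thr)

        self.e0_, self.slope_, self.threshold_ = float(e0), float(s), thr
        self.n_obs_ = len(y)

        # identifiability: F-test of the hinge (3 params) against a flat
        # mean-only fit; pure baseline noise should not pass
        flat_sse = float(np.sum((y - y.mean()) ** 2))
        n = len(y)
        if flat_sse == 0.0:
            p_hinge = 1.0  # exactly constant response: nothing to explain
        elif best_sse <= 1e-300 * flat_sse:
            p_hinge = 0.0
        elif n > 3 and flat_sse > best_sse:
            f_stat = ((flat_sse - best_sse) / 2.0) / (best_sse / (n - 3))
            p_hinge = float(stats.f.sf(f_stat, 2, n - 3))
        else:
            p_hinge = 1.0
        self.identifiable_ = bool(p_hinge < self.identifiability_alpha
                                  and thr < cmax)
        self.converged_ = True

        # Gauss-Newton SEs; d/dthr = -s on the active segment
        active = conc > thr
        J = np.column_stack([
            np.ones_like(conc),
            np.clip(conc - thr, 0.0, None),
            np.where(active, -s, 0.0),
        ])
        dof = max(len(y) - 3, 1)
        s2 = best_sse / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.se_ = dict(zip(_HOCKEY_PARAMS, se))
        est = dict(zip(_HOCKEY_PARAMS, (self.e0_, self.slope_, thr)))
        self.rse_percent_ = _rse(est, self.se_)
        self.residual_sd_ = float(np.sqrt(s2))
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float)
        if conc.ndim == 2:
            conc = conc[:, 0]
        return self.e0_ + self.slope_ * np.clip(conc - self.threshold_, 0.0, None)

    def to_result(self, readout: str = "") -> HockeyStickFit:
        return HockeyStickFit(
            e0=self.e0_, slope_s=self.slope_, tcb_threshold=self.threshold_,
            se=dict(self.se_), rse_percent=dict(self.rse_percent_),
            residual_sd=self.residual_sd_, converged=self.converged_,
            identifiable=self.identifiable_, readout=readout,
        )


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def fit_sigmoid(
    table: DoseResponseTable,
    direction: Literal["auto", "stimulatory", "inhibitory"] = "auto",
    readout: str = "",
) -> SigmoidFit:
    """Fit the Hill model to a dose-response table (additive error)."""
    est = EmaxRegressor(direction=direction)
    est.fit(table.concentrations.reshape(-1, 1), table.values)
    return est.to_result(readout=readout or table.metric_name)


def fit_hockey_stick(table: DoseResponseTable, readout: str = "") -> HockeyStickFit:
    """Fit the segmented threshold model to a dose-response table."""
    est = HockeyStickRegressor()
    est.fit(table.concentrations.reshape(-1, 1), table.values)
    return est.to_result(readout=readout or table.metric_name)


def fit_static(
    ds: TimeCourseDataset,
    readout: str,
    time: float,
    direction: Literal["auto", "stimulatory", "inhibitory"] = "auto",
) -> SigmoidFit:
    """Single-time-point ("static") sigmoid potency estimate.

    Aggregates replicates (median) if needed, slices the requested time
    point and fits the Hill model to the resulting dose-response.
    """
    sub = ds.select(readout)
    if ds.data.duplicated(["readout", "concentration_pm", "time_h"]).any():
        sub = aggregate_replicates(ds).select(readout)
    times = np.sort(sub["time_h"].unique())
    match = times[np.isclose(times, time)]
    if match.size == 0:
        raise ValueError(
            f"time {time:g} h not observed for {readout!r}; "
            f"available: {', '.join(f'{t:g}' for t in times)}"
        )
    slc = sub[np.isclose(sub["time_h"], match[0])].sort_values("concentration_pm")
    table = DoseResponseTable(
        f"static@{match[0]:g}h",
        slc["concentration_pm"].to_numpy(),
        slc["value"].to_numpy(),
        ds.readout_units.get(readout, ""),
    )
    return fit_sigmoid(table, direction=direction, readout=readout)


def derive_pa(fit: SigmoidFit, x_percent: float) -> float:
    """Concentration giving x% of maximal pharmacological activity.

    PA_x = EC50 * (x / (100 - x))^(1/gamma); PA_50 is exactly the EC50.
    """
    if not (0.0 < x_percent < 100.0):
        raise ValueError("x_percent must lie strictly between 0 and 100")
    if not fit.converged:
        raise ValueError("cannot derive PA from a non-converged fit")
    return float(fit.ec50 * (x_percent / (100.0 - x_percent)) ** (1.0 / fit.gamma))


def derive_ecx(fit: SigmoidFit, x_percent: float) -> float:
    """ECx/ICx alias of :func:`derive_pa` (identical Hill algebra)."""
    return derive_pa(fit, x_percent)


def compare_potencies(fits: Mapping[str, SigmoidFit]) -> pd.DataFrame:
    """Pairwise EC50 fold-ratios between converged fits.

    Returns a tidy table with columns ``numerator``, ``denominator``,
    ``fold`` (raw ratio EC50_num / EC50_den) and ``fold_rounded``.
    """
    usable = {k: f for k, f in fits.items() if f.converged}
    if len(usable) < 2:
        raise ValueError("need at least two converged fits to compare")
    rows = []
    labels = list(usable)
    for a in labels:
        for b in labels:
            if a == b:
                continue
            fold = usable[a].ec50 / usable[b].ec50
            rows.append({
                "numerator": a, "denominator": b,
                "fold": fold, "fold_rounded": int(round(fold)),
            })
    return pd.DataFrame(rows)
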