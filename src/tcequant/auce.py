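"""Time-independent effect metrics.

The central quantity is the area-under-the-effect-curve (AUCE): the
trapezoidal integral of a pharmacodynamic readout over the observed assay
window, computed per drug concentration.  Together with the maximum
response R_max and its time T_max it summarizes a whole time course in a
single dose-response point, removing the time-point-selection bias of
static (single-time) potency estimates.

Integration starts at the first observed time point; no baseline value at
t=0 is imputed (typical first observations are 18-24 h into the assay and
earlier kinetics are simply unobserved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import DoseResponseTable, TimeCourseDataset

__all__ = ["EffectSummary", "compute_auce", "summarize_effects", "auce_table"]


@dataclass(frozen=True)
class EffectSummary:
    """Per-concentration time-independent effect summary.

    auce is in readout-units x h; rmax in readout-units; tmax is the
    earliest observed time at which the maximum is attained.
    """

    concentration: float
    auce: float
    rmax: float
    tmax: float


def compute_auce(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under an effect time course.

    Points are sorted by time internally; duplicate times are rejected.
    No extrapolation is performed outside the observed window, so the
    result is sum over adjacent pairs of (t_{i+1}-t_i)*(v_i+v_{i+1})/2.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and aligned")
    if len(t) < 2:
        raise ValueError("AUCE needs at least 2 distinct time points")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate time points in effect series")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite time or value in effect series")
    return float(np.trapezoid(v, t))


def summarize_effects(
    ds: TimeCourseDataset, readout: str
) -> list[EffectSummary]:
    """One :class:`EffectSummary` per concentration, ascending.

    Requires aggregated data (one value per concentration x time).  Ties
    in the maximum resolve to the earliest time point.
    """
    sub = ds.select(readout)
    if sub.duplicated(["concentration_pm", "time_h"]).any():
        raise ValueError("summarize_effects requires aggregated data; "
                         "call aggregate_replicates first")
    out: list[EffectSummary] = []
    for conc, grp in sub.groupby("concentration_pm"):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy()
        v = grp["value"].to_numpy()
        try:
            auce = compute_auce(t, v)
        except ValueError as exc:
            raise ValueError(f"AUCE failed at concentration {conc:g} pM: {exc}") from exc
        imax = int(np.argmax(v))  # argmax returns the first maximum
        out.append(EffectSummary(float(conc), auce, float(v[imax]), float(t[imax])))
    out.sort(key=lambda s: s.concentration)
    return out


def auce_table(
    ds: TimeCourseDataset, readout: str, metric: str = "AUCE"
) -> DoseResponseTable:
    """Dose-response table of AUCE (or Rmax) values for one readout."""
    summaries = summarize_effects(ds, readout)
    conc = np.array([s.concentration for s in summaries])
    if metric == "AUCE":
        vals = np.array([s.auce for s in summaries])
        units = f"{ds.readout_units.get(readout, 'units')}*h"
    elif metric == "Rmax":
        vals = np.array([s.rmax for s in summaries])
        units = ds.readout_units.get(readout, "units")
    else:
        raise ValueError(f"unknown effect metric {metric!r}")
    return DoseResponseTable(metric, conc, vals, units)
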