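"""Data-reduction rules applied before dose-response analysis.

Mirrors standard bioanalytical practice for T-cell engager co-culture
assays: sub-LLOQ readings are reported as half the LLOQ, replicate wells
are collapsed to their median, and cytotoxicity readouts are normalized
against the time-matched drug-free control (the control grows over the
assay, so a fixed baseline would misstate kill).
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .datasets import TimeCourseDataset

__all__ = ["substitute_lloq", "aggregate_replicates", "normalize_to_control"]

logger = logging.getLogger(__name__)


def substitute_lloq(ds: TimeCourseDataset) -> TimeCourseDataset:
    """Replace every value strictly below its readout's LLOQ by LLOQ/2.

    Values exactly at the LLOQ are kept.  Readouts without an LLOQ entry
    are left untouched; if such a readout contains implausibly low values
    nothing can be substituted, and no warning is possible because "below
    LLOQ" is undefined.  The number of substitutions per readout is logged.

    The operation is idempotent: LLOQ/2 is itself below the LLOQ but maps
    to LLOQ/2 again.
    """
    df = ds.data.copy()
    for readout, lloq in ds.lloq.items():
        mask = (df["readout"] == readout) & (df["value"] < lloq)
        n = int(mask.sum())
        if n:
            df.loc[mask, "value"] = lloq / 2.0
            logger.info("LLOQ substitution: %d value(s) of %r set to %g",
                        n, readout, lloq / 2.0)
    return ds.with_data(df)


def aggregate_replicates(
    ds: TimeCourseDataset, method: Literal["median", "mean"] = "median"
) -> TimeCourseDataset:
    """Collapse replicates to one value per (readout, concentration, time).

    The default is the median, the robust summary conventionally used for
    triplicate co-culture wells.  The replicate id of the aggregate is
    ``"agg"``.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    grouped = (
        ds.data.groupby(["readout", "concentration_pm", "time_h"], as_index=False)[
            "value"
        ].agg(method)
    )
    grouped["replicate"] = "agg"
    return ds.with_data(grouped)


def normalize_to_control(
    ds: TimeCourseDataset,
    readout: str,
    mode: Literal["percent_of_control", "drug_related_kill"] = "percent_of_control",
) -> TimeCourseDataset:
    """Normalize a readout against the time-matched zero-dose control.

    ``percent_of_control``
        value(c, t) / value(0, t) * 100 — percent viability.
    ``drug_related_kill``
        (1 - value(c, t) / value(0, t)) * 100 — drug-related cytotoxicity.
        Negative kill (growth beyond control) is deliberately preserved so
        downstream effect metrics can distinguish stimulation from no
        effect.

    Requires an aggregated dataset (one value per concentration x time) and
    a zero-concentration series covering every time point of the readout.
    Other readouts pass through unchanged.
    """
    if mode not in ("percent_of_control", "drug_related_kill"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    sub = ds.select(readout)
    dup = sub.duplicated(["concentration_pm", "time_h"])
    if dup.any():
        raise ValueError("normalize_to_control requires aggregated data "
                         "(one value per concentration and time)")
    control = sub[sub["concentration_pm"] == 0].set_index("time_h")["value"]
    missing = sorted(set(sub["time_h"]) - set(control.index))
    if missing:
        raise ValueError(
            f"no zero-concentration control for {readout!r} at time(s) "
            f"{', '.join(f'{t:g} h' for t in missing)}"
        )
    if (control == 0).any():
        t0 = control.index[control == 0][0]
        raise ValueError(f"control value is zero at t={t0:g} h; cannot normalize")

    sub = sub.copy()
    ratio = sub["value"].to_numpy() / control.loc[sub["time_h"]].to_numpy()
    if mode == "percent_of_control":
        sub["value"] = ratio * 100.0
        unit = "% of control"
    else:
        sub["value"] = (1.0 - ratio) * 100.0
        unit = "% kill"

    df = ds.data.copy()
    df.loc[df["readout"] == readout, "value"] = sub["value"].to_numpy()
    out = ds.with_data(df)
    out.readout_units[readout] = unit
    out.lloq.pop(readout, None)  # LLOQ no longer meaningful on the % scale
    return out
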