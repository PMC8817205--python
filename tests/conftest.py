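"""Shared fixtures: synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

import tcequant as tq


@pytest.fixture(scope="session")
def recovery_truth():
    """Kill-model truth used for parameter-recovery studies."""
    return tq.KillModelParams(
        kg=1000.0, capacity=100_000.0, emax=0.08, ec50=20.0, tau=30.0,
        tumor0=30_000.0,
    )


@pytest.fixture(scope="session")
def slow_kill_truth():
    """Slow-kill regime: moderate kill rate, long transit delay."""
    return tq.KillModelParams(
        kg=1000.0, capacity=100_000.0, emax=0.03, ec50=20.0, tau=40.0,
        tumor0=30_000.0,
    )


@pytest.fixture(scope="session")
def noiseless_tdcc(recovery_truth):
    return tq.generate_tdcc(tq.CIBISATAMAB_DESIGN, recovery_truth,
                            tq.NoiseModel(), seed=0)


@pytest.fixture()
def tiny_timecourse():
    """One readout, one concentration, one time, three replicates."""
    df = pd.DataFrame(
        {
            "readout": ["IL6"] * 3,
            "concentration_pm": [800.0] * 3,
            "time_h": [48.0] * 3,
            "replicate": ["r1", "r2", "r3"],
            "value": [1.0, 2.0, 9.0],
        }
    )
    return tq.TimeCourseDataset(df, readout_units={"IL6": "pg/mL"},
                                lloq={"IL6": 10.0})


def make_dataset(rows, **kwargs):
    """rows: iterable of (readout, conc, time, replicate, value)."""
    df = pd.DataFrame(rows, columns=["readout", "concentration_pm", "time_h",
                                     "replicate", "value"])
    return tq.TimeCourseDataset(df, **kwargs)


@pytest.fixture()
def control_growth():
    """Aggregated two-dose dataset with a growing control."""
    rows = []
    for t, ctrl in [(24.0, 100.0), (48.0, 200.0), (72.0, 400.0)]:
        rows.append(("count", 0.0, t, "agg", ctrl))
        rows.append(("count", 100.0, t, "agg", ctrl / 2.0))
    return make_dataset(rows, readout_units={"count": "cells"})
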