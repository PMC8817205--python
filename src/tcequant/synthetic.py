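"""Synthetic TDCC-like datasets with known ground truth.

Two generators emulate the structure of T-cell-dependent cellular
cytotoxicity assays (6-8 concentrations including a drug-free control,
4-5 time points, triplicate wells):

* :func:`generate_tdcc` — tumor cell counts simulated from the delayed
  transit-compartment kill model with combined (additive + proportional)
  replicate noise, floored at zero.
* :func:`generate_cytokine` — cytokine release built as a separable
  product of a Hill dose amplitude and a pulse time profile (linear rise
  to a peak, then exponential decay).  Because time factors out, the AUCE
  dose-response of noiseless output carries exactly the generating EC50
  and Hill coefficient — an analytic ground truth for the whole AUCE
  pipeline.  This kinetic shape is a test scaffold, not a mechanistic
  cytokine model.

Both are pure functions of (design, truth, noise, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import COLUMNS, TimeCourseDataset
from .dose_response import hill
from .kill_model import KillModelParams, _simulate_tumor

__all__ = [
    "AssayDesign",
    "NoiseModel",
    "CytokineTruth",
    "CIBISATAMAB_DESIGN",
    "INCUCYTE_DESIGN",
    "generate_tdcc",
    "generate_cytokine",
]


@dataclass(frozen=True)
class AssayDesign:
    """Plate design: doses (pM, may include 0), sampling times (h), replicates."""

    doses: tuple[float, ...]
    times: tuple[float, ...]
    replicates: int = 3

    def __post_init__(self) -> None:
        if len(self.doses) < 2 or len(self.times) < 2:
            raise ValueError("need at least 2 doses and 2 time points")
        if any(d < 0 for d in self.doses) or any(t < 0 for t in self.times):
            raise ValueError("doses and times must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


#: FACS-based co-culture design (8 concentrations, 5 sampling times, triplicate)
CIBISATAMAB_DESIGN = AssayDesign(
    doses=(0.0, 6.0, 32.0, 160.0, 800.0, 4000.0, 20_000.0, 100_000.0),
    times=(24.0, 48.0, 72.0, 96.0, 168.0),
    replicates=3,
)

#: live-imaging design (6 concentrations + control, 4 supernatant times)
INCUCYTE_DESIGN = AssayDesign(
    doses=(0.0, 0.5, 5.0, 50.0, 500.0, 5000.0, 50_000.0),
    times=(18.0, 44.0, 68.0, 94.0),
    replicates=3,
)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: sd = additive_sd + proportional_cv * value."""

    additive_sd: float = 0.0
    proportional_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.proportional_cv < 0:
            raise ValueError("noise components must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        sd = self.additive_sd + self.proportional_cv * np.abs(values)
        return values + rng.normal(0.0, 1.0, size=values.shape) * sd


@dataclass(frozen=True)
class CytokineTruth:
    """Ground truth of the separable cytokine generator.

    Amplitude follows a Hill curve (ec50 pM, Hill gamma, plateau
    rmax_scale in pg/mL); the time profile rises linearly from 0 to 1 at
    peak_time and decays exponentially with decay_halflife thereafter.
    """

    ec50: float
    gamma: float = 1.2
    peak_time: float = 48.0
    decay_halflife: float = 36.0
    rmax_scale: float = 1000.0
    baseline: float = 0.0

    def amplitude(self, doses: np.ndarray) -> np.ndarray:
        return hill(doses, 0.0, self.rmax_scale, self.ec50, self.gamma)

    def pulse(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        rise = np.clip(t / self.peak_time, 0.0, 1.0) if self.peak_time > 0 else 1.0
        decay = np.where(
            t > self.peak_time,
            0.5 ** ((t - self.peak_time) / self.decay_halflife),
            1.0,
        )
        return rise * decay


def _to_dataset(
    grid: np.ndarray,
    design: AssayDesign,
    readout: str,
    unit: str,
    noise: NoiseModel,
    rng: np.random.Generator,
    lloq: float | None = None,
    floor_at_zero: bool = True,
) -> TimeCourseDataset:
    doses = np.asarray(design.doses, float)
    times = np.asarray(design.times, float)
    rows = []
    for r in range(design.replicates):
        vals = noise.apply(grid, rng)
        if floor_at_zero:
            vals = np.clip(vals, 0.0, None)
        for i, d in enumerate(doses):
            for j, t in enumerate(times):
                rows.append((readout, d, t, f"rep{r + 1}", vals[i, j]))
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return TimeCourseDataset(
        data=df,
        readout_units={readout: unit},
        lloq={} if lloq is None else {readout: float(lloq)},
    )


def generate_tdcc(
    design: AssayDesign,
    truth: KillModelParams,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    readout: str = "tumor_count",
) -> TimeCourseDataset:
    """Tumor-count time courses from the delayed-kill model plus noise.

    Deterministic given the seed; with zero noise the values equal the
    model simulation exactly (floored at zero, which never binds for the
    noiseless positive trajectories).
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(design.doses, float)
    times = np.asarray(design.times, float)
    # one integration per dose, identical to the single-dose simulator
    grid = np.vstack([_simulate_tumor(truth, [d], times)[0] for d in doses])
    return _to_dataset(grid, design, readout, "cells", noise, rng)


def generate_cytokine(
    design: AssayDesign,
    truth: CytokineTruth,
    noise: NoiseModel = NoiseModel(),
    lloq: float | None = None,
    seed: int = 0,
    readout: str = "cytokine",
) -> TimeCourseDataset:
    """Cytokine release time courses: Hill amplitude x pulse profile.

    Values below ``lloq`` are left as generated — censoring is the job of
    the downstream half-LLOQ substitution, which this generator triggers
    by attaching the LLOQ metadata to the dataset.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(design.doses, float)
    times = np.asarray(design.times, float)
    grid = (truth.baseline
            + np.outer(truth.amplitude(doses), truth.pulse(times)))
    return _to_dataset(grid, design, readout, "pg/mL", noise, rng, lloq=lloq)
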