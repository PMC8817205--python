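"""Quasi-equilibrium ternary (trimeric) complex prediction.

A CD3-bispecific binds a tumor antigen (TA) with one arm and CD3 with the
other; the pharmacologically active species is the trimeric complex
TA-drug-CD3.  Under quasi-equilibrium the species obey mass-action
relations

    dimer_ta  = C * R / Kd_ta
    dimer_cd3 = C * S / Kd_cd3
    trimer    = alpha * C * R * S / (Kd_ta * Kd_cd3)

with C, R, S the free drug, free TA and free CD3 concentrations, and the
three conservation laws for total drug, total TA and total CD3.  alpha is
an optional cooperativity factor (1 = no avidity gain on the membrane).

The solver reduces the system to a single bracketed root-find on free
drug in [0, C_tot]: at fixed C, free CD3 solves a quadratic in closed
form and free TA follows linearly, so the outer residual is monotone
enough for Brent's method on a sign-bracketing interval.

Characteristic behavior: the trimer concentration is unimodal in total
drug (the "hook effect" — at high dose, binary dimers outcompete the
trimer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TrimerSystem",
    "TrimerSolution",
    "molecules_per_cell_to_conc",
    "solve_trimer",
    "trimer_dose_scan",
]

N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class TrimerSystem:
    """Totals (pM) and dissociation constants (nM) of the ternary system.

    c_tot : total drug; r_ta_tot : total tumor antigen (convert surface
    copies with :func:`molecules_per_cell_to_conc`); r_cd3_tot : total
    CD3; kd_ta, kd_cd3 : arm dissociation constants in nM; alpha :
    dimensionless cooperativity (default 1).
    """

    c_tot: float
    r_ta_tot: float
    r_cd3_tot: float
    kd_ta: float
    kd_cd3: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_tot", "r_ta_tot", "r_cd3_tot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("kd_ta", "kd_cd3", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def kd_ta_pm(self) -> float:
        return self.kd_ta * 1e3

    @property
    def kd_cd3_pm(self) -> float:
        return self.kd_cd3 * 1e3


@dataclass(frozen=True)
class TrimerSolution:
    """Equilibrium species concentrations, all in pM."""

    free_drug: float
    dimer_ta: float
    dimer_cd3: float
    trimer: float
    free_ta: float
    free_cd3: float

    def conservation_residuals(self, sys: TrimerSystem) -> tuple[float, float, float]:
        c = self.free_drug + self.dimer_ta + self.dimer_cd3 + self.trimer
        r = self.free_ta + self.dimer_ta + self.trimer
        s = self.free_cd3 + self.dimer_cd3 + self.trimer
        return (c - sys.c_tot, r - sys.r_ta_tot, s - sys.r_cd3_tot)


def molecules_per_cell_to_conc(copies: float, cell_density_per_ml: float) -> float:
    """Surface copies/cell at a cell density (cells/mL) -> total pM.

    copies * density gives molecules/mL; times 1000 -> molecules/L;
    divided by Avogadro -> mol/L; times 1e12 -> pM.
    """
    if copies < 0 or cell_density_per_ml < 0:
        raise ValueError("copies and cell density must be >= 0")
    molecules_per_l = copies * cell_density_per_ml * 1e3
    return molecules_per_l / N_AVOGADRO * 1e12


def _free_receptors(sys: TrimerSystem, c: float) -> tuple[float, float]:
    """Free TA and CD3 at fixed free drug c, closed form.

    With u = c/Kd_ta, v = c/Kd_cd3 and g = alpha*u/Kd_cd3 the CD3 balance
    becomes a quadratic in free CD3 after eliminating free TA; the
    positive root is taken in a numerically stable form.
    """
    u = c / sys.kd_ta_pm
    v = c / sys.kd_cd3_pm
    R_tot, S_tot = sys.r_ta_tot, sys.r_cd3_tot
    g = sys.alpha * u / sys.kd_cd3_pm   # trimer = g * R * S given c

    # R*(1 + u + g*S) = R_tot ;  S*(1 + v) + g*R*S = S_tot
    # eliminate R:  S*(1+v)*(1+u+g*S) + g*R_tot*S = S_tot*(1+u+g*S)
    a = g * (1.0 + v)
    bq = (1.0 + v) * (1.0 + u) + g * (R_tot - S_tot)
    cq = -S_tot * (1.0 + u)
    if a == 0.0:  # no trimer coupling (c=0 or alpha*u underflow)
        S = S_tot / (1.0 + v)
    else:
        disc = bq * bq - 4.0 * a * cq
        disc = max(disc, 0.0)
        # stable positive root (cq <= 0 so the +sqrt branch is positive)
        S = (-bq + np.sqrt(disc)) / (2.0 * a) if bq <= 0 else 2.0 * -cq / (
            bq + np.sqrt(disc)
        )
    R = R_tot / (1.0 + u + g * S)
    return R, S


def solve_trimer(sys: TrimerSystem, xtol: float = 1e-14) -> TrimerSolution:
    """Solve the ternary quasi-equilibrium for all species.

    Bracketed root-finding (Brent) on free drug in [0, c_tot] with the
    receptor balances solved in closed form at each candidate.  All
    outputs are nonnegative and satisfy the three conservation laws to
    ~1e-6 relative.
    """
    if sys.c_tot == 0.0:
        return TrimerSolution(0.0, 0.0, 0.0, 0.0, sys.r_ta_tot, sys.r_cd3_tot)

    def drug_balance(c: float) -> float:
        R, S = _free_receptors(sys, c)
        trimer = sys.alpha * c * R / sys.kd_ta_pm * S / sys.kd_cd3_pm
        return c + c * R / sys.kd_ta_pm + c * S / sys.kd_cd3_pm + trimer - sys.c_tot

    lo, hi = 0.0, sys.c_tot
    f_lo = drug_balance(lo)          # = -c_tot < 0
    f_hi = drug_balance(hi)          # >= 0 (binding only adds mass)
    if f_hi < 0:                      # numerically flat system; free drug ~ c_tot
        c_free = sys.c_tot
    else:
        c_free = optimize.brentq(drug_balance, lo, hi,
                                 xtol=xtol * max(sys.c_tot, 1.0), rtol=8.9e-16,
                                 maxiter=200)
    R, S = _free_receptors(sys, c_free)
    dimer_ta = c_free * R / sys.kd_ta_pm
    dimer_cd3 = c_free * S / sys.kd_cd3_pm
    trimer = sys.alpha * dimer_ta * S / sys.kd_cd3_pm
    sol = TrimerSolution(
        free_drug=float(c_free), dimer_ta=float(dimer_ta),
        dimer_cd3=float(dimer_cd3), trimer=float(trimer),
        free_ta=float(R), free_cd3=float(S),
    )
    scale = max(sys.c_tot, sys.r_ta_tot, sys.r_cd3_tot)
    if any(abs(r) > 1e-6 * scale for r in sol.conservation_residuals(sys)):
        raise RuntimeError(
            f"trimer solve failed conservation check: "
            f"residuals={sol.conservation_residuals(sys)}, system={sys}"
        )
    return sol


def trimer_dose_scan(
    sys_template: TrimerSystem, c_grid: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """Trimer concentration over a dose grid.

    Returns (list of (c_tot, trimer), dose maximizing trimer).  The grid
    must be positive ascending.  The resulting curve is unimodal in dose
    (hook effect).
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid <= 0) or np.any(np.diff(c_grid) <= 0):
        raise ValueError("c_grid must be positive and strictly ascending")
    points = []
    for c in c_grid:
        sol = solve_trimer(
            TrimerSystem(float(c), sys_template.r_ta_tot, sys_template.r_cd3_tot,
                         sys_template.kd_ta, sys_template.kd_cd3,
                         sys_template.alpha)
        )
        points.append((float(c), sol.trimer))
    best = max(points, key=lambda p: p[1])
    return points, best[0]
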