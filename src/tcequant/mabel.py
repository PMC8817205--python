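"""MABEL first-in-human dose calculation and unit conversions.

The minimum anticipated biological effect level (MABEL) dose is defined
here as the dose whose initial serum Cmax equals a chosen minimally
active concentration (e.g. the PA30 of the most relevant safety readout),
assuming instantaneous distribution into a typical human plasma volume
of 3000 mL — no PK model, no absorption or clearance.  With the potency
in ng/mL the dose is simply concentration x plasma volume.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datasets import Compound
from .dose_response import SigmoidFit, derive_pa

__all__ = [
    "MabelInputs",
    "pm_to_ng_per_ml",
    "ng_per_ml_to_pm",
    "mabel_dose",
    "back_calculate_pa",
    "mabel_report",
]

DEFAULT_PLASMA_VOLUME_ML = 3000.0


@dataclass(frozen=True)
class MabelInputs:
    """Potency concentration (pM) + compound + assumed plasma volume (mL)."""

    potency_conc: float
    compound: Compound
    plasma_volume: float = DEFAULT_PLASMA_VOLUME_ML

    def __post_init__(self) -> None:
        if self.potency_conc < 0:
            raise ValueError("potency_conc must be >= 0")
        if not self.plasma_volume > 0:
            raise ValueError("plasma_volume must be > 0")


def pm_to_ng_per_ml(conc_pm: float, molecular_weight: float) -> float:
    """Molar (pM) to mass (ng/mL) concentration at a given MW (g/mol).

    conc * 1e-12 mol/L * MW g/mol = g/L; 1 g/L = 1e6 ng/mL * 1e-3 -> the
    net factor is conc * MW * 1e-6.
    """
    if conc_pm < 0:
        raise ValueError("concentration must be >= 0")
    if not molecular_weight > 0:
        raise ValueError("molecular_weight must be > 0")
    return conc_pm * 1e-12 * molecular_weight * 1e9 / 1e3


def ng_per_ml_to_pm(conc_ng_ml: float, molecular_weight: float) -> float:
    """Inverse of :func:`pm_to_ng_per_ml`."""
    if conc_ng_ml < 0:
        raise ValueError("concentration must be >= 0")
    return conc_ng_ml * 1e3 / 1e9 / molecular_weight * 1e12


def mabel_dose(inputs: MabelInputs) -> float:
    """MABEL dose in µg: potency (ng/mL) x plasma volume (mL) / 1000.

    The potency concentration dissolves instantaneously into the plasma
    volume, so the resulting Cmax equals the potency concentration.
    """
    ng_per_ml = pm_to_ng_per_ml(inputs.potency_conc,
                                inputs.compound.molecular_weight)
    return ng_per_ml * inputs.plasma_volume / 1e3


def back_calculate_pa(
    ecx_conc: float, x_percent: float, hill: float, target_percent: float
) -> float:
    """Convert an ECx into a PA_target on the same (mass or molar) scale.

    Inverts the Hill algebra: EC50 = ECx * ((100-x)/x)^(1/hill), then
    PA_target = EC50 * (target/(100-target))^(1/hill).  Used e.g. to
    translate a historically reported EC20 into a PA30 under an assumed
    Hill coefficient.
    """
    for name, v in (("x_percent", x_percent), ("target_percent", target_percent)):
        if not (0.0 < v < 100.0):
            raise ValueError(f"{name} must lie strictly between 0 and 100")
    if not hill > 0:
        raise ValueError("hill must be > 0")
    if ecx_conc < 0:
        raise ValueError("ecx_conc must be >= 0")
    ec50 = ecx_conc * ((100.0 - x_percent) / x_percent) ** (1.0 / hill)
    return ec50 * (target_percent / (100.0 - target_percent)) ** (1.0 / hill)


def mabel_report(
    fit: SigmoidFit,
    compound: Compound,
    activity_percent: float = 30.0,
    plasma_volume: float = DEFAULT_PLASMA_VOLUME_ML,
) -> dict:
    """Full potency -> first-in-human chain for one readout.

    From a fitted sigmoid: PA_x in pM, the same in ng/mL at the compound's
    MW, and the MABEL dose in µg at the assumed plasma volume.
    """
    pa_pm = derive_pa(fit, activity_percent)
    pa_ng_ml = pm_to_ng_per_ml(pa_pm, compound.molecular_weight)
    dose_ug = mabel_dose(MabelInputs(pa_pm, compound, plasma_volume))
    return {
        "readout": fit.readout,
        "compound": compound.name,
        "activity_percent": activity_percent,
        "ec50_pm": fit.ec50,
        "hill": fit.gamma,
        "pa_pm": pa_pm,
        "pa_ng_per_ml": pa_ng_ml,
        "plasma_volume_ml": plasma_volume,
        "mabel_dose_ug": dose_ug,
    }
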