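"""Empiric dose selection and label (SmPC) standard regimens.

The individualized arm solves the continuous-infusion steady-state relation
Css = daily_dose / (24 * CL) for the dose that puts Css at the target band
setpoint, then rounds to a pump-practical increment and clamps to daily-dose
bounds.  The comparison arm returns the renal-tiered standard meropenem
regimens of the German label, either as 0.5 h intermittent boluses or as the
same daily dose given as a 24 h continuous infusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pk import DoseRegimen, InvalidParameterError

__all__ = [
    "TargetDefinition",
    "DEFAULT_SMPC_TIERS",
    "round_to_increment",
    "empiric_daily_dose",
    "loading_regimen",
    "smpc_standard_regimen",
]


@dataclass(frozen=True)
class TargetDefinition:
    """Therapeutic exposure band (mg/L) and the dose-solving setpoint.

    Defaults: 8–16 mg/L (4–8x the Pseudomonas aeruginosa ECOFF of 2 mg/L)
    with the setpoint at the band midpoint, 12 mg/L.
    """

    lower: float = 8.0
    upper: float = 16.0
    setpoint: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.setpoint < self.upper:
            raise ValueError(
                f"require 0 < lower < setpoint < upper, got {self.lower}, {self.setpoint}, {self.upper}"
            )


#: (min_crcl_exclusive, dose_mg, interval_h) tiers of the German meropenem
#: SmPC for serious infections, scanned top-down; the CRRT tier overrides.
DEFAULT_SMPC_TIERS = (
    (50.0, 1000.0, 8.0),
    (25.0, 1000.0, 12.0),
    (9.0, 500.0, 12.0),
    (-1.0, 500.0, 24.0),
)
SMPC_CRRT_TIER = (1000.0, 12.0)


def round_to_increment(x: float, increment: float) -> float:
    """Round to the nearest multiple of ``increment``, ties away from zero."""
    if increment <= 0:
        raise InvalidParameterError("rounding increment must be positive")
    return math.floor(x / increment + 0.5) * increment


def empiric_daily_dose(
    target: TargetDefinition,
    cl_pred: float,
    rounding_increment_mg: float = 100.0,
    dose_bounds_mg: tuple[float, float] = (500.0, 6000.0),
) -> DoseRegimen:
    """Continuous-infusion regimen hitting the target setpoint at predicted CL.

    daily_dose = setpoint * CL * 24, rounded to ``rounding_increment_mg`` and
    clamped to ``dose_bounds_mg``.  Returned as a 24 h continuous regimen.
    """
    if cl_pred <= 0:
        raise InvalidParameterError(f"predicted clearance must be positive, got {cl_pred}")
    raw = target.setpoint * cl_pred * 24.0
    dose = round_to_increment(raw, rounding_increment_mg)
    lo, hi = dose_bounds_mg
    dose = min(max(dose, lo), hi)
    return DoseRegimen(mode="continuous", dose_mg=dose, infusion_duration_h=24.0, interval_h=24.0)


def loading_regimen() -> DoseRegimen:
    """The fixed loading dose: 500 mg infused over 15 min, once."""
    return DoseRegimen(mode="loading", dose_mg=500.0, infusion_duration_h=0.25)


def smpc_standard_regimen(
    crcl: float,
    mode: str = "bolus",
    on_crrt: bool = False,
    tiers=DEFAULT_SMPC_TIERS,
) -> DoseRegimen:
    """Label-standard meropenem regimen for the given renal function.

    ``mode='bolus'`` returns the tier as 0.5 h intermittent infusions;
    ``mode='ci'`` returns the tier's daily dose as a 24 h continuous infusion
    (equal-daily-dose comparison).
    """
    if crcl < 0:
        raise InvalidParameterError("crcl must be non-negative")
    if mode not in ("bolus", "ci"):
        raise InvalidParameterError(f"mode must be 'bolus' or 'ci', got {mode!r}")
    if on_crrt:
        dose, interval = SMPC_CRRT_TIER
    else:
        for threshold, dose, interval in tiers:
            if crcl > threshold:
                break
        else:  # pragma: no cover - last tier has threshold -1
            raise InvalidParameterError("tier table does not cover this crcl")
    if mode == "bolus":
        return DoseRegimen(mode="intermittent", dose_mg=dose, infusion_duration_h=0.5, interval_h=interval)
    daily = dose * 24.0 / interval
    return DoseRegimen(mode="continuous", dose_mg=daily, infusion_duration_h=24.0, interval_h=24.0)
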