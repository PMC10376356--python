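"""Therapeutic drug monitoring: observed clearance and dose adjustment.

Under continuous infusion at steady state the observed drug clearance
follows directly from the measured concentration:

    CL_obs [L/h] = (daily_dose [mg] / 24 h) / c [mg/L]

Dose adjustment is proportional re-dosing: the new daily dose puts the
predicted steady state at the target setpoint given CL_obs, i.e.
new_dose = current_dose * setpoint / c.  Measurements already inside the
target band leave the dose untouched (configurable no-touch rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dosing import TargetDefinition, round_to_increment
from .pk import DoseRegimen, InvalidParameterError

__all__ = [
    "ConcentrationRecord",
    "observed_clearance",
    "adjust_dose",
    "is_steady_state_sample",
]

#: Hours a sample must lie past therapy start / the last dose change for the
#: steady-state assumption behind the clearance equation to be acceptable.
DEFAULT_STEADY_STATE_LAG_H = 6.0


@dataclass(frozen=True)
class ConcentrationRecord:
    """A measured drug concentration under a known continuous-infusion dose."""

    patient_id: str
    time_h: float            # hours since therapy start
    daily_dose_mg: float     # daily dose in effect at sampling
    value: float             # measured concentration, mg/L

    @property
    def phase(self) -> str:
        """Observation stratum: 'first48' (<=48 h, empiric dosing) or 'post48'."""
        return "first48" if self.time_h <= 48.0 else "post48"


def observed_clearance(rec: ConcentrationRecord) -> float:
    """Observed clearance (daily_dose/24)/c, L/h; requires c > 0 at steady state."""
    if rec.value <= 0:
        raise InvalidParameterError(
            f"measured concentration must be positive for clearance estimation, got {rec.value}"
        )
    if rec.daily_dose_mg <= 0:
        raise InvalidParameterError("daily dose at sampling must be positive")
    return (rec.daily_dose_mg / 24.0) / rec.value


def is_steady_state_sample(
    rec: ConcentrationRecord,
    last_dose_change_h: float = 0.0,
    lag_h: float = DEFAULT_STEADY_STATE_LAG_H,
) -> bool:
    """Whether the sample is far enough past the last dose change to assume Css."""
    return rec.time_h - last_dose_change_h >= lag_h


def adjust_dose(
    current: DoseRegimen,
    rec: ConcentrationRecord,
    target: TargetDefinition,
    rounding_increment_mg: float = 100.0,
    dose_bounds_mg: tuple[float, float] = (500.0, 6000.0),
    no_touch_in_band: bool = True,
) -> DoseRegimen:
    """TDM-guided proportional dose adjustment to the target setpoint.

    Returns a 24 h continuous regimen whose predicted steady state (given the
    observed clearance) equals ``target.setpoint`` before rounding; an
    in-band measurement returns the current regimen unchanged when the
    no-touch rule is active.
    """
    cl_obs = observed_clearance(rec)  # validates the record
    if no_touch_in_band and target.lower <= rec.value <= target.upper:
        return current
    new_daily = target.setpoint * cl_obs * 24.0  # == current_daily * setpoint / c
    dose = round_to_increment(new_daily, rounding_increment_mg)
    lo, hi = dose_bounds_mg
    dose = min(max(dose, lo), hi)
    return DoseRegimen(mode="continuous", dose_mg=dose, infusion_duration_h=24.0, interval_h=24.0)
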