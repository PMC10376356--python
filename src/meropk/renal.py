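"""Renal function estimation and renally adjusted clearance prediction.

Creatinine clearance is estimated with the Cockcroft–Gault equation from
age, actual body weight, sex and serum creatinine.  Drug clearance is then
predicted with the Dettli method: total clearance is the sum of a non-renal
fraction (q0) and a renal fraction scaling linearly with creatinine
clearance.  Under continuous renal replacement therapy (CRRT) the renal term
is replaced by the extracorporeal clearance, approximately effluent flow
times the saturation coefficient (~1 for small, unbound molecules such as
meropenem).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "CrrtSettings",
    "RenalStatus",
    "PopulationPkConfig",
    "crcl_cockcroft_gault",
    "predict_clearance",
]


@dataclass(frozen=True)
class CrrtSettings:
    """Continuous renal replacement therapy settings.

    effluent_flow: total effluent (dialysate + ultrafiltrate) flow, L/h.
    saturation_coefficient: fraction of plasma concentration recovered in the
    effluent, dimensionless in [0, 1].
    """

    effluent_flow: float = 2.0
    saturation_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.effluent_flow < 0:
            raise ValueError("effluent_flow must be non-negative")
        if not 0.0 <= self.saturation_coefficient <= 1.0:
            raise ValueError("saturation_coefficient must be in [0, 1]")


@dataclass(frozen=True)
class RenalStatus:
    """A patient's renal elimination status at dosing time."""

    serum_creatinine: float  # mg/dL
    crcl: float              # mL/min
    on_crrt: bool = False
    crrt: CrrtSettings | None = None

    def __post_init__(self) -> None:
        if self.serum_creatinine <= 0:
            raise ValueError("serum_creatinine must be positive")
        if self.crcl < 0:
            raise ValueError("crcl must be non-negative")
        if self.on_crrt and self.crrt is None:
            object.__setattr__(self, "crrt", CrrtSettings())
        if not self.on_crrt and self.crrt is not None:
            raise ValueError("crrt settings supplied for a patient not on CRRT")


@dataclass(frozen=True)
class PopulationPkConfig:
    """Population PK constants anchoring the Dettli prediction.

    cl_normal: total clearance at the reference renal function, L/h.
    q0: non-renal fraction of cl_normal (the anuric floor is q0*cl_normal).
    crcl_reference: creatinine clearance at which clearance equals cl_normal,
    mL/min.  volume: distribution volume for concentration predictions, L.
    """

    cl_normal: float = 12.5
    q0: float = 0.25
    crcl_reference: float = 100.0
    volume: float = 25.0
    include_residual_renal_on_crrt: bool = False
    crcl_cap: float | None = None  # optional ARC guard, mL/min

    def __post_init__(self) -> None:
        if self.cl_normal <= 0:
            raise ValueError("cl_normal must be positive")
        if not 0.0 < self.q0 < 1.0:
            raise ValueError("q0 must be in (0, 1)")
        if self.crcl_reference <= 0:
            raise ValueError("crcl_reference must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


def crcl_cockcroft_gault(age: float, weight: float, serum_creatinine: float, sex: str) -> float:
    """Cockcroft–Gault creatinine clearance, mL/min.

    CrCL = (140 - age) * weight / (72 * SCr), times 0.85 for women.
    Age in years, actual body weight in kg, serum creatinine in mg/dL.
    Ages >= 140 (degenerate) clamp the estimate to 0 with a warning.
    """
    if age < 18:
        raise ValueError(f"adult equation; age must be >= 18, got {age}")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if serum_creatinine <= 0:
        raise ValueError("serum_creatinine must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if age >= 140:
        warnings.warn(f"age {age} >= 140 yields non-positive CrCL; clamping to 0", stacklevel=2)
        return 0.0
    crcl = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex == "female":
        crcl *= 0.85
    return crcl


def predict_clearance(cfg: PopulationPkConfig, renal: RenalStatus) -> float:
    """Dettli-predicted drug clearance, L/h.

    Without CRRT::

        CL = q0*cl_normal + (1 - q0)*cl_normal * (CrCL / crcl_reference)

    affine and non-decreasing in CrCL, with the anuric floor q0*cl_normal at
    CrCL = 0 and exactly cl_normal at the reference CrCL.

    With CRRT the renal term is replaced by the extracorporeal clearance
    ``saturation_coefficient * effluent_flow``; residual renal clearance is
    excluded unless ``cfg.include_residual_renal_on_crrt`` is set.
    """
    crcl = renal.crcl
    if crcl < 0:
        raise ValueError("crcl must be non-negative")
    if cfg.crcl_cap is not None:
        crcl = min(crcl, cfg.crcl_cap)
    nonrenal = cfg.q0 * cfg.cl_normal
    renal_term = (1.0 - cfg.q0) * cfg.cl_normal * (crcl / cfg.crcl_reference)
    if renal.on_crrt:
        crrt = renal.crrt
        cl = nonrenal + crrt.saturation_coefficient * crrt.effluent_flow
        if cfg.include_residual_renal_on_crrt:
            cl += renal_term
        return cl
    return nonrenal + renal_term
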