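"""One-compartment pharmacokinetic model with first-order elimination.

Closed-form concentration predictions for the three administration modes used
in continuous-infusion beta-lactam therapy:

* a short loading infusion (single dose),
* a 24 h continuous infusion (CI), and
* repeated intermittent infusions at steady state.

All concentrations are total plasma concentrations in mg/L, times in hours,
doses in mg, clearance in L/h and volume in L.  Meropenem has negligible
protein binding, so free and total concentrations are treated as equal.

A numeric ODE integrator (:func:`conc_by_ode`) is provided as an independent
oracle for the closed forms; it integrates ``dC/dt = R(t)/V - k_e * C``
directly and shares no code with the analytic expressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PkParameters",
    "DoseRegimen",
    "conc_continuous_infusion",
    "conc_single_infusion",
    "conc_intermittent_ss",
    "conc_profile",
    "conc_by_ode",
]


class InvalidParameterError(ValueError):
    """Raised for non-physical PK parameters or doses."""


@dataclass(frozen=True)
class PkParameters:
    """Clearance/volume parameterization of the one-compartment model.

    Parameters
    ----------
    clearance : float
        Drug clearance CL, L/h.  Must be positive.
    volume : float
        Apparent volume of distribution V, L.  Must be positive.
    """

    clearance: float
    volume: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.clearance) and self.clearance > 0):
            raise InvalidParameterError(f"clearance must be positive, got {self.clearance}")
        if not (math.isfinite(self.volume) and self.volume > 0):
            raise InvalidParameterError(f"volume must be positive, got {self.volume}")

    @property
    def k_e(self) -> float:
        """First-order elimination rate constant CL/V, 1/h."""
        return self.clearance / self.volume


#: Administration modes.
MODES = ("loading", "continuous", "intermittent")


@dataclass(frozen=True)
class DoseRegimen:
    """A dosing regimen: amount, infusion duration and repeat interval.

    ``mode`` is one of ``loading`` (single short infusion, not repeated),
    ``continuous`` (the daily dose infused over 24 h, repeated back to back,
    i.e. a constant-rate infusion) or ``intermittent`` (repeated short
    infusions every ``interval_h``).
    """

    mode: str
    dose_mg: float
    infusion_duration_h: float
    interval_h: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.dose_mg <= 0:
            raise InvalidParameterError(f"dose_mg must be positive, got {self.dose_mg}")
        if self.infusion_duration_h <= 0:
            raise InvalidParameterError("infusion_duration_h must be positive")
        if self.mode == "loading":
            if self.interval_h is not None:
                raise InvalidParameterError("loading regimens carry no interval")
        else:
            if self.interval_h is None:
                raise InvalidParameterError(f"{self.mode} regimen requires interval_h")
            if self.infusion_duration_h > self.interval_h:
                raise InvalidParameterError(
                    "infusion_duration_h must not exceed interval_h "
                    f"({self.infusion_duration_h} > {self.interval_h})"
                )

    @property
    def daily_dose_mg(self) -> float:
        """Maintenance daily dose, mg/day.  Loading doses do not count."""
        if self.mode == "loading":
            return 0.0
        return self.dose_mg * 24.0 / self.interval_h  # type: ignore[operator]

    @property
    def rate_mg_h(self) -> float:
        """Infusion rate while the pump runs, mg/h."""
        return self.dose_mg / self.infusion_duration_h


def conc_continuous_infusion(rate_mg_h: float, pk: PkParameters, t) -> np.ndarray | float:
    """Concentration during a constant-rate infusion started at t=0 from zero.

    C(t) = (R0/CL) * (1 - exp(-k_e t)); approaches the steady state R0/CL.
    Accepts scalar or array ``t`` (hours, >= 0).
    """
    if rate_mg_h < 0:
        raise InvalidParameterError(f"rate must be non-negative, got {rate_mg_h}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be non-negative")
    c = (rate_mg_h / pk.clearance) * (1.0 - np.exp(-pk.k_e * t_arr))
    return float(c) if np.isscalar(t) else c


def conc_single_infusion(dose_mg: float, infusion_duration_h: float, pk: PkParameters, t) -> np.ndarray | float:
    """Concentration after a single infusion of ``dose_mg`` over ``infusion_duration_h``.

    Rises per :func:`conc_continuous_infusion` while the pump runs, then
    decays mono-exponentially.
    """
    rate = dose_mg / infusion_duration_h
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    c = np.empty_like(t_arr)
    during = t_arr <= infusion_duration_h
    c[during] = (rate / pk.clearance) * (1.0 - np.exp(-pk.k_e * t_arr[during]))
    c_end = (rate / pk.clearance) * (1.0 - math.exp(-pk.k_e * infusion_duration_h))
    c[~during] = c_end * np.exp(-pk.k_e * (t_arr[~during] - infusion_duration_h))
    return float(c[0]) if np.isscalar(t) else c


def conc_intermittent_ss(reg: DoseRegimen, pk: PkParameters, t_in_interval: float) -> float:
    """Steady-state concentration within a dosing interval of repeated infusions.

    Standard multiple-infusion superposition with accumulation factor
    ``1/(1 - exp(-k_e * tau))``.  ``t_in_interval`` is hours since the start
    of the current infusion, in [0, tau].  The trough is the value at
    ``t_in_interval = tau``.
    """
    if reg.mode != "intermittent":
        raise InvalidParameterError(f"regimen mode must be intermittent, got {reg.mode!r}")
    tau = reg.interval_h
    tinf = reg.infusion_duration_h
    if not 0.0 <= t_in_interval <= tau:
        raise InvalidParameterError(f"t_in_interval {t_in_interval} outside [0, {tau}]")
    ke = pk.k_e
    rate = reg.rate_mg_h
    acc = 1.0 / (1.0 - math.exp(-ke * tau))
    # residual of all previous doses, each fully infused, decayed into this interval
    prev_end = (rate / pk.clearance) * (1.0 - math.exp(-ke * tinf))
    if t_in_interval <= tinf:
        current = (rate / pk.clearance) * (1.0 - math.exp(-ke * t_in_interval))
        residual = prev_end * math.exp(-ke * (tau - tinf + t_in_interval)) * acc
        return current + residual
    return prev_end * math.exp(-ke * (t_in_interval - tinf)) * acc


def conc_profile(
    regimens: Sequence[tuple[float, DoseRegimen]],
    pk: PkParameters,
    times: Iterable[float],
) -> np.ndarray:
    """Concentration-time profile under superposed regimens (linear PK).

    Parameters
    ----------
    regimens
        ``(start_h, regimen)`` pairs.  Loading regimens contribute a single
        infusion; continuous regimens a constant-rate infusion from their
        start onward; intermittent regimens repeat every interval from their
        start through the last requested time.
    times
        Sorted sample times, hours.

    Returns the summed concentration at each time (mg/L).
    """
    if not regimens:
        raise InvalidParameterError("empty regimen list")
    t = np.asarray(list(times), dtype=float)
    total = np.zeros_like(t)
    t_max = t.max() if t.size else 0.0
    for start, reg in regimens:
        rel = t - start
        active = rel > 0
        if not np.any(active):
            continue
        contrib = np.zeros_like(t)
        if reg.mode == "continuous":
            contrib[active] = conc_continuous_infusion(reg.rate_mg_h, pk, rel[active])
        elif reg.mode == "loading":
            contrib[active] = conc_single_infusion(reg.dose_mg, reg.infusion_duration_h, pk, rel[active])
        else:  # intermittent: superpose repeated doses
            n_doses = int(math.floor((t_max - start) / reg.interval_h)) + 1
            for i in range(n_doses):
                rel_i = rel - i * reg.interval_h
                act_i = rel_i > 0
                if not np.any(act_i):
                    break
                contrib[act_i] += conc_single_infusion(
                    reg.dose_mg, reg.infusion_duration_h, pk, rel_i[act_i]
                )
        total += contrib
    return total


def conc_by_ode(
    segments: Sequence[tuple[float, float, float]],
    pk: PkParameters,
    times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numeric oracle: integrate dC/dt = R(t)/V - k_e*C for piecewise-constant rates.

    Parameters
    ----------
    segments
        ``(start_h, duration_h, rate_mg_h)`` infusion windows; rates add where
        windows overlap.
    times
        Sorted, non-negative sample times.

    The integration is split at every window edge so the solver never steps
    across a rate discontinuity.
    """
    times = np.asarray(times, dtype=float)
    breaks = {0.0}
    for start, dur, _ in segments:
        breaks.add(start)
        breaks.add(start + dur)
    breaks.update(times.tolist())
    grid = np.array(sorted(b for b in breaks if b <= times.max() + 1e-12))

    def rate_at(t: float) -> float:
        return sum(r for s, d, r in segments if s <= t < s + d)

    ke = pk.k_e
    out = {}
    c = 0.0
    if grid[0] in times:
        out[grid[0]] = c
    for a, b in zip(grid[:-1], grid[1:]):
        if b - a < 1e-15:
            out[b] = c
            continue
        rate = rate_at((a + b) / 2.0)
        sol = solve_ivp(
            lambda t, y: [rate / pk.volume - ke * y[0]],
            (a, b),
            [c],
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        c = float(sol.y[0, -1])
        out[b] = c
    return np.array([out[t] for t in times])
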