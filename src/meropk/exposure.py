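"""Exposure-band classification and dosing-strategy comparison.

Concentrations are classified into five ordered bands anchored on the
Pseudomonas aeruginosa ECOFF (2 mg/L): <2 (subtherapeutic), 2–8, 8–16
(therapeutic target), 16–24 (moderately high) and >24 mg/L (potentially
harmful).  Edges are half-open with ties going upward ([8, 16) is
therapeutic) except that 24.0 itself remains moderately high, matching the
strict ">24" definition of the harmful band.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dosing import TargetDefinition, empiric_daily_dose, smpc_standard_regimen
from .pk import InvalidParameterError, PkParameters, conc_intermittent_ss

__all__ = [
    "ExposureBand",
    "BandTally",
    "classify_band",
    "tally_bands",
    "compare_strategies",
    "round_half_up",
    "STRATEGIES",
]


class ExposureBand(enum.IntEnum):
    """Ordered concentration bands, mg/L."""

    below_2 = 0
    from_2_to_8 = 1
    therapeutic_8_16 = 2
    moderate_16_24 = 3
    harmful_above_24 = 4

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    ExposureBand.below_2: "<2",
    ExposureBand.from_2_to_8: "2-8",
    ExposureBand.therapeutic_8_16: "8-16",
    ExposureBand.moderate_16_24: "16-24",
    ExposureBand.harmful_above_24: ">24",
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (table-style percentages)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def classify_band(c: float) -> ExposureBand:
    """Map a positive concentration (mg/L) to its exposure band."""
    if not (c > 0 and math.isfinite(c)):
        raise InvalidParameterError(f"concentration must be positive and finite, got {c}")
    if c < 2.0:
        return ExposureBand.below_2
    if c < 8.0:
        return ExposureBand.from_2_to_8
    if c < 16.0:
        return ExposureBand.therapeutic_8_16
    if c <= 24.0:
        return ExposureBand.moderate_16_24
    return ExposureBand.harmful_above_24


@dataclass(frozen=True)
class BandTally:
    """Counts of concentrations per exposure band, with table percentages."""

    counts: Mapping[ExposureBand, int]

    @classmethod
    def from_counts(cls, counts: Mapping[ExposureBand, int]) -> "BandTally":
        full = {band: int(counts.get(band, 0)) for band in ExposureBand}
        if any(v < 0 for v in full.values()):
            raise InvalidParameterError("band counts must be non-negative")
        return cls(counts=full)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def fraction(self, band: ExposureBand) -> float:
        return self.counts[band] / self.n

    def percent(self, band: ExposureBand, decimals: int = 1) -> float:
        """Percentage of measurements in ``band``, half-up to ``decimals``."""
        return round_half_up(100.0 * self.fraction(band), decimals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": [b.label for b in ExposureBand],
                "count": [self.counts[b] for b in ExposureBand],
                "percent": [self.percent(b) for b in ExposureBand],
            }
        )


def tally_bands(values: Iterable[float]) -> BandTally:
    """Classify every concentration and tally the bands."""
    values = list(values)
    if not values:
        raise InvalidParameterError("cannot tally an empty list of concentrations")
    counts: dict[ExposureBand, int] = {band: 0 for band in ExposureBand}
    for v in values:
        counts[classify_band(v)] += 1
    return BandTally.from_counts(counts)


STRATEGIES = ("standard_bolus", "standard_ci", "individualized_ci")


def compare_strategies(
    measurements: pd.DataFrame,
    volume: float = 25.0,
    target: TargetDefinition | None = None,
    strategies: Sequence[str] = STRATEGIES,
    rounding_increment_mg: float = 100.0,
    dose_bounds_mg: tuple[float, float] = (500.0, 6000.0),
    per_patient: bool = False,
) -> dict[str, BandTally]:
    """Predicted exposure bands per dosing strategy at observed clearances.

    ``measurements`` needs columns ``clearance_L_h``, ``crcl_ml_min`` and
    ``on_crrt`` (and ``patient_id`` if ``per_patient``); one row per
    measurement occasion.  For each strategy the classified concentration is:

    * ``standard_bolus`` — steady-state trough of the label tier given as
      0.5 h infusions (the binding value for 100% fT>MIC),
    * ``standard_ci`` — Css of the same daily dose as a 24 h infusion,
    * ``individualized_ci`` — Css of the setpoint-solved dose at the
      observed clearance.

    With ``per_patient`` the clearances are first averaged per patient so
    each patient contributes one classification.
    """
    target = target or TargetDefinition()
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise InvalidParameterError(f"unknown strategies: {sorted(unknown)}")
    df = measurements
    if per_patient:
        df = (
            df.groupby("patient_id", as_index=False)
            .agg(clearance_L_h=("clearance_L_h", "mean"), crcl_ml_min=("crcl_ml_min", "first"), on_crrt=("on_crrt", "first"))
        )
    out: dict[str, BandTally] = {}
    for strat in strategies:
        concs = []
        for row in df.itertuples(index=False):
            cl = float(row.clearance_L_h)
            pk = PkParameters(clearance=cl, volume=volume)
            if strat == "standard_bolus":
                reg = smpc_standard_regimen(float(row.crcl_ml_min), mode="bolus", on_crrt=bool(row.on_crrt))
                c = conc_intermittent_ss(reg, pk, reg.interval_h)  # trough
            elif strat == "standard_ci":
                reg = smpc_standard_regimen(float(row.crcl_ml_min), mode="ci", on_crrt=bool(row.on_crrt))
                c = reg.daily_dose_mg / (24.0 * cl)
            else:
                reg = empiric_daily_dose(target, cl, rounding_increment_mg, dose_bounds_mg)
                c = reg.daily_dose_mg / (24.0 * cl)
            concs.append(c)
        out[strat] = tally_bands(concs)
    return out
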