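"""Run configuration: schema-validated JSON config for the pipeline.

Unknown keys are rejected (``extra='forbid'``) so typos fail loudly before
any stage runs.  ``RunConfig.default()`` gives the study-default settings;
``load_config`` reads a JSON file and validates it against the schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import CohortConfig
from .dosing import DEFAULT_SMPC_TIERS, TargetDefinition
from .renal import PopulationPkConfig

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationPkSection(_Strict):
    cl_normal: float = 12.5
    q0: float = Field(default=0.25, gt=0, lt=1)
    crcl_reference: float = 100.0
    volume: float = 25.0
    include_residual_renal_on_crrt: bool = False
    crcl_cap: float | None = None

    def to_domain(self) -> PopulationPkConfig:
        return PopulationPkConfig(**self.model_dump())


class TargetSection(_Strict):
    lower: float = 8.0
    upper: float = 16.0
    setpoint: float = 12.0

    def to_domain(self) -> TargetDefinition:
        return TargetDefinition(**self.model_dump())


class SmpcTier(_Strict):
    min_crcl_exclusive: float
    dose_mg: float
    interval_h: float


class SyntheticSection(_Strict):
    n: int = Field(default=500, ge=1)
    omega: float = Field(default=0.25, ge=0)
    assay_cv: float = Field(default=0.10, ge=0)
    crrt_fraction: float = Field(default=0.13, ge=0, le=1)
    crcl_cap: float = 130.0
    post48_samples_min: int = Field(default=1, ge=1)
    post48_samples_max: int = Field(default=3, ge=1)


class StatsSection(_Strict):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    yates_correction: bool = False


class RunConfig(_Strict):
    population_pk: PopulationPkSection = Field(default_factory=PopulationPkSection)
    target: TargetSection = Field(default_factory=TargetSection)
    rounding_increment_mg: float = Field(default=100.0, gt=0)
    dose_bounds_mg: tuple[float, float] = (500.0, 6000.0)
    smpc_tiers: list[SmpcTier] = Field(
        default_factory=lambda: [
            SmpcTier(min_crcl_exclusive=t, dose_mg=d, interval_h=i) for t, d, i in DEFAULT_SMPC_TIERS
        ]
    )
    no_touch_in_band: bool = True
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    stats: StatsSection = Field(default_factory=StatsSection)
    seed: int = 42
    output_dir: str = "out"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_bounds(self) -> "RunConfig":
        lo, hi = self.dose_bounds_mg
        if not 0 < lo < hi:
            raise ValueError(f"dose_bounds_mg must satisfy 0 < lower < upper, got {self.dose_bounds_mg}")
        if self.synthetic.post48_samples_min > self.synthetic.post48_samples_max:
            raise ValueError("post48_samples_min must not exceed post48_samples_max")
        return self

    @classmethod
    def default(cls) -> "RunConfig":
        return cls()

    def tier_tuples(self) -> tuple[tuple[float, float, float], ...]:
        return tuple((t.min_crcl_exclusive, t.dose_mg, t.interval_h) for t in self.smpc_tiers)

    def cohort_config(self, seed: int | None = None) -> CohortConfig:
        return CohortConfig(
            n=self.synthetic.n,
            seed=self.seed if seed is None else seed,
            omega=self.synthetic.omega,
            assay_cv=self.synthetic.assay_cv,
            crrt_fraction=self.synthetic.crrt_fraction,
            crcl_cap=self.synthetic.crcl_cap,
            population=self.population_pk.to_domain(),
        )

    def config_hash(self) -> str:
        """Stable hash of the validated config, for run provenance."""
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON run config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig.default()
    raw = json.loads(Path(path).read_text())
    return RunConfig.model_validate(raw)
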