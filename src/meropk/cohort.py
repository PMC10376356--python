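"""Seeded virtual ICU cohorts and the end-to-end dosing program simulation.

The generator emulates a septic ICU population: elderly, renally impaired
(median CrCL ~45 mL/min), 13% on CRRT, no augmented renal clearance.
Marginals are parameterized by median/IQR — log-normal for weight,
creatinine clearance and (derived) serum creatinine, truncated normal for
age, height and severity scores, Bernoulli for sex and CRRT.  Each
patient's latent true meropenem clearance is the Dettli prediction at their
CrCL multiplied by a log-normal between-patient deviation exp(eta),
eta ~ N(0, omega^2) truncated at +/-2 SD; omega defaults to 0.25,
calibrated so the predicted-vs-observed clearance Pearson correlation of a
default cohort sits in the low-to-mid 0.8s, the range reported for renal
dosing calculators in this population.  Measurements carry proportional
assay noise (default CV 10%).

Hospital mortality is generated from the SOFA score alone (logistic, odds
ratio 1.161 per point), so by construction drug exposure does not cause
death in the synthetic world — the null the cohort statistics should
recover.

``simulate_tdm_program`` runs the full program per patient: 500 mg loading
dose, software-guided empiric continuous infusion, one measured
concentration in the first 48 h, proportional TDM adjustment, then 1–3
post-48 h measurements; it returns band tallies per phase, the
three-strategy comparison and the mortality-by-band statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosing import TargetDefinition, empiric_daily_dose, loading_regimen
from .exposure import BandTally, ExposureBand, compare_strategies, tally_bands
from .renal import CrrtSettings, PopulationPkConfig, RenalStatus, predict_clearance
from .stats import ChiSquareResult, ContingencyTable2x2, OddsRatioResult, chi_square, odds_ratio_woolf
from .tdm import ConcentrationRecord, adjust_dose

__all__ = ["CohortConfig", "PatientProfile", "SimulationResult", "generate_cohort", "simulate_tdm_program"]

_Z_QUARTILE = 0.6744897501960817  # standard normal 75th percentile


def _lognormal_sigma(median: float, iqr: float) -> float:
    """Sigma of a log-normal with the given median and interquartile range."""
    return math.asinh(iqr / (2.0 * median)) / _Z_QUARTILE


def _normal_sd(iqr: float) -> float:
    return iqr / (2.0 * _Z_QUARTILE)


@dataclass(frozen=True)
class PatientProfile:
    """One virtual patient.  ``true_clearance`` is latent (generator-only)."""

    patient_id: str
    age: float                 # years
    sex: str                   # 'male' | 'female'
    weight: float              # kg
    height: float              # cm
    serum_creatinine: float    # mg/dL
    crcl: float                # mL/min (Cockcroft-Gault-consistent)
    on_crrt: bool
    crrt: CrrtSettings | None
    sofa: int
    saps: int
    died_in_hospital: bool
    true_clearance: float      # L/h, latent

    def renal_status(self) -> RenalStatus:
        return RenalStatus(
            serum_creatinine=self.serum_creatinine,
            crcl=self.crcl,
            on_crrt=self.on_crrt,
            crrt=self.crrt if self.on_crrt else None,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Study-population marginals and noise model for the generator.

    Location/spread values are median/IQR of the emulated population.
    ``omega`` is the SD of the log-normal between-patient deviation of true
    clearance around the Dettli prediction (truncated at
    ``eta_trunc_sd`` SDs); ``assay_cv`` the proportional measurement noise.
    """

    n: int = 500
    seed: int = 42
    age_median: float = 73.0
    age_iqr: float = 18.0
    age_bounds: tuple[float, float] = (18.0, 100.0)
    weight_median: float = 80.0
    weight_iqr: float = 20.0
    height_median: float = 170.0
    height_iqr: float = 10.0
    male_fraction: float = 0.66
    crcl_median: float = 45.3
    crcl_iqr: float = 53.7
    crcl_cap: float = 130.0          # no augmented renal clearance
    crrt_fraction: float = 0.13
    crrt_effluent_flow: float = 2.0  # L/h
    crrt_saturation: float = 1.0
    sofa_median: float = 8.0
    sofa_iqr: float = 8.0
    saps_median: float = 41.0
    saps_iqr: float = 18.0
    omega: float = 0.25
    eta_trunc_sd: float = 2.0
    assay_cv: float = 0.10
    mortality_slope: float = math.log(1.161)   # per SOFA point
    mortality_intercept: float = -1.835        # cohort-mean mortality ~39% under the SOFA marginal
    population: PopulationPkConfig = field(default_factory=PopulationPkConfig)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.omega < 0 or self.assay_cv < 0:
            raise ValueError("omega and assay_cv must be non-negative")


def _truncated_normal(rng: np.random.Generator, loc, scale, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds far enough out that this is cheap)."""
    if scale == 0:
        return np.full(size, float(np.clip(loc, lo, hi)))
    out = rng.normal(loc, scale, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(cfg: CohortConfig) -> list[PatientProfile]:
    """Draw a deterministic virtual cohort for the given config/seed.

    Serum creatinine is back-derived from the sampled CrCL by inverting
    Cockcroft–Gault, so the cohort CSV is self-consistent: re-estimating
    CrCL from the demographics reproduces the sampled value.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    age = _truncated_normal(rng, cfg.age_median, _normal_sd(cfg.age_iqr), *cfg.age_bounds, size=n)
    weight = cfg.weight_median * np.exp(rng.normal(0.0, _lognormal_sigma(cfg.weight_median, cfg.weight_iqr), n))
    height = _truncated_normal(rng, cfg.height_median, _normal_sd(cfg.height_iqr), 140.0, 210.0, size=n)
    male = rng.random(n) < cfg.male_fraction
    crcl = cfg.crcl_median * np.exp(rng.normal(0.0, _lognormal_sigma(cfg.crcl_median, cfg.crcl_iqr), n))
    crcl = np.minimum(crcl, cfg.crcl_cap)
    on_crrt = rng.random(n) < cfg.crrt_fraction
    sofa = np.rint(_truncated_normal(rng, cfg.sofa_median, _normal_sd(cfg.sofa_iqr), 0.0, 24.0, size=n)).astype(int)
    saps = np.rint(_truncated_normal(rng, cfg.saps_median, _normal_sd(cfg.saps_iqr), 0.0, 120.0, size=n)).astype(int)

    # invert Cockcroft-Gault for a consistent serum creatinine; after clipping
    # SCr to the assay range, recompute CrCL so the two stay exactly consistent
    sex_factor = np.where(male, 1.0, 0.85)
    scr = (140.0 - age) * weight * sex_factor / (72.0 * crcl)
    scr = np.clip(scr, 0.1, 15.0)  # upper clip only binds at extreme anuria; lower never given the CrCL cap
    crcl = np.minimum((140.0 - age) * weight * sex_factor / (72.0 * scr), cfg.crcl_cap)

    eta_cap = cfg.eta_trunc_sd * cfg.omega
    if cfg.omega > 0:
        eta = _truncated_normal(rng, 0.0, cfg.omega, -eta_cap, eta_cap, size=n)
    else:
        eta = np.zeros(n)

    logit = cfg.mortality_intercept + cfg.mortality_slope * sofa
    p_death = 1.0 / (1.0 + np.exp(-logit))
    died = rng.random(n) < p_death

    crrt_settings = CrrtSettings(cfg.crrt_effluent_flow, cfg.crrt_saturation)
    patients = []
    for i in range(n):
        status = RenalStatus(
            serum_creatinine=float(scr[i]),
            crcl=float(crcl[i]),
            on_crrt=bool(on_crrt[i]),
            crrt=crrt_settings if on_crrt[i] else None,
        )
        cl_pred = predict_clearance(cfg.population, status)
        patients.append(
            PatientProfile(
                patient_id=f"P{i + 1:04d}",
                age=float(age[i]),
                sex="male" if male[i] else "female",
                weight=float(weight[i]),
                height=float(height[i]),
                serum_creatinine=float(scr[i]),
                crcl=float(crcl[i]),
                on_crrt=bool(on_crrt[i]),
                crrt=crrt_settings if on_crrt[i] else None,
                sofa=int(sofa[i]),
                saps=int(saps[i]),
                died_in_hospital=bool(died[i]),
                true_clearance=float(cl_pred * math.exp(eta[i])),
            )
        )
    return patients


@dataclass
class SimulationResult:
    """Outputs of one end-to-end simulated TDM program."""

    patients: pd.DataFrame          # per-patient doses and predictions
    measurements: pd.DataFrame      # all simulated concentration records
    tally_first48: BandTally
    tally_post48: BandTally
    strategy_tallies: dict[str, BandTally]
    mortality_table: ContingencyTable2x2 | None
    mortality_or: OddsRatioResult | None
    mortality_chi2: ChiSquareResult | None
    mortality_band: ExposureBand | None     # high band used in the 2x2 (vs therapeutic)
    recovery_slope: float           # observed vs true clearance OLS slope
    pred_vs_obs_pearson_r: float    # predicted vs observed clearance

    def therapeutic_fraction(self, phase: str) -> float:
        tally = self.tally_first48 if phase == "first48" else self.tally_post48
        return tally.fraction(ExposureBand.therapeutic_8_16)


def simulate_tdm_program(
    patients: list[PatientProfile],
    seed: int,
    target: TargetDefinition | None = None,
    population: PopulationPkConfig | None = None,
    assay_cv: float = 0.10,
    rounding_increment_mg: float = 100.0,
    dose_bounds_mg: tuple[float, float] = (500.0, 6000.0),
    no_touch_in_band: bool = True,
    post48_samples: tuple[int, int] = (1, 3),
    per_patient_strategies: bool = False,
) -> SimulationResult:
    """Run the full dosing program on a cohort and assemble all analyses.

    Per patient: loading dose (bookkeeping only — it has washed out by the
    sampling times simulated here), empiric continuous infusion solved from
    the Dettli-predicted clearance, one steady-state sample in 24–48 h with
    proportional assay noise, a TDM adjustment, then 1–3 post-48 h samples
    under the adjusted dose.  Sampling noise uses an RNG stream derived from
    ``seed`` and independent of the cohort's.
    """
    target = target or TargetDefinition()
    population = population or PopulationPkConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7D0]))

    loading = loading_regimen()
    patient_rows = []
    meas_rows = []
    for p in patients:
        status = p.renal_status()
        cl_pred = predict_clearance(population, status)
        emp = empiric_daily_dose(target, cl_pred, rounding_increment_mg, dose_bounds_mg)

        css1 = emp.daily_dose_mg / (24.0 * p.true_clearance)
        t1 = float(rng.uniform(24.0, 48.0))
        c1 = css1 * max(1.0 + assay_cv * rng.standard_normal(), 0.05)
        rec1 = ConcentrationRecord(p.patient_id, t1, emp.daily_dose_mg, c1)
        adjusted = adjust_dose(
            emp, rec1, target, rounding_increment_mg, dose_bounds_mg, no_touch_in_band
        )
        css2 = adjusted.daily_dose_mg / (24.0 * p.true_clearance)

        meas_rows.append(
            dict(patient_id=p.patient_id, time_h=t1, daily_dose_mg=emp.daily_dose_mg,
                 conc_mg_L=c1, phase="first48", true_clearance=p.true_clearance,
                 cl_pred=cl_pred, crcl_ml_min=p.crcl, on_crrt=p.on_crrt)
        )
        n_post = int(rng.integers(post48_samples[0], post48_samples[1] + 1))
        for t in np.sort(rng.uniform(54.0, 168.0, n_post)):
            c = css2 * max(1.0 + assay_cv * rng.standard_normal(), 0.05)
            meas_rows.append(
                dict(patient_id=p.patient_id, time_h=float(t), daily_dose_mg=adjusted.daily_dose_mg,
                     conc_mg_L=c, phase="post48", true_clearance=p.true_clearance,
                     cl_pred=cl_pred, crcl_ml_min=p.crcl, on_crrt=p.on_crrt)
            )
        patient_rows.append(
            dict(patient_id=p.patient_id, crcl_ml_min=p.crcl, on_crrt=p.on_crrt,
                 cl_pred_L_h=cl_pred, true_clearance_L_h=p.true_clearance,
                 loading_dose_mg=loading.dose_mg, empiric_daily_mg=emp.daily_dose_mg,
                 first48_conc_mg_L=c1, adjusted_daily_mg=adjusted.daily_dose_mg,
                 css_post_adjust_mg_L=css2, died_in_hospital=p.died_in_hospital)
        )

    patients_df = pd.DataFrame(patient_rows)
    meas_df = pd.DataFrame(meas_rows)
    first48 = meas_df[meas_df["phase"] == "first48"]
    post48 = meas_df[meas_df["phase"] == "post48"]
    tally_first = tally_bands(first48["conc_mg_L"])
    tally_post = tally_bands(post48["conc_mg_L"])

    # strategy comparison at the dose-normalized observed clearance of every measurement
    cl_obs = meas_df["daily_dose_mg"] / 24.0 / meas_df["conc_mg_L"]
    strat_df = pd.DataFrame(
        dict(patient_id=meas_df["patient_id"], clearance_L_h=cl_obs,
             crcl_ml_min=meas_df["crcl_ml_min"], on_crrt=meas_df["on_crrt"])
    )
    strategy_tallies = compare_strategies(
        strat_df, volume=population.volume, target=target,
        rounding_increment_mg=rounding_increment_mg, dose_bounds_mg=dose_bounds_mg,
        per_patient=per_patient_strategies,
    )

    # Mortality by first-48h exposure band: harmful (>24) vs therapeutic (8-16).
    # A well-calibrated program rarely overshoots into the harmful band, so
    # when it is empty the comparison falls back to the moderately-high band
    # (16-24) vs therapeutic; the band actually used is recorded.
    from .exposure import classify_band

    by_band = patients_df.set_index("patient_id").loc[first48["patient_id"]].reset_index()
    by_band["band"] = first48["conc_mg_L"].map(classify_band).values
    grp_t = by_band[by_band["band"] == ExposureBand.therapeutic_8_16]
    table = mort_or = mort_chi2 = None
    mortality_band = None
    for high_band in (ExposureBand.harmful_above_24, ExposureBand.moderate_16_24):
        grp_h = by_band[by_band["band"] == high_band]
        if len(grp_h) > 0 and len(grp_t) > 0:
            table = ContingencyTable2x2(
                a=int(grp_h["died_in_hospital"].sum()), b=int((~grp_h["died_in_hospital"]).sum()),
                c=int(grp_t["died_in_hospital"].sum()), d=int((~grp_t["died_in_hospital"]).sum()),
            )
            mort_or = odds_ratio_woolf(table)
            mort_chi2 = chi_square(table.to_array())
            mortality_band = high_band
            break

    slope = float(np.polyfit(meas_df["true_clearance"], cl_obs, 1)[0])
    r = float(np.corrcoef(meas_df["cl_pred"], cl_obs)[0, 1])

    return SimulationResult(
        patients=patients_df, measurements=meas_df,
        tally_first48=tally_first, tally_post48=tally_post,
        strategy_tallies=strategy_tallies,
        mortality_table=table, mortality_or=mort_or, mortality_chi2=mort_chi2,
        mortality_band=mortality_band,
        recovery_slope=slope, pred_vs_obs_pearson_r=r,
    )
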