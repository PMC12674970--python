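"""Seeded synthetic ICU cohort with one-compartment vancomycin pharmacokinetics.

Every downstream stage (eligibility filtering, feature engineering, model
training, dose recommendation) is exercised on cohorts produced here, so no
real EHR extract is required. The simulator emulates the data substrate of a
vancomycin TDM study: covariate-driven drug clearance, intermittent IV
dosing, irregularly sampled labs and vitals with realistic missingness,
time-varying serum creatinine with AKI episodes, and noisy trough
measurements with patient-specific therapeutic ranges.

Ground truth is a one-compartment model with intermittent infusions. Each
encounter's clearance is held constant at the value implied by its
stay-averaged creatinine clearance ("quasi-static clearance"), so every
noise-free trough equals the closed-form superposition `concentration_at`
exactly — the test suite relies on this oracle equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PatientStatic",
    "PKParams",
    "ScrTrajectory",
    "TimedObservation",
    "DoseEvent",
    "TroughObservation",
    "TherapeuticRange",
    "Encounter",
    "CohortConfig",
    "cockcroft_gault",
    "concentration_at",
    "steady_state_trough",
    "classify_aki_stage",
    "generate_cohort",
    "COMORBIDITY_SCHEMA",
    "LAB_VARIABLES",
    "VITAL_VARIABLES",
]

COMORBIDITY_SCHEMA = (
    "ckd",
    "diabetes",
    "hypertension",
    "liver_disease",
    "sepsis",
    "anemia",
    "coronary_artery_disease",
)

# labs drawn every 6-24 h; vitals hourly with dropout
LAB_VARIABLES = ("scr", "bun", "wbc", "hemoglobin")
VITAL_VARIABLES = ("heart_rate", "sbp", "temperature", "resp_rate")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientStatic:
    """Time-invariant covariates of one ICU admission."""

    patient_id: str
    age: float  # years
    sex: str  # "male" | "female"
    weight: float  # kg
    height: float  # cm
    ethnicity: int  # categorical code
    comorbidities: tuple  # binary flags, schema COMORBIDITY_SCHEMA
    baseline_scr: float  # mg/dL

    def __post_init__(self):
        if self.age < 18:
            raise ValueError("age must be >= 18")
        if self.weight <= 0 or self.baseline_scr <= 0:
            raise ValueError("weight and baseline_scr must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class PKParams:
    """Population parameters of the one-compartment simulator.

    clearance (L/h) = clearance_intercept + clearance_slope * CrCl(L/h);
    Vd (L) = vd_per_kg * weight. Defaults reproduce the well-known
    correlation between vancomycin clearance and creatinine clearance with a
    standard adult distribution volume of 0.7 L/kg.
    """

    clearance_slope: float = 0.75
    clearance_intercept: float = 0.05  # L/h
    vd_per_kg: float = 0.7  # L/kg
    residual_sd: float = 1.0  # mg/L, trough measurement noise
    infusion_duration: float = 1.0  # h

    def __post_init__(self):
        if min(self.clearance_slope, self.clearance_intercept, self.vd_per_kg,
               self.infusion_duration) <= 0:
            raise ValueError("PK parameters must be strictly positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class ScrTrajectory:
    """Latent hourly serum creatinine (mg/dL) with AKI episode markers."""

    values: np.ndarray  # one value per hour of the stay
    aki_onset_hour: int | None = None
    aki_peak_ratio: float | None = None
    aki_resolution_hour: int | None = None

    def __post_init__(self):
        if np.any(self.values <= 0):
            raise ValueError("SCr must stay positive")
        if self.aki_peak_ratio is not None and self.aki_peak_ratio < 1:
            raise ValueError("peak ratio must be >= 1")


@dataclass(frozen=True)
class TimedObservation:
    variable_id: str
    t: float  # hours from ICU admission
    value: float

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("observation time must be >= 0")
        if not math.isfinite(self.value):
            raise ValueError("observation value must be finite")


@dataclass(frozen=True)
class DoseEvent:
    t_start: float  # hours
    amount: float  # mg
    infusion_duration: float  # h
    route: str = "IV intermittent"

    def __post_init__(self):
        if self.amount <= 0 or self.infusion_duration <= 0:
            raise ValueError("dose amount and infusion duration must be positive")


@dataclass(frozen=True)
class TherapeuticRange:
    lower: float  # mg/L
    upper: float  # mg/L

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("require 0 < lower < upper")


@dataclass(frozen=True)
class TroughObservation:
    t: float  # hours
    value: float  # mg/L
    range: TherapeuticRange
    pharmacist_prediction: float | None = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("trough value must be positive")


@dataclass
class Encounter:
    """One ICU admission with its observation, dose and trough streams."""

    static: PatientStatic
    observations: list  # of TimedObservation
    doses: list  # of DoseEvent, sorted by t_start
    troughs: list  # of TroughObservation
    krt_hours: set = field(default_factory=set)
    continuous_infusion_days: set = field(default_factory=set)
    icu_admit: float = 0.0
    icu_discharge: float = 0.0
    # synthetic ground truth (absent for real data, not serialized)
    true_clearance: float | None = None  # L/h
    true_vd: float | None = None  # L
    scr_trajectory: "ScrTrajectory | None" = None
    aki_stage: int | None = None

    def __post_init__(self):
        for d in self.doses:
            if not (self.icu_admit <= d.t_start <= self.icu_discharge):
                raise ValueError("dose outside the ICU stay")
        if any(self.doses[i].t_start > self.doses[i + 1].t_start
               for i in range(len(self.doses) - 1)):
            raise ValueError("doses must be sorted by time")


# ---------------------------------------------------------------------------
# Pharmacokinetic primitives
# ---------------------------------------------------------------------------

def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault formula."""
    if age <= 0 or weight <= 0 or scr <= 0:
        raise ValueError("age, weight and scr must be positive")
    crcl = ((140.0 - age) * weight) / (72.0 * scr)
    if sex == "female":
        crcl *= 0.85
    return crcl


def concentration_at(params: PKParams, clearance: float, vd: float,
                     doses: list, t: float) -> float:
    """Noise-free serum concentration (mg/L) at time `t` hours.

    Closed-form superposition of intermittent zero-order infusions into a
    one-compartment model with first-order elimination k = CL/V. During an
    infusion of rate R = D/T the contribution is (R/CL)(1 - e^{-k(t-ts)});
    after it ends, the end-of-infusion value decays mono-exponentially.
    """
    if vd <= 0:
        raise ValueError("volume of distribution must be positive")
    if clearance <= 0:
        raise ValueError("clearance must be positive")
    if t < 0:
        raise ValueError("time must be >= 0")
    k = clearance / vd
    conc = 0.0
    for dose in doses:
        dt = t - dose.t_start
        if dt <= 0:
            continue
        rate_over_cl = dose.amount / (dose.infusion_duration * clearance)
        if dt <= dose.infusion_duration:
            conc += rate_over_cl * (1.0 - math.exp(-k * dt))
        else:
            c_end = rate_over_cl * (1.0 - math.exp(-k * dose.infusion_duration))
            conc += c_end * math.exp(-k * (dt - dose.infusion_duration))
    return conc


def steady_state_trough(params: PKParams, clearance: float, vd: float,
                        dose: float, tau: float) -> float:
    """Steady-state trough (mg/L) for dose `dose` mg every `tau` h.

    Single-dose trough at t = tau scaled by the accumulation factor
    1 / (1 - e^{-k tau}).
    """
    if tau <= 0:
        raise ValueError("dosing interval must be positive")
    if tau <= params.infusion_duration:
        raise ValueError("dosing interval must exceed the infusion duration")
    single = concentration_at(
        params, clearance, vd,
        [DoseEvent(0.0, dose, params.infusion_duration)], tau)
    k = clearance / vd
    return single / (1.0 - math.exp(-k * tau))


def classify_aki_stage(peak_scr: float, baseline_scr: float) -> int:
    """KDIGO AKI stage from the ratio of peak to baseline serum creatinine."""
    if peak_scr <= 0 or baseline_scr <= 0:
        raise ValueError("SCr values must be positive")
    ratio = peak_scr / baseline_scr
    if ratio >= 3.0:
        return 3
    if ratio >= 2.0:
        return 2
    if ratio >= 1.5:
        return 1
    return 0


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Incidence rates follow the published ICU vancomycin TDM population
    (AKI stage I/II/III about 29/12/2.4%, median stay near 5 days, 63% male,
    median baseline SCr 0.63 mg/dL); exclusion-triggering features (KRT,
    continuous infusion, >14-day stays) are injected at configurable rates
    so the eligibility filter always has work to do.
    """

    n_encounters: int = 500
    pk: PKParams = field(default_factory=PKParams)
    aki_stage_probs: tuple = (0.29, 0.12, 0.024)  # stages 1, 2, 3
    frac_krt: float = 0.08
    frac_continuous_infusion: float = 0.05
    frac_long_stay: float = 0.10  # stays forced beyond 14 days
    p_range_10_15: float = 0.7  # remainder 15-20 mg/L
    trough_noise_sd: float | None = None  # None -> pk.residual_sd
    lab_interval_hours: tuple = (6.0, 24.0)
    vital_dropout: float = 0.2
    lab_noise_frac: float = 0.03
    pharmacist_clearance_bias: float = 0.9  # mis-specified stand-in benchmark
    with_pharmacist_predictions: bool = True
    dosing_interval: float = 12.0  # h
    median_stay_days: float = 4.9
    empiric_mg_per_kg: float = 15.0  # initial weight-based dose
    p_informed_dosing: float = 0.5  # fraction started on PK-informed doses
    titration_prob: float = 0.8  # chance an out-of-range trough is acted on
    titration_strength: float = 0.7  # partial correction exponent

    def __post_init__(self):
        self.aki_stage_probs = tuple(self.aki_stage_probs)
        self.lab_interval_hours = tuple(self.lab_interval_hours)
        rates = (self.frac_krt, self.frac_continuous_infusion,
                 self.frac_long_stay, self.vital_dropout,
                 *self.aki_stage_probs)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_encounters < 0:
            raise ValueError("n_encounters must be >= 0")
        if self.trough_noise_sd is not None and self.trough_noise_sd < 0:
            raise ValueError("trough_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pk"] = asdict(self.pk)
        return d


def _round_to_250(x: float) -> float:
    return max(250.0, 250.0 * round(x / 250.0))


def _make_scr_trajectory(rng: np.random.Generator, baseline: float,
                         n_hours: int, stage: int) -> ScrTrajectory:
    """Piecewise log-linear SCr around an optional AKI episode."""
    values = np.full(n_hours, baseline, dtype=float)
    if stage == 0 or n_hours < 72:
        return ScrTrajectory(values)
    lo, hi = {1: (1.55, 1.95), 2: (2.05, 2.9), 3: (3.05, 3.9)}[stage]
    peak_ratio = float(rng.uniform(lo, hi))
    rise = int(rng.integers(24, 49))
    plateau = int(rng.integers(12, 25))
    fall = int(rng.integers(48, 97))
    onset = int(rng.integers(6, max(7, min(n_hours // 2, n_hours - rise - 2))))
    peak = baseline * peak_ratio
    t = onset
    for h in range(min(rise, n_hours - t)):
        values[t + h] = baseline * math.exp(math.log(peak_ratio) * (h + 1) / rise)
    t = min(onset + rise, n_hours)
    t_plateau_end = min(t + plateau, n_hours)
    values[t:t_plateau_end] = peak
    for h in range(t_plateau_end, n_hours):
        frac = (h - t_plateau_end + 1) / fall
        values[h] = peak * math.exp(-math.log(peak_ratio) * min(frac, 1.0))
    resolution = min(t_plateau_end + fall, n_hours - 1)
    return ScrTrajectory(values, aki_onset_hour=onset,
                         aki_peak_ratio=peak_ratio,
                         aki_resolution_hour=resolution)


_VITAL_BASE = {"heart_rate": (85.0, 12.0), "sbp": (118.0, 15.0),
               "temperature": (37.0, 0.5), "resp_rate": (18.0, 3.0)}
_LAB_BASE = {"bun": (22.0, 8.0), "wbc": (11.0, 3.5), "hemoglobin": (10.5, 1.5)}


def _simulate_encounter(rng: np.random.Generator, cfg: CohortConfig,
                        idx: int) -> Encounter:
    pid = f"enc{idx:05d}"
    sex = "male" if rng.random() < 0.633 else "female"
    age = float(rng.uniform(18.0, 92.0))
    weight = float(np.clip(rng.lognormal(math.log(80.0), 0.28), 40.0, 180.0))
    height = float(np.clip(rng.normal(170.0 if sex == "male" else 160.0, 8.0),
                           140.0, 205.0))
    ethnicity = int(rng.choice(4, p=[0.52, 0.07, 0.06, 0.35]))
    comorbidity_p = (0.03, 0.11, 0.15, 0.005, 0.17, 0.07, 0.07)
    comorbidities = tuple(int(rng.random() < p) for p in comorbidity_p)
    baseline_scr = float(np.clip(rng.lognormal(math.log(0.7), 0.5), 0.25, 5.0))
    static = PatientStatic(pid, age, sex, weight, height, ethnicity,
                           comorbidities, baseline_scr)

    if rng.random() < cfg.frac_long_stay:
        stay_days = float(rng.uniform(15.0, 20.0))
    else:
        stay_days = float(np.clip(rng.lognormal(math.log(cfg.median_stay_days), 0.6),
                                  0.7, 14.0))
    n_hours = max(12, int(round(stay_days * 24)))

    stage = int(rng.choice([0, 1, 2, 3],
                           p=[1.0 - sum(cfg.aki_stage_probs), *cfg.aki_stage_probs]))
    scr_traj = _make_scr_trajectory(rng, baseline_scr, n_hours, stage)
    if scr_traj.aki_peak_ratio is None:
        stage = 0  # stay too short to fit an episode

    # quasi-static clearance from the stay-averaged creatinine clearance
    mean_scr = float(np.mean(scr_traj.values))
    crcl_lh = cockcroft_gault(age, weight, mean_scr, sex) * 0.06  # mL/min -> L/h
    cl_true = cfg.pk.clearance_intercept + cfg.pk.clearance_slope * crcl_lh
    vd = cfg.pk.vd_per_kg * weight

    # dosing policy: q12h 1-h infusions sized from a noisy clearance estimate,
    # titrated after each measured trough
    tau = cfg.dosing_interval
    first_dose_t = float(rng.uniform(6.0, 24.0))
    range_ = (TherapeuticRange(10.0, 15.0) if rng.random() < cfg.p_range_10_15
              else TherapeuticRange(15.0, 20.0))
    target_mid = 0.5 * (range_.lower + range_.upper)
    if rng.random() < cfg.p_informed_dosing:
        # PK-informed start from a slightly biased clearance estimate
        cl_est = (cfg.pk.clearance_intercept
                  + cfg.pharmacist_clearance_bias * cfg.pk.clearance_slope
                  * crcl_lh) * float(rng.lognormal(0.0, 0.1))
        per_1000 = steady_state_trough(cfg.pk, cl_est, vd, 1000.0, tau)
        dose_amt = float(np.clip(
            _round_to_250(1000.0 * target_mid / max(per_1000, 1e-6)),
            250.0, 3000.0))
    else:
        # empiric weight-based start (~15 mg/kg q12h)
        dose_amt = float(np.clip(_round_to_250(cfg.empiric_mg_per_kg * weight),
                                 500.0, 2250.0))

    noise_sd = (cfg.pk.residual_sd if cfg.trough_noise_sd is None
                else cfg.trough_noise_sd)

    doses: list[DoseEvent] = []
    troughs: list[TroughObservation] = []
    t_dose = first_dose_t
    dose_idx = 0
    while t_dose <= n_hours - cfg.pk.infusion_duration:
        # troughs drawn 0-60 min before every 4th scheduled dose (~ every 2 d)
        if dose_idx >= 4 and dose_idx % 4 == 0:
            t_trough = t_dose - float(rng.uniform(0.0, 1.0))
            true_conc = concentration_at(cfg.pk, cl_true, vd, doses, t_trough)
            value = true_conc + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else true_conc
            value = max(value, 0.05)
            pharm = None
            if cfg.with_pharmacist_predictions:
                cl_pharm = (cfg.pk.clearance_intercept
                            + cfg.pharmacist_clearance_bias
                            * cfg.pk.clearance_slope * crcl_lh)
                pharm = concentration_at(cfg.pk, cl_pharm, vd, doses, t_trough)
            troughs.append(TroughObservation(t_trough, value, range_, pharm))
            # sluggish partial titration: adjust only when the measured
            # trough sits outside the range, and correct part-way
            if (value > 0.5 and rng.random() < cfg.titration_prob
                    and not range_.lower <= value <= range_.upper):
                factor = (target_mid / value) ** cfg.titration_strength
                dose_amt = float(np.clip(
                    _round_to_250(dose_amt * factor), 250.0, 3000.0))
        doses.append(DoseEvent(float(t_dose), dose_amt, cfg.pk.infusion_duration))
        t_dose += tau
        dose_idx += 1

    # observation streams
    observations: list[TimedObservation] = []
    for var in LAB_VARIABLES:
        t = float(rng.uniform(0.0, 6.0))
        while t < n_hours:
            if var == "scr":
                latent = float(scr_traj.values[min(int(t), n_hours - 1)])
            else:
                mu, sd = _LAB_BASE[var]
                latent = float(np.clip(rng.normal(mu, sd), 0.1, None))
            value = latent * float(1.0 + rng.normal(0.0, cfg.lab_noise_frac))
            observations.append(TimedObservation(var, t, max(value, 0.01)))
            t += float(rng.uniform(*cfg.lab_interval_hours))
    for var in VITAL_VARIABLES:
        mu, sd = _VITAL_BASE[var]
        level = float(rng.normal(mu, sd))
        for h in range(n_hours):
            if rng.random() < cfg.vital_dropout:
                continue
            value = level + float(rng.normal(0.0, sd * 0.3))
            observations.append(TimedObservation(var, h + float(rng.uniform(0, 1)),
                                                 max(value, 0.01)))

    krt_hours: set[int] = set()
    if rng.random() < cfg.frac_krt:
        start = int(rng.integers(0, max(1, n_hours - 24)))
        krt_hours = set(range(start, min(n_hours, start + int(rng.integers(24, 72)))))
    ci_days: set[int] = set()
    if rng.random() < cfg.frac_continuous_infusion:
        d0 = int(rng.integers(0, max(1, n_hours // 24)))
        ci_days = {d0, d0 + 1} if rng.random() < 0.5 else {d0}

    return Encounter(static=static, observations=observations, doses=doses,
                     troughs=troughs, krt_hours=krt_hours,
                     continuous_infusion_days=ci_days,
                     icu_admit=0.0, icu_discharge=float(n_hours),
                     true_clearance=cl_true, true_vd=vd,
                     scr_trajectory=scr_traj, aki_stage=stage)


def generate_cohort(config: CohortConfig, seed: int) -> list:
    """Generate a deterministic synthetic cohort of ICU encounters."""
    rng = np.random.default_rng(seed)
    return [_simulate_encounter(rng, config, i) for i in range(config.n_encounters)]
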