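"""Eligibility filtering: encounters -> one prediction instance per patient-day.

A patient-day is eligible for trough forecasting when the patient is an
adult with at least 24 h in the ICU, the day falls within the first 14 days
of the stay, the patient received no continuous vancomycin infusion that day
and no kidney replacement therapy that day or in the preceding 7 days, at
least one intermittent IV dose was given that day, and a trough level was
measured about 2 days later. Exclusions operate on patient-days, not whole
encounters, so one encounter can contribute several instances.

Days are whole 24 h blocks from ICU admission (day d covers hours
[24d, 24(d+1))); the prediction is made at the end of the day. The "2 days
later" trough is matched in a configurable 36-60 h window after the
prediction time to avoid brittle exact-hour joins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .synthetic_cohort import Encounter, TherapeuticRange

__all__ = ["PredictionInstance", "EligibilityRules", "select_eligible",
           "split_train_test"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionInstance:
    """One eligible patient-day with its target trough two days later."""

    patient_id: str
    prediction_day: int  # day index from ICU admission (0-based)
    prediction_time: float  # hours; end of the prediction day
    target_trough: float  # mg/L, measured
    target_time: float  # hours
    range: TherapeuticRange
    pharmacist_prediction: float | None = None
    encounter: Encounter | None = field(default=None, repr=False, compare=False)


@dataclass
class EligibilityRules:
    """Thresholds of the patient-day eligibility filter.

    Set a rule's field to None (or False for the flags) to disable it; the
    instance count is monotone non-increasing as rules are switched on.
    """

    min_age: float | None = 18.0
    min_icu_hours: float | None = 24.0
    max_prediction_day: int | None = 14  # prediction day must be < this
    exclude_continuous_infusion: bool = True
    exclude_krt: bool = True
    krt_lookback_days: int = 7
    target_window_hours: tuple = (36.0, 60.0)  # nominal 48 h after prediction
    require_dose_on_day: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _day_has_krt(enc: Encounter, day: int, lookback_days: int) -> bool:
    lo = 24.0 * (day - lookback_days)
    hi = 24.0 * (day + 1)
    return any(lo <= h < hi for h in enc.krt_hours)


def select_eligible(encounters: list, rules: EligibilityRules | None = None) -> list:
    """Apply the eligibility rules; returns one instance per retained day."""
    rules = rules or EligibilityRules()
    w_lo, w_hi = rules.target_window_hours
    instances: list[PredictionInstance] = []
    for enc in encounters:
        try:
            age = enc.static.age
            stay = enc.icu_discharge - enc.icu_admit
        except AttributeError:
            log.warning("skipping malformed encounter record: %r", enc)
            continue
        if rules.min_age is not None and age < rules.min_age:
            continue
        if rules.min_icu_hours is not None and stay < rules.min_icu_hours:
            continue
        n_days = int(np.ceil(stay / 24.0))
        for day in range(n_days):
            if (rules.max_prediction_day is not None
                    and day >= rules.max_prediction_day):
                continue
            if (rules.exclude_continuous_infusion
                    and day in enc.continuous_infusion_days):
                continue
            if rules.exclude_krt and _day_has_krt(enc, day, rules.krt_lookback_days):
                continue
            day_lo, day_hi = 24.0 * day, 24.0 * (day + 1)
            if rules.require_dose_on_day and not any(
                    day_lo <= d.t_start < day_hi for d in enc.doses):
                continue
            prediction_time = day_hi
            in_window = [tr for tr in enc.troughs
                         if prediction_time + w_lo <= tr.t <= prediction_time + w_hi]
            if not in_window:
                continue
            target = min(in_window, key=lambda tr: tr.t)
            instances.append(PredictionInstance(
                patient_id=enc.static.patient_id,
                prediction_day=day,
                prediction_time=prediction_time,
                target_trough=target.value,
                target_time=target.t,
                range=target.range,
                pharmacist_prediction=target.pharmacist_prediction,
                encounter=enc,
            ))
    return instances


def split_train_test(instances: list, fraction: float = 0.8,
                     seed: int = 0) -> tuple:
    """Encounter-level train/test split (no patient appears on both sides)."""
    if not instances:
        raise ValueError("no instances to split")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    patient_ids = sorted({inst.patient_id for inst in instances})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patient_ids))
    n_train = int(round(fraction * len(patient_ids)))
    train_ids = {patient_ids[i] for i in order[:n_train]}
    train = [inst for inst in instances if inst.patient_id in train_ids]
    test = [inst for inst in instances if inst.patient_id not in train_ids]
    return train, test
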