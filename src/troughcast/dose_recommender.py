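"""Line-search dose recommendation and the distance-vs-reward analysis.

Starting from the dose actually given between prediction time and trough
collection, candidate adjustments of +/-250 mg up to +/-1500 mg (never below
zero total dose) are each re-scored by re-predicting the trough with the
candidate dose substituted into the dose shortcut features. The candidate
maximizing a proximity reward — 0 inside the patient's therapeutic range,
minus the distance in mg/L to the nearest bound outside it — is returned;
ties prefer the predicted trough closest to the range midpoint, then the
smallest dose change. The search is exhaustive over the 250 mg grid, so the
result is independent of evaluation order.

The reward-curve analysis bins the distance between the administered and
recommended dose at 250 mg resolution and averages the reward of the
*measured* trough per bin, reproducing the qualitative check that doses
closer to the recommendation land closer to the therapeutic range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .feature_pipeline import SequenceSample, SKIP_FEATURES
from .synthetic_cohort import TherapeuticRange

__all__ = ["DoseRecommendation", "RewardCurve", "reward", "recommend",
           "reward_curve", "DELTA_GRID", "STEP_MG", "MAX_DELTA_MG"]

STEP_MG = 250.0
MAX_DELTA_MG = 1500.0
DELTA_GRID = tuple(np.arange(-MAX_DELTA_MG, MAX_DELTA_MG + STEP_MG, STEP_MG))
_INTERVAL_IDX = SKIP_FEATURES.index("interval_dose_mg")
_DAY_IDX = SKIP_FEATURES.index("day_dose_mg")


@dataclass(frozen=True)
class DoseRecommendation:
    base_dose: float  # mg actually given over the interval
    recommended_dose: float  # mg
    delta: float  # mg, recommended - base; multiple of 250
    predicted_trough: float  # mg/L at the recommended dose
    reward: float
    search_trace: tuple  # of (candidate dose, predicted trough, reward)

    def __post_init__(self):
        assert abs(self.delta) <= MAX_DELTA_MG + 1e-9
        assert self.recommended_dose >= 0
        assert abs(self.delta % STEP_MG) < 1e-6 or abs(self.delta % STEP_MG - STEP_MG) < 1e-6


@dataclass(frozen=True)
class RewardCurve:
    """Mean reward (with standard error) per 250 mg distance bin."""

    distances: np.ndarray  # bin centers, mg (actual - recommended)
    mean_reward: np.ndarray
    se_reward: np.ndarray
    n: np.ndarray


def reward(trough: float, range_: TherapeuticRange) -> float:
    """0 inside the range; minus the mg/L distance to the nearest bound outside."""
    if trough < range_.lower:
        return trough - range_.lower
    if trough > range_.upper:
        return range_.upper - trough
    return 0.0


def _candidate_sample(sample: SequenceSample, candidate_dose: float,
                      scale_day_dose: bool = False) -> SequenceSample:
    skip = sample.skip_features.copy()
    base = skip[_INTERVAL_IDX]
    skip[_INTERVAL_IDX] = candidate_dose
    if scale_day_dose and base > 0:
        skip[_DAY_IDX] *= candidate_dose / base
    return replace(sample, skip_features=skip)


def recommend(predict_fn, sample: SequenceSample,
              range_: TherapeuticRange | None = None,
              reward_fn=reward, scale_day_dose: bool = False) -> DoseRecommendation:
    """Exhaustive 250 mg line search over interval-dose adjustments.

    `predict_fn` maps a list of SequenceSample to predicted troughs (mg/L);
    pass `model.predict` for a trained model. The dose edit is applied to
    the interval-dose skip feature (optionally rescaling the prediction-day
    dose with it).
    """
    range_ = range_ or sample.range
    base = float(sample.skip_features[_INTERVAL_IDX])
    candidates = [base + d for d in DELTA_GRID if base + d >= 0.0]
    preds = np.asarray(predict_fn(
        [_candidate_sample(sample, c, scale_day_dose) for c in candidates]),
        dtype=float)
    rewards = np.array([reward_fn(p, range_) for p in preds])
    mid = 0.5 * (range_.lower + range_.upper)
    # maximize reward; break ties toward mid-range trough, then small |delta|
    keys = [(-rewards[i], abs(preds[i] - mid), abs(candidates[i] - base))
            for i in range(len(candidates))]
    best = min(range(len(candidates)), key=lambda i: keys[i])
    trace = tuple((float(candidates[i]), float(preds[i]), float(rewards[i]))
                  for i in range(len(candidates)))
    return DoseRecommendation(
        base_dose=base, recommended_dose=float(candidates[best]),
        delta=float(candidates[best] - base),
        predicted_trough=float(preds[best]), reward=float(rewards[best]),
        search_trace=trace)


def reward_curve(samples: list, predict_fn, reward_fn=reward,
                 use_measured: bool = True,
                 scale_day_dose: bool = False) -> RewardCurve:
    """Distance between actual and recommended dose vs mean reward.

    Per instance: distance = administered interval dose - recommended dose,
    binned at 250 mg; reward is computed on the measured trough against the
    instance's own range (set `use_measured=False` to score the model's
    base-dose prediction instead). Empty bins are omitted.
    """
    bins: dict[float, list] = {}
    base_preds = np.asarray(predict_fn(samples), dtype=float)
    for sample, base_pred in zip(samples, base_preds):
        rec = recommend(predict_fn, sample, reward_fn=reward_fn,
                        scale_day_dose=scale_day_dose)
        distance = STEP_MG * round((rec.base_dose - rec.recommended_dose) / STEP_MG)
        trough = sample.target if use_measured else float(base_pred)
        bins.setdefault(distance, []).append(reward_fn(trough, sample.range))
    distances = np.array(sorted(bins))
    means = np.array([np.mean(bins[d]) for d in distances])
    ses = np.array([
        (np.std(bins[d], ddof=1) / np.sqrt(len(bins[d]))
         if len(bins[d]) > 1 else 0.0) for d in distances])
    ns = np.array([len(bins[d]) for d in distances])
    return RewardCurve(distances, means, ses, ns)
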