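"""Performance statistics for trough predictions.

Regression error (MAE / RMSE / MAPE), therapeutic-category concordance as a
3x3 confusion matrix with overall accuracy, Bland-Altman agreement, and the
paired comparisons against a benchmark predictor (paired t-test on absolute
errors; McNemar's test on category correctness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .synthetic_cohort import TherapeuticRange

__all__ = ["MetricsReport", "ConfusionMatrix3", "BlandAltmanResult",
           "PairedComparison", "CATEGORIES", "regression_metrics",
           "classify_trough", "confusion_accuracy", "bland_altman",
           "paired_tests"]

CATEGORIES = ("subtherapeutic", "therapeutic", "supratherapeutic")


@dataclass(frozen=True)
class MetricsReport:
    mae: float  # mg/L
    rmse: float  # mg/L
    mape: float  # percent, 0-100 scale
    n: int

    def __post_init__(self):
        assert self.rmse >= self.mae >= 0 and self.n >= 1


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts: predicted category (rows) x measured category (columns)."""

    counts: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def measured_marginals(self) -> tuple:
        return tuple(int(c) for c in self.counts.sum(axis=0))

    @property
    def predicted_marginals(self) -> tuple:
        return tuple(int(c) for c in self.counts.sum(axis=1))


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float  # predicted - measured, mg/L
    sd_diff: float
    loa_lower: float  # mean - 1.96 sd
    loa_upper: float  # mean + 1.96 sd
    n: int


@dataclass(frozen=True)
class PairedComparison:
    mean_error_diff: float  # model - benchmark, mg/L absolute error
    t_statistic: float | None
    t_pvalue: float | None
    mcnemar_b: int  # model correct, benchmark wrong
    mcnemar_c: int  # model wrong, benchmark correct
    mcnemar_statistic: float | None
    mcnemar_pvalue: float
    exact: bool
    n: int


def regression_metrics(pred, obs, mape_floor: float = 0.5) -> MetricsReport:
    """MAE, RMSE and MAPE (percent) of predictions vs observations.

    Pairs whose observed value is below `mape_floor` mg/L are excluded from
    MAPE (with a warning) to avoid ratio blow-up near zero.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be non-empty and aligned")
    err = pred - obs
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    ok = obs >= mape_floor
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} pair(s) below {mape_floor} mg/L "
                      "excluded from MAPE", stacklevel=2)
    if not ok.any():
        raise ValueError("no valid pairs for MAPE")
    mape = float(100.0 * (np.abs(err[ok]) / obs[ok]).mean())
    return MetricsReport(mae=mae, rmse=rmse, mape=mape, n=int(pred.size))


def classify_trough(value: float, range_: TherapeuticRange) -> str:
    """Therapeutic category of a trough; range bounds are inclusive."""
    if value < range_.lower:
        return "subtherapeutic"
    if value > range_.upper:
        return "supratherapeutic"
    return "therapeutic"


def confusion_accuracy(pred, obs, ranges) -> ConfusionMatrix3:
    """Tally predicted vs measured categories, each pair on its own range."""
    if not (len(pred) == len(obs) == len(ranges)):
        raise ValueError("pred, obs and ranges must be aligned")
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    counts = np.zeros((3, 3), dtype=int)
    for p, o, r in zip(pred, obs, ranges):
        counts[idx[classify_trough(p, r)], idx[classify_trough(o, r)]] += 1
    return ConfusionMatrix3(counts)


def bland_altman(pred, obs) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need at least two aligned pairs")
    d = pred - obs
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd,
                             int(d.size))


def paired_tests(err_model, err_bench, correct_model, correct_bench,
                 exact_threshold: int = 25) -> PairedComparison:
    """Paired t-test on absolute errors; McNemar's test on correctness.

    McNemar uses the continuity-corrected chi-square statistic
    (|b - c| - 1)^2 / (b + c), falling back to the exact binomial test when
    the discordant count b + c is below `exact_threshold`.
    """
    err_model = np.asarray(err_model, dtype=float)
    err_bench = np.asarray(err_bench, dtype=float)
    cm = np.asarray(correct_model, dtype=bool)
    cb = np.asarray(correct_bench, dtype=bool)
    n = err_model.size
    if not (err_bench.size == cm.size == cb.size == n) or n < 2:
        raise ValueError("inputs must be aligned with n >= 2")
    diff = err_model - err_bench
    if np.allclose(diff.std(ddof=1), 0.0):
        t_stat, t_p = None, None  # zero variance: t undefined
    else:
        t = sps.ttest_rel(err_model, err_bench)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    b = int(np.sum(cm & ~cb))
    c = int(np.sum(~cm & cb))
    table = [[int(np.sum(cm & cb)), b], [c, int(np.sum(~cm & ~cb))]]
    if b + c == 0:
        return PairedComparison(float(diff.mean()), t_stat, t_p, b, c,
                                None, 1.0, True, n)
    use_exact = (b + c) < exact_threshold
    res = _sm_mcnemar(table, exact=use_exact, correction=True)
    statistic = None if use_exact else float(res.statistic)
    return PairedComparison(float(diff.mean()), t_stat, t_p, b, c,
                            statistic, float(res.pvalue), use_exact, n)
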