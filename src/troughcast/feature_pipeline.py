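"""Feature engineering: eligible patient-day -> fixed-shape model inputs.

Observation streams are binned to an hourly grid (median per bin), carried
forward for up to 24 h, and mean-imputed from training-set statistics. Each
time-varying variable contributes its hourly value plus the slope and mean
over the previous 72 h; static covariates are broadcast across the 24 time
steps. The dose shortcut ("skip") vector collects the dosing information the
network feeds directly to its output layer: prediction-day total dose, the
total dose given between prediction time and trough collection, time since
the last dose, and the most recent prior measured trough (train-mean filled,
with a presence flag, when none exists).

Sequences are z-scored per continuous feature with training-set statistics;
categorical flags stay 0/1. Skip features are kept in raw clinical units
(mg, h, mg/L) — the model normalizes them internally — so that downstream
dose counterfactuals can edit them directly in milligrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_builder import PredictionInstance
from .synthetic_cohort import (COMORBIDITY_SCHEMA, LAB_VARIABLES,
                               VITAL_VARIABLES, Encounter, TherapeuticRange)

__all__ = ["HourlyGrid", "NormalizationStats", "FeatureSchema",
           "SequenceSample", "bin_hourly", "impute", "trend_features",
           "assemble", "FeaturePipeline", "SEQ_HOURS", "DOSE_CHANNEL",
           "SKIP_FEATURES"]

SEQ_HOURS = 24
DOSE_CHANNEL = "vanco_dose_mg"  # hourly administered dose, event channel
SKIP_FEATURES = ("day_dose_mg", "interval_dose_mg", "hours_since_last_dose",
                 "prior_trough_mg_per_L", "prior_trough_present")
_EPS = 1e-6

N_ETHNICITY = 4


@dataclass
class HourlyGrid:
    """Hour x variable matrix with a parallel missingness mask (hour 0 = admit)."""

    variables: tuple
    values: np.ndarray  # (H, V)
    mask: np.ndarray  # (H, V) bool, True where observed


@dataclass
class FeatureSchema:
    """Names and kinds of every sequence and skip feature column."""

    sequence_features: tuple
    skip_features: tuple = SKIP_FEATURES
    categorical: frozenset = frozenset()

    @property
    def n_seq(self) -> int:
        return len(self.sequence_features)

    def to_dict(self) -> dict:
        return {"sequence_features": list(self.sequence_features),
                "skip_features": list(self.skip_features),
                "categorical": sorted(self.categorical)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(tuple(d["sequence_features"]), tuple(d["skip_features"]),
                   frozenset(d["categorical"]))


@dataclass
class NormalizationStats:
    """Training-set statistics; never computed from test instances."""

    variable_means: dict  # raw-scale mean per time-varying variable
    seq_mean: np.ndarray  # per sequence feature
    seq_sd: np.ndarray  # floored at eps; 1.0 for categorical features
    skip_mean: np.ndarray
    skip_sd: np.ndarray

    def to_dict(self) -> dict:
        return {"variable_means": self.variable_means,
                "seq_mean": self.seq_mean.tolist(),
                "seq_sd": self.seq_sd.tolist(),
                "skip_mean": self.skip_mean.tolist(),
                "skip_sd": self.skip_sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(dict(d["variable_means"]),
                   np.asarray(d["seq_mean"]), np.asarray(d["seq_sd"]),
                   np.asarray(d["skip_mean"]), np.asarray(d["skip_sd"]))


@dataclass
class SequenceSample:
    """Fixed-shape input of one prediction instance."""

    patient_id: str
    sequence: np.ndarray  # (24, F), normalized
    skip_features: np.ndarray  # raw units, order SKIP_FEATURES
    target: float  # mg/L
    range: TherapeuticRange
    prediction_time: float = 0.0
    target_time: float = 0.0
    pharmacist_prediction: float | None = None


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def bin_hourly(observations: list, n_hours: int,
               variables: tuple | None = None) -> HourlyGrid:
    """Median-per-hour binning of raw timed observations."""
    if variables is None:
        variables = tuple(sorted({o.variable_id for o in observations}))
    var_index = {v: j for j, v in enumerate(variables)}
    buckets: dict[tuple, list] = {}
    for obs in observations:
        if obs.t < 0:
            raise ValueError(f"negative timestamp on {obs.variable_id}")
        if obs.variable_id not in var_index:
            continue
        h = int(obs.t)
        if h >= n_hours:
            continue
        buckets.setdefault((h, var_index[obs.variable_id]), []).append(obs.value)
    values = np.zeros((n_hours, len(variables)))
    mask = np.zeros((n_hours, len(variables)), dtype=bool)
    for (h, j), vals in buckets.items():
        values[h, j] = float(np.median(vals))
        mask[h, j] = True
    return HourlyGrid(variables, values, mask)


def impute(grid: HourlyGrid, stats: "NormalizationStats",
           max_carry_hours: int = 24) -> HourlyGrid:
    """Carry observed values forward up to 24 h, then fill with train means.

    Fills are always derived from observed cells, so the operation is
    idempotent; the original mask is kept for audit.
    """
    values = grid.values.copy()
    for j, var in enumerate(grid.variables):
        col_mask = grid.mask[:, j]
        if var not in stats.variable_means:
            raise KeyError(f"no training mean for variable {var!r}")
        fallback = stats.variable_means[var]
        last_value, last_hour = None, None
        for h in range(len(values)):
            if col_mask[h]:
                last_value, last_hour = grid.values[h, j], h
            elif last_value is not None and h - last_hour <= max_carry_hours:
                values[h, j] = last_value
            else:
                values[h, j] = fallback
    return HourlyGrid(grid.variables, values, grid.mask.copy())


def trend_features(grid: HourlyGrid, hour: int, window: int = 72) -> dict:
    """Per-variable (OLS slope in units/h, mean) over the previous `window` h.

    Uses the hours [hour - window, hour) of an imputed grid; with less
    history the available prefix is used, and fewer than two points yields a
    slope of zero by convention.
    """
    lo = max(0, hour - window)
    rows = grid.values[lo:hour]
    out: dict[str, tuple] = {}
    t = np.arange(rows.shape[0], dtype=float)
    for j, var in enumerate(grid.variables):
        y = rows[:, j]
        mean = float(y.mean()) if len(y) else 0.0
        if len(y) >= 2:
            slope = float(np.polyfit(t, y, 1)[0])
        else:
            slope = 0.0
        out[var] = (slope, mean)
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _static_features(enc: Encounter) -> tuple:
    s = enc.static
    names, vals, cat = [], [], []
    names.append("age"); vals.append(s.age); cat.append(False)
    names.append("sex_female"); vals.append(1.0 if s.sex == "female" else 0.0); cat.append(True)
    names.append("weight"); vals.append(s.weight); cat.append(False)
    names.append("height"); vals.append(s.height); cat.append(False)
    for e in range(N_ETHNICITY):
        names.append(f"ethnicity_{e}")
        vals.append(1.0 if s.ethnicity == e else 0.0)
        cat.append(True)
    for name, flag in zip(COMORBIDITY_SCHEMA, s.comorbidities):
        names.append(f"comorbidity_{name}")
        # missing categorical covariates are imputed as not present
        vals.append(float(flag) if flag is not None else 0.0)
        cat.append(True)
    return tuple(names), np.array(vals, dtype=float), tuple(cat)


def _dose_channel(enc: Encounter, n_hours: int) -> np.ndarray:
    col = np.zeros(n_hours)
    for d in enc.doses:
        h = int(d.t_start)
        if 0 <= h < n_hours:
            col[h] += d.amount
    return col


def _raw_skip(instance: PredictionInstance, prior_trough_fill: float) -> np.ndarray:
    enc = instance.encounter
    pt, tt = instance.prediction_time, instance.target_time
    day_dose = sum(d.amount for d in enc.doses if pt - 24.0 <= d.t_start < pt)
    interval_dose = sum(d.amount for d in enc.doses if pt < d.t_start <= tt)
    before = [d.t_start for d in enc.doses if d.t_start < pt]
    since_last = pt - max(before) if before else 24.0
    prior = [tr for tr in enc.troughs if tr.t < pt]
    if prior:
        prior_val, present = max(prior, key=lambda tr: tr.t).value, 1.0
    else:
        prior_val, present = prior_trough_fill, 0.0
    return np.array([day_dose, interval_dose, since_last, prior_val, present])


def _crcl_column(enc: Encounter, scr: np.ndarray) -> np.ndarray:
    """Hourly Cockcroft-Gault creatinine clearance from imputed SCr."""
    s = enc.static
    factor = 0.85 if s.sex == "female" else 1.0
    return factor * ((140.0 - s.age) * s.weight) / (72.0 * np.maximum(scr, 0.1))


def _raw_sequence(instance: PredictionInstance, imputed: HourlyGrid,
                  dose_col: np.ndarray, skip_raw: np.ndarray,
                  window: int = 72) -> tuple:
    """Unnormalized (24, F) matrix and its column names/kinds.

    The vancomycin-specific features (interval dose, time since last dose,
    prior trough) are broadcast into the sequence as well as carried in the
    skip vector: the recurrent/attention path can then form nonlinear
    interactions with kidney function while the shortcut keeps them
    undiluted at the output layer.
    """
    enc = instance.encounter
    hi = int(instance.prediction_time)
    lo = hi - SEQ_HOURS
    day_rows = imputed.values[lo:hi]
    dose_rows = dose_col[lo:hi]
    trends = trend_features(imputed, hi, window)
    names: list[str] = []
    cols: list[np.ndarray] = []
    cat: list[bool] = []
    for j, var in enumerate(imputed.variables):
        names.append(var); cols.append(day_rows[:, j]); cat.append(False)
    names.append(DOSE_CHANNEL); cols.append(dose_rows); cat.append(False)
    if "scr" in imputed.variables:
        j_scr = imputed.variables.index("scr")
        crcl = _crcl_column(enc, imputed.values[:, j_scr])
        names.append("crcl"); cols.append(crcl[lo:hi]); cat.append(False)
        t72 = crcl[max(0, hi - window):hi]
        slope = float(np.polyfit(np.arange(len(t72), dtype=float), t72, 1)[0]) \
            if len(t72) >= 2 else 0.0
        names.append("crcl_slope_72h"); cols.append(np.full(SEQ_HOURS, slope)); cat.append(False)
        names.append("crcl_mean_72h"); cols.append(np.full(SEQ_HOURS, float(t72.mean()) if len(t72) else 0.0)); cat.append(False)
    for var in imputed.variables:
        slope, mean = trends[var]
        names.append(f"{var}_slope_72h"); cols.append(np.full(SEQ_HOURS, slope)); cat.append(False)
        names.append(f"{var}_mean_72h"); cols.append(np.full(SEQ_HOURS, mean)); cat.append(False)
    snames, svals, scat = _static_features(enc)
    for name, v, c in zip(snames, svals, scat):
        names.append(name); cols.append(np.full(SEQ_HOURS, v)); cat.append(c)
    for j, sk_name in enumerate(SKIP_FEATURES):
        names.append(f"seq_{sk_name}")
        cols.append(np.full(SEQ_HOURS, skip_raw[j]))
        cat.append(sk_name == "prior_trough_present")
    seq = np.column_stack(cols)
    categorical = frozenset(n for n, c in zip(names, cat) if c)
    return seq, FeatureSchema(tuple(names), SKIP_FEATURES, categorical)


def assemble(instance: PredictionInstance, imputed: HourlyGrid,
             dose_col: np.ndarray, schema: FeatureSchema,
             stats: NormalizationStats) -> SequenceSample:
    """Build the normalized (24, F) sequence and raw skip vector."""
    if instance.encounter is None:
        raise ValueError(f"instance {instance.patient_id} lacks its encounter")
    skip = _raw_skip(instance, stats.variable_means.get("_prior_trough", 10.0))
    seq, seq_schema = _raw_sequence(instance, imputed, dose_col, skip)
    if seq_schema.sequence_features != schema.sequence_features:
        raise ValueError("feature schema mismatch")
    normed = (seq - stats.seq_mean) / stats.seq_sd
    return SequenceSample(
        patient_id=instance.patient_id, sequence=normed, skip_features=skip,
        target=instance.target_trough, range=instance.range,
        prediction_time=instance.prediction_time,
        target_time=instance.target_time,
        pharmacist_prediction=instance.pharmacist_prediction)


# ---------------------------------------------------------------------------
# Fitted pipeline
# ---------------------------------------------------------------------------

class FeaturePipeline:
    """Fit normalization statistics on training instances, then transform.

    All statistics (variable means for imputation, z-score means/SDs, skip
    normalizers) come exclusively from the training split.
    """

    def __init__(self, variables: tuple | None = None, window: int = 72):
        self.variables = tuple(variables) if variables else tuple(
            sorted(LAB_VARIABLES + VITAL_VARIABLES))
        self.window = window
        self.schema: FeatureSchema | None = None
        self.stats: NormalizationStats | None = None
        self._grid_cache: dict = {}

    # -- internals ------------------------------------------------------
    def _encounter_grid(self, enc: Encounter) -> tuple:
        key = id(enc)
        if key not in self._grid_cache:
            n_hours = max(SEQ_HOURS, int(math.ceil(enc.icu_discharge)))
            grid = bin_hourly(enc.observations, n_hours, self.variables)
            dose_col = _dose_channel(enc, n_hours)
            self._grid_cache[key] = (grid, dose_col)
        return self._grid_cache[key]

    def fit(self, train_instances: list) -> "FeaturePipeline":
        if not train_instances:
            raise ValueError("cannot fit on zero training instances")
        # pass 1: raw-scale means of observed cells (for mean imputation)
        sums = {v: 0.0 for v in self.variables}
        counts = {v: 0 for v in self.variables}
        encounters = {id(i.encounter): i.encounter for i in train_instances}
        for enc in encounters.values():
            grid, _ = self._encounter_grid(enc)
            for j, var in enumerate(grid.variables):
                m = grid.mask[:, j]
                sums[var] += float(grid.values[m, j].sum())
                counts[var] += int(m.sum())
        variable_means = {v: (sums[v] / counts[v] if counts[v] else 0.0)
                          for v in self.variables}
        priors = [max((tr for tr in i.encounter.troughs
                       if tr.t < i.prediction_time),
                      key=lambda tr: tr.t, default=None)
                  for i in train_instances]
        prior_vals = [p.value for p in priors if p is not None]
        variable_means["_prior_trough"] = (float(np.mean(prior_vals))
                                           if prior_vals else 10.0)
        stats = NormalizationStats(variable_means,
                                   np.zeros(1), np.ones(1),
                                   np.zeros(len(SKIP_FEATURES)),
                                   np.ones(len(SKIP_FEATURES)))
        # pass 2: z-score statistics over raw training sequences
        raw_seqs, raw_skips = [], []
        for inst in train_instances:
            grid, dose_col = self._encounter_grid(inst.encounter)
            imputed = impute(grid, stats)
            skip = _raw_skip(inst, variable_means["_prior_trough"])
            seq, schema = _raw_sequence(inst, imputed, dose_col, skip,
                                        self.window)
            raw_seqs.append(seq)
            raw_skips.append(skip)
            self.schema = schema
        stacked = np.concatenate(raw_seqs, axis=0)
        seq_mean = stacked.mean(axis=0)
        seq_sd = np.maximum(stacked.std(axis=0), _EPS)
        for j, name in enumerate(self.schema.sequence_features):
            if name in self.schema.categorical:
                seq_mean[j], seq_sd[j] = 0.0, 1.0  # flags stay 0/1
        skips = np.asarray(raw_skips)
        skip_mean = skips.mean(axis=0)
        skip_sd = np.maximum(skips.std(axis=0), _EPS)
        skip_mean[-1], skip_sd[-1] = 0.0, 1.0  # presence flag stays 0/1
        self.stats = NormalizationStats(variable_means, seq_mean, seq_sd,
                                        skip_mean, skip_sd)
        return self

    def transform(self, instances: list) -> list:
        if self.stats is None or self.schema is None:
            raise RuntimeError("pipeline must be fit before transform")
        samples = []
        for inst in instances:
            grid, dose_col = self._encounter_grid(inst.encounter)
            imputed = impute(grid, self.stats)
            samples.append(assemble(inst, imputed, dose_col,
                                    self.schema, self.stats))
        return samples

    def fit_transform(self, train_instances: list) -> list:
        return self.fit(train_instances).transform(train_instances)
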