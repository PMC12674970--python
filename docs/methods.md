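# Methods

## Scope

`troughcast` predicts the steady-state vancomycin trough concentration
measured about two days after a prediction day in ICU patients, scores
feature relevance, and searches over dose adjustments for the candidate
most likely to land the trough in the patient's therapeutic range. Since
no public ICU vancomycin extract exists, the package includes a synthetic
cohort generator; everything below separates what the generator *assumes*
from what the model and analyses *measure*.

## Synthetic cohort generator

**Pharmacokinetic ground truth.** One-compartment kinetics with
first-order elimination and zero-order intermittent infusions. Clearance
is linear in creatinine clearance, CL (L/h) = 0.05 + 0.75·CrCl(L/h),
chosen to reproduce the well-established CL–CrCl correlation without
committing to any specific population model; the distribution volume is
0.7 L/kg, the standard adult value. Both are configurable (`PKParams`).
CrCl comes from Cockcroft–Gault on age, weight, sex and serum creatinine.

**Quasi-static clearance.** Each encounter's clearance is fixed at the
value implied by its stay-averaged SCr. AKI therefore affects troughs
through the *average* creatinine of the stay while the hourly SCr stream
(the model's input) shows the full episode. This keeps every noise-free
trough exactly equal to the closed-form superposition — the oracle
equivalence the test suite asserts at 1e−9 relative tolerance — at the
cost of not modelling within-stay clearance dynamics. Consequences: the
simulator cannot produce the within-encounter prediction-lag failures
seen with real AKI, so passing tests demonstrate pipeline and learning
correctness, not clinical robustness to non-stationary kidney function.

**Covariates.** Age ~ U(18, 92); weight lognormal around 80 kg; sex 63%
male; baseline SCr lognormal around 0.7 mg/dL (σ = 0.5, clipped to
0.25–5); seven comorbidity flags at ICU-typical rates; four ethnicity
codes. AKI stages 1/2/3 are injected at 29/12/2.4% with piecewise
log-linear SCr rise (24–48 h), plateau (12–24 h) and resolution
(48–96 h); the injected peak ratio is drawn inside the KDIGO band for the
sampled stage, away from the 1.5/2/3 thresholds, so the staging function
recovers it exactly.

**Observation streams.** Labs (SCr, BUN, WBC, hemoglobin) every 6–24 h
with 3% multiplicative noise; vitals (HR, SBP, temperature, RR) hourly
with 20% dropout. This gives the LOCF/mean-imputation logic realistic
work. Missingness is completely at random within these schedules — real
informative missingness (sicker patients measured more) is not emulated.

**Dosing policy.** q12h one-hour infusions. Half of encounters start
empirically at 15 mg/kg (rounded to 250 mg); the other half start from a
PK-informed estimate computed with a deliberately mis-specified clearance
(0.9× the true CrCl slope, the same bias as the benchmark predictions) —
a mixture reflecting variation in practice. Troughs are drawn 0–60 min
before every fourth dose (≈ every 2 days) with Gaussian measurement noise
(SD 1.0 mg/L, configurable). After an out-of-range trough the dose is
corrected part-way toward the range midpoint (exponent 0.7) with
probability 0.8 — titration in practice is sluggish and partial. The
therapeutic range is 10–15 mg/L (70%) or 15–20 mg/L (30%) per encounter.

**Benchmark column.** Each trough carries a stand-in "pharmacist"
prediction: the noise-free concentration under the 0.9×-biased clearance.
It exists so the paired-comparison machinery (paired t, McNemar) has
deterministic, non-trivial input; it is synthetic and makes no claim
about real Bayesian-software-aided practice.

**Exclusion-triggering features.** 8% of encounters carry kidney
replacement therapy blocks, 5% continuous-infusion days, and 10% stays
forced beyond 14 days, so each eligibility rule has real work.

## Eligibility and instances

A "day" is a whole 24 h block from ICU admission; the prediction is made
at the end of the day. A patient-day becomes an instance if age ≥ 18, the
stay is ≥ 24 h, the day index is < 14, there is no continuous infusion
that day, no KRT that day or in the preceding 7 days, at least one IV
dose that day, and a trough 36–60 h after the prediction time (the paper
of record says "2 days" without tolerance; a windowed join avoids brittle
exact-hour matching, and the earliest in-window trough is the target).
Exclusions are per patient-day, not per encounter. The train/test split
is at the encounter level (80/20) to prevent leakage.

## Features

Per time-varying variable: the 24 hourly values of the prediction day
(median per bin, LOCF up to 24 h, then training-mean fill) plus the OLS
slope and mean over the previous 72 h. An hourly Cockcroft–Gault CrCl
channel (with its own 72 h trend) is derived from imputed SCr — kidney
function expressed as clearance is a standard covariate in this problem.
Statics (age, sex, weight, height, ethnicity one-hot, comorbidities) are
broadcast over the 24 rows; missing categoricals are imputed as absent
(0). The dose shortcut vector is [prediction-day total dose, interval
dose from prediction time to trough collection, hours since last dose,
most recent prior trough, prior-trough-present flag]; the prior trough is
training-mean-filled when absent. These five are *also* broadcast into
the sequence so the recurrent path can form dose×kidney-function
interactions, while the linear shortcut keeps them undiluted at the
output layer.

Continuous sequence features are z-scored with training-set statistics
(SD floored at 1e−6); 0/1 flags are left raw. Skip features stay in raw
clinical units and are normalized inside the model — this lets the dose
line search edit the interval dose directly in milligrams. Normalization
statistics never see test instances.

## Model and training

LSTM with hidden size 16 over the 24 steps, returning all hidden states;
2-head self-attention over the time axis with key dimension 64 (per-head
query/key/value projections from the 16-dim states, softmax over time,
output projection back to 16); mean pooling over the 24 attended vectors
(the reduction between attention and the dense layer is not dictated by
the architecture description, and mean pooling is the simplest
shape-correct choice, kept isolated in one line for ablation);
concatenation with the normalized skip vector; a single linear unit
outputs mg/L. Implemented on an in-package numpy reverse-mode autodiff
tape; backprop is verified against central finite differences at 1e−4
relative tolerance in the test suite.

Training: Adam (lr 1e−2), MSE on internally standardized targets, L2
5e−2 on all weight kernels (biases unpenalized), batch 64, up to 200
epochs, early stopping (patience 30) on a held-out 15% of training
*patients*, halving the learning rate after 10 stale epochs, best-epoch
weights restored. The unusually strong L2 is deliberate: at ~10³ training
instances the attention stack memorizes patients within a few epochs
otherwise. All randomness (init, shuffling, validation split) derives
from one seed; identical seeds give bitwise-identical weights. A seeded
random search over lr/L2/batch size (`random_search`) stands in for
Bayesian hyperparameter optimization with the same interface. Raw
predictions are unconstrained; clipping at 0 happens only at reporting
time in the pipeline driver.

## Evaluation

MAE, RMSE and MAPE (0–100 scale; pairs with observed troughs below
0.5 mg/L are excluded from MAPE with a warning — the ratio explodes near
zero; threshold configurable). Therapeutic categories use each instance's
own range with inclusive bounds ("10–15" clinically includes both ends);
accuracy is the confusion-matrix trace over the total. Bland–Altman
reports the mean difference and mean ± 1.96·SD limits of agreement.
Paired model-vs-benchmark comparisons use the paired t-test on absolute
errors and McNemar's test on category correctness (continuity-corrected
chi-square, exact binomial below 25 discordant pairs).

## Dose recommendation

Candidates are the interval dose plus every multiple of 250 mg in
[−1500, +1500], clipped below at 0 mg total. Each candidate is re-scored
by substituting it into the interval-dose skip feature (optionally also
rescaling the prediction-day dose via `scale_day_dose`) and re-running
the model. Reward: 0 inside the range, minus the mg/L distance to the
nearest bound outside — the proximity form, injectable for variants.
Selection maximizes reward; ties prefer the predicted trough closest to
the range midpoint, then the smallest |change|. The search is exhaustive
over the 13 candidates, so it is evaluation-order-free and matches
brute-force enumeration exactly (tested over randomized predictors).

The distance–reward analysis bins (administered − recommended) dose at
250 mg and averages the reward of the *measured* trough per bin (a flag
switches to predicted troughs). With an accurate model, instances dosed
at the recommendation score near 0 and the mean reward decays toward the
±1500 mg bins.

## Study sizes and numerical choices

The synthetic study used by the acceptance checks is 500 encounters
(≈ 1000 instances) with three training seeds — large enough for stable
learning-vs-baseline comparisons while keeping a full run in minutes on
one CPU. Center bins of the distance–reward curve hold tens of instances
after pooling the three seeds, so curve comparisons are made on pooled
bins; the ±500 mg comparison in particular has an expected margin of only
a few tenths of a mg/L because a 500 mg interval-dose deviation moves the
trough by ~1 mg/L against a 5 mg/L-wide range. Degenerate inputs: slopes
with fewer than two points are 0 by convention; empty reward-curve bins
are omitted; feature SDs are floored at 1e−6; trough values are floored
at 0.05 mg/L in the generator.

## Known limitations

- One-compartment, quasi-static clearance: no within-stay PK
  non-stationarity, no KRT drug removal, no continuous-infusion PK.
- Missingness is non-informative; real EHR sampling is not.
- The benchmark prediction column is a synthetic biased-model stand-in.
- The default schema (8 observed variables, ~53 features) is far smaller
  than a production EHR feature inventory; the schema is configurable.
- Model performance numbers quoted anywhere in this repository are
  properties of the synthetic cohort, not of any clinical dataset.
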