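import numpy as np
import pytest

import troughcast as tc


@pytest.fixture(scope="session")
def small_cohort():
    """Forty synthetic encounters, enough for every downstream stage."""
    return tc.generate_cohort(tc.CohortConfig(n_encounters=40), seed=7)


@pytest.fixture(scope="session")
def small_instances(small_cohort):
    return tc.select_eligible(small_cohort)


@pytest.fixture(scope="session")
def small_split(small_instances):
    return tc.split_train_test(small_instances, 0.8, seed=3)


@pytest.fixture(scope="session")
def fitted_pipeline(small_split):
    train, _ = small_split
    pipe = tc.FeaturePipeline()
    pipe.fit(train)
    return pipe


@pytest.fixture(scope="session")
def small_samples(small_split, fitted_pipeline):
    train, test = small_split
    return (fitted_pipeline.transform(train), fitted_pipeline.transform(test))


@pytest.fixture(scope="session")
def tiny_model(fitted_pipeline, small_samples):
    """Briefly trained model for plumbing tests (not a performance fixture)."""
    train_samples, _ = small_samples
    cfg = tc.ModelConfig(max_epochs=4, early_stop_patience=4, seed=0)
    model = tc.build(cfg, fitted_pipeline.schema, fitted_pipeline.stats)
    return tc.train(model, train_samples)


def make_encounter(patient_id="p1", age=50.0, sex="male", weight=80.0,
                   stay_hours=240.0, doses=(), troughs=(), observations=(),
                   krt_hours=(), ci_days=(), baseline_scr=1.0):
    """Hand-built encounter for rule-targeted fixtures."""
    static = tc.PatientStatic(patient_id, age, sex, weight, 175.0, 0,
                              (0,) * 7, baseline_scr)
    rng = tc.TherapeuticRange(10.0, 15.0)
    trough_objs = [tc.TroughObservation(t, v, rng) for t, v in troughs]
    dose_objs = [tc.DoseEvent(t, amt, 1.0) for t, amt in doses]
    obs_objs = [tc.TimedObservation(var, t, v) for var, t, v in observations]
    return tc.Encounter(static=static, observations=obs_objs, doses=dose_objs,
                        troughs=trough_objs, krt_hours=set(krt_hours),
                        continuous_infusion_days=set(ci_days),
                        icu_admit=0.0, icu_discharge=stay_hours)
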