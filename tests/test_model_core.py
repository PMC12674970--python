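"""Network architecture, training, persistence and relevance scoring."""

import dataclasses

import numpy as np
import pytest

import troughcast as tc
from troughcast._autodiff import Tensor
from troughcast.feature_pipeline import (SKIP_FEATURES, FeatureSchema,
                                         NormalizationStats, SequenceSample)
from troughcast.model_core import gradient_times_input


def toy_schema(f=6):
    return FeatureSchema(tuple(f"f{i}" for i in range(f)), SKIP_FEATURES,
                         frozenset())


def identity_stats(f, s=len(SKIP_FEATURES)):
    return NormalizationStats({}, np.zeros(f), np.ones(f),
                              np.zeros(s), np.ones(s))


def toy_model(f=6, seed=0, **kw):
    cfg = tc.ModelConfig(seed=seed, **kw)
    return tc.build(cfg, toy_schema(f), identity_stats(f)), cfg


def toy_samples(n, f=6, seed=0, target_fn=None):
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        seq = rng.normal(size=(24, f))
        skip = np.abs(rng.normal(size=len(SKIP_FEATURES))) + 0.1
        target = target_fn(seq, skip) if target_fn else float(rng.normal(12, 3))
        samples.append(SequenceSample(
            patient_id=f"p{i}", sequence=seq, skip_features=skip,
            target=target, range=tc.TherapeuticRange(10, 15)))
    return samples


class TestArchitecture:
    def test_parameter_count_matches_actual(self):
        model, cfg = toy_model(f=10)
        actual = sum(t.data.size for t in model.params.values())
        assert actual == tc.parameter_count(10, len(SKIP_FEATURES), cfg)
        # closed form for the defaults: LSTM 4(16(F+16)+16), attention
        # 3(16*128+128)+(128*16+16), dense (16+S)+1
        assert tc.parameter_count(10, 4, cfg) == \
            4 * (16 * 26 + 16) + (3 * (2048 + 128) + 2048 + 16) + 21

    def test_zeroed_skip_weights_ignore_skip_features(self):
        model, _ = toy_model()
        model.params["Wd"].data[16:, :] = 0.0
        s = toy_samples(3)
        preds_a = model.predict(s)
        for sample in s:
            sample.skip_features = sample.skip_features * 7.0 + 1.0
        preds_b = model.predict(s)
        assert np.allclose(preds_a, preds_b)

    def test_time_order_sensitivity(self):
        model, _ = toy_model()
        (s,) = toy_samples(1)
        base = model.predict([s])[0]
        flipped = dataclasses.replace(s, sequence=s.sequence[::-1].copy())
        assert model.predict([flipped])[0] != pytest.approx(base, abs=1e-9)

    def test_batch_invariance_and_duplication(self):
        model, _ = toy_model()
        samples = toy_samples(5)
        alone = model.predict([samples[2]])[0]
        batch = model.predict(samples)
        assert batch[2] == pytest.approx(alone, rel=1e-12)
        dup = model.predict([samples[2], samples[2]])
        assert dup[0] == dup[1]


class TestTraining:
    def test_learns_linear_skip_relationship(self):
        """Noiseless target linear in the skip dose is fit to < 0.5 mg/L."""
        samples = toy_samples(
            200, target_fn=lambda seq, skip: 5.0 + 2.0 * skip[1])
        model, cfg = toy_model(max_epochs=150, early_stop_patience=150,
                               val_fraction=0.0, l2_lambda=1e-4)
        tc.train(model, samples)
        mae = np.abs(model.predict(samples)
                     - np.array([s.target for s in samples])).mean()
        assert mae < 0.5

    def test_seed_reproducibility(self):
        samples = toy_samples(40)
        m1, _ = toy_model(seed=5, max_epochs=3)
        m2, _ = toy_model(seed=5, max_epochs=3)
        tc.train(m1, samples)
        tc.train(m2, samples)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)

    def test_huge_l2_shrinks_to_bias(self):
        samples = toy_samples(60)
        model, _ = toy_model(l2_lambda=1e4, max_epochs=30,
                             early_stop_patience=30, val_fraction=0.0)
        tc.train(model, samples)
        preds = model.predict(samples)
        assert np.std(preds) < 0.5  # essentially constant output

    def test_nonfinite_loss_aborts(self):
        samples = toy_samples(30)
        samples[0] = dataclasses.replace(samples[0], target=float("nan"))
        model, _ = toy_model(max_epochs=5, val_fraction=0.0)
        with pytest.raises(FloatingPointError):
            tc.train(model, samples)

    def test_requires_samples(self):
        model, _ = toy_model()
        with pytest.raises(ValueError):
            tc.train(model, [])

    def test_beats_mean_baseline_on_synthetic_split(self):
        cohort = tc.generate_cohort(tc.CohortConfig(n_encounters=150), seed=7)
        train, test = tc.split_train_test(tc.select_eligible(cohort), 0.8, 3)
        pipe = tc.FeaturePipeline()
        train_samples = pipe.fit_transform(train)
        test_samples = pipe.transform(test)
        cfg = tc.ModelConfig(seed=0, max_epochs=80, early_stop_patience=25)
        model = tc.train(tc.build(cfg, pipe.schema, pipe.stats),
                         train_samples)
        y = np.array([s.target for s in test_samples])
        y_train = np.array([s.target for s in train_samples])
        mae = np.abs(model.predict(test_samples) - y).mean()
        baseline = np.abs(y_train.mean() - y).mean()
        assert mae < baseline

    def test_history_recorded(self, tiny_model):
        assert len(tiny_model.history["train_mse"]) >= 1
        assert len(tiny_model.history["val_mse"]) \
            == len(tiny_model.history["train_mse"])


class TestGradients:
    def test_input_gradient_matches_finite_difference(self):
        model, _ = toy_model(f=5)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2, 24, 5))
        S = rng.normal(size=(2, len(SKIP_FEATURES)))
        xt = Tensor(X, requires_grad=True)
        st = Tensor(S, requires_grad=True)
        model.forward(xt, st).sum().backward()
        eps = 1e-6
        for _ in range(12):
            b, t, f = (int(rng.integers(2)), int(rng.integers(24)),
                       int(rng.integers(5)))
            xp, xm = X.copy(), X.copy()
            xp[b, t, f] += eps
            xm[b, t, f] -= eps
            fd = (model.forward(Tensor(xp), Tensor(S)).data.sum()
                  - model.forward(Tensor(xm), Tensor(S)).data.sum()) / (2 * eps)
            assert xt.grad[b, t, f] == pytest.approx(fd, rel=1e-4, abs=1e-10)
        for _ in range(6):
            b, j = int(rng.integers(2)), int(rng.integers(len(SKIP_FEATURES)))
            sp, sm = S.copy(), S.copy()
            sp[b, j] += eps
            sm[b, j] -= eps
            fd = (model.forward(Tensor(X), Tensor(sp)).data.sum()
                  - model.forward(Tensor(X), Tensor(sm)).data.sum()) / (2 * eps)
            assert st.grad[b, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestRelevance:
    def test_linear_stub_gradient_times_input(self):
        # y = 2 x1 + 0.5 x2 at x = (3, 4) -> relevance (6.0, 2.0)
        def linear(x):
            w = Tensor(np.array([[2.0], [0.5]]))
            return x @ w

        (rel,) = gradient_times_input(linear, np.array([[3.0, 4.0]]))
        assert np.allclose(rel, [[6.0, 2.0]])

    def test_zero_input_zero_relevance(self, tiny_model, small_samples):
        _, test_samples = small_samples
        s = dataclasses.replace(test_samples[0],
                                sequence=test_samples[0].sequence.copy())
        s.sequence[:, 0] = 0.0
        rel = tc.relevance_scores(tiny_model, [s])
        assert np.all(rel.sequence_cells[:, :, 0] == 0.0)

    def test_aggregate_covers_all_features(self, tiny_model, small_samples):
        _, test_samples = small_samples
        rel = tc.relevance_scores(tiny_model, test_samples[:5])
        expected = set(tiny_model.schema.sequence_features) \
            | set(tiny_model.schema.skip_features)
        assert set(rel.aggregate) == expected
        cont, cat = rel.ranked_split()
        assert {n for n, _ in cont} | {n for n, _ in cat} == expected


class TestPersistence:
    def test_save_load_roundtrip_exact(self, tiny_model, small_samples, tmp_path):
        _, test_samples = small_samples
        tc.save_model(tiny_model, str(tmp_path / "m"))
        loaded = tc.load_model(str(tmp_path / "m"))
        a = tiny_model.predict(test_samples)
        b = loaded.predict(test_samples)
        assert np.array_equal(a, b)
        assert loaded.config == tiny_model.config
        assert loaded.schema.sequence_features \
            == tiny_model.schema.sequence_features
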