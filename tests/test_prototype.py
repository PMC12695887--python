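"""Prototype learning: losses, classification rule, splitting, training."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pafingerprint as pf
from pafingerprint.prototype import (
    CE_EPSILON,
    PrototypeError,
    PrototypeNetClassifier,
    TrainConfig,
    split_dataset,
    train,
)
from conftest import make_two_class_set

CLASSES = ("c1", "c2", "c3", "c4", "c5")


def random_protoset(rng, C=5, D=8, K=1):
    return pf.PrototypeSet(
        prototypes=rng.standard_normal((C, K, D)),
        class_names=CLASSES[:C],
        K=K,
    )


class TestClassify:
    def test_feature_equal_to_prototype(self):
        rng = np.random.default_rng(0)
        ps = random_protoset(rng)
        cls, dist = pf.classify(ps.prototypes[2, 0], ps)
        assert cls == "c3"
        assert dist == pytest.approx(0.0)

    def test_equidistant_tie_breaks_to_lower_class_index(self):
        protos = np.zeros((2, 1, 3))
        protos[0, 0] = [1.0, 0.0, 0.0]
        protos[1, 0] = [-1.0, 0.0, 0.0]
        ps = pf.PrototypeSet(protos, ("c1", "c2"))
        cls, _ = pf.classify(np.zeros(3), ps)
        assert cls == "c1"

    def test_matches_exhaustive_scan_over_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            K = int(rng.integers(1, 4))
            ps = random_protoset(rng, C=5, D=6, K=K)
            f = rng.standard_normal(6)
            cls, dist = pf.classify(f, ps)
            # exhaustive scan over all C*K prototypes
            best = min(
                ((ci, float(np.linalg.norm(f - ps.prototypes[ci, ki])))
                 for ci in range(5) for ki in range(K)),
                key=lambda t: t[1],
            )
            assert cls == ps.class_names[best[0]]
            assert dist == pytest.approx(best[1])

    def test_dimension_mismatch_rejected(self):
        ps = random_protoset(np.random.default_rng(0), D=8)
        with pytest.raises(PrototypeError):
            pf.classify(np.zeros(5), ps)


class TestClassProbabilities:
    def test_equidistant_gives_uniform(self):
        protos = np.zeros((5, 1, 3))
        for i in range(5):
            protos[i, 0, 0] = math.cos(2 * math.pi * i / 5)
            protos[i, 0, 1] = math.sin(2 * math.pi * i / 5)
        ps = pf.PrototypeSet(protos, CLASSES)
        p = pf.class_probabilities(np.zeros(3), ps).probabilities
        np.testing.assert_allclose(p, 0.2, atol=1e-12)

    def test_closed_form_two_class(self):
        # d1 = 0, d2 = ln 3  =>  p1 = 1/(1+e^{-ln3}) = 0.75
        protos = np.zeros((2, 1, 1))
        protos[1, 0, 0] = math.log(3.0)
        ps = pf.PrototypeSet(protos, ("c1", "c2"))
        p = pf.class_probabilities(np.zeros(1), ps).probabilities
        assert p[0] == pytest.approx(0.75, abs=1e-12)

    def test_shift_invariance_of_distances(self):
        # moving the feature so every distance grows by the same amount is
        # not generally possible in Euclidean space; verify directly on the
        # softmax: adding a constant to all distances leaves p unchanged
        rng = np.random.default_rng(2)
        d = rng.random(5) + 0.5
        for shift in (0.0, 10.0):
            z = -(d + shift)
            z = z - z.max()
            e = np.exp(z)
            p = e / e.sum()
            if shift == 0.0:
                base = p
        np.testing.assert_allclose(p, base, atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_argmax_probability_equals_classify(self, seed):
        rng = np.random.default_rng(seed)
        ps = random_protoset(rng, C=int(rng.integers(2, 6)), D=4)
        f = rng.standard_normal(4)
        probs = pf.class_probabilities(f, ps)
        assert probs.top == pf.classify(f, ps)[0]
        assert float(probs.probabilities.sum()) == pytest.approx(1.0, abs=1e-12)


class TestLosses:
    def test_ce_of_certain_prediction_is_zero(self):
        probs = pf.ClassProbabilities(np.array([1.0, 0.0]), ("a", "b"))
        assert pf.cross_entropy(probs, "a") == pytest.approx(0.0, abs=1e-9)

    def test_ce_uniform_is_log_c(self):
        probs = pf.ClassProbabilities(np.full(5, 0.2), CLASSES)
        assert pf.cross_entropy(probs, "c3") == pytest.approx(math.log(5), abs=1e-12)

    def test_ce_consistent_with_probability_pipeline(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = random_protoset(rng, D=4)
            f = rng.standard_normal(4)
            probs = pf.class_probabilities(f, ps)
            y = CLASSES[int(rng.integers(5))]
            want = -math.log(max(probs.probabilities[CLASSES.index(y)], CE_EPSILON))
            assert pf.cross_entropy(probs, y) == pytest.approx(want, rel=1e-12)

    def test_ce_unknown_class_rejected(self):
        probs = pf.ClassProbabilities(np.full(5, 0.2), CLASSES)
        with pytest.raises(PrototypeError):
            pf.cross_entropy(probs, "zebra")

    def test_pl_zero_iff_feature_on_prototype(self):
        rng = np.random.default_rng(4)
        ps = random_protoset(rng, D=3)
        assert pf.prototype_loss(ps.prototypes[1, 0], ps, "c2") == pytest.approx(0.0)
        assert pf.prototype_loss(ps.prototypes[1, 0] + 0.1, ps, "c2") > 0

    def test_pl_direct_arithmetic(self):
        protos = np.zeros((2, 1, 3))
        ps = pf.PrototypeSet(protos, ("c1", "c2"))
        assert pf.prototype_loss(np.array([1.0, 2.0, 2.0]), ps, "c1") == pytest.approx(9.0)

    def test_pl_matches_coordinate_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ps = random_protoset(rng, D=6)
            f = rng.standard_normal(6)
            y = CLASSES[int(rng.integers(5))]
            want = sum(
                (f[j] - ps.prototypes[CLASSES.index(y), 0, j]) ** 2 for j in range(6)
            )
            assert pf.prototype_loss(f, ps, y) == pytest.approx(want, rel=1e-12)

    def test_total_loss_weighting(self):
        lb = pf.total_loss(2.0, 5.0, 0.1)
        assert lb.total == pytest.approx(2.5)
        assert (lb.total - lb.ce) / lb.pl == pytest.approx(0.1, rel=1e-12)
        assert pf.total_loss(3.0, 0.0, 0.1).total == 3.0
        assert pf.total_loss(3.0, 9.0, 0.0).total == 3.0
        with pytest.raises(PrototypeError):
            pf.total_loss(-1.0, 0.0, 0.1)


class TestSplitDataset:
    def test_balanced_100_samples_gives_80_20(self, rbc_dataset):
        half = pf.LabeledSignalSet(
            [s for s in rbc_dataset.signals][:100], list(rbc_dataset.class_names)
        )
        # first 100 signals = 40 pig, 40 sheep, 20 turkey: rebuild balanced
        per_class = {}
        signals = []
        for s in rbc_dataset.signals:
            if per_class.get(s.label, 0) < 20:
                per_class[s.label] = per_class.get(s.label, 0) + 1
                signals.append(s)
        ds = pf.LabeledSignalSet(signals, list(rbc_dataset.class_names))
        assert len(ds) == 100
        tr, te, rec = split_dataset(ds, 0.8, True, seed=0)
        assert len(tr) == 80 and len(te) == 20
        assert all(c == 16 for c in tr.counts.values())
        assert all(c == 4 for c in te.counts.values())

    def test_union_always_equals_input(self, two_class_set):
        tr, te, _ = split_dataset(two_class_set, 0.93, True, seed=1)
        assert len(tr) + len(te) == len(two_class_set)
        # every class keeps at least one test sample even under rounding
        assert all(c >= 1 for c in te.counts.values())

    def test_same_seed_reproduces_assignment(self, two_class_set):
        _, _, a = split_dataset(two_class_set, 0.8, True, seed=7)
        _, _, b = split_dataset(two_class_set, 0.8, True, seed=7)
        assert a["assignment"] == b["assignment"]

    def test_impossible_stratification_rejected(self, rbc_templates):
        ds = pf.generate_dataset(rbc_templates[:2], 1, pf.AcquisitionConfig(seed=0))
        with pytest.raises(PrototypeError):
            split_dataset(ds, 0.8, True, seed=0)


class TestTraining:
    def test_zero_epochs_returns_initialization(self, two_class_set):
        tc = TrainConfig(epochs=0, seed=3)
        clf = train(two_class_set, train_config=tc)
        from pafingerprint.features import ModelConfig, init_model
        init = init_model(ModelConfig(seed=3))
        assert clf.model_state.digest() == init.digest()

    def test_separable_two_class_converges(self):
        ds = make_two_class_set(n_per_class=10, seed=5)
        mc = pf.ModelConfig(input_length=128, conv_kernels=((5, 8),), pool_width=4,
                            feature_dim=8, seed=5)
        clf = train(ds, model_config=mc,
                    train_config=TrainConfig(epochs=800, seed=5))
        hist = clf.history
        assert hist[-1]["train_accuracy"] == 1.0
        # at convergence the prototype pull dominates: features sit far
        # closer to their class prototypes than after the first epoch
        assert hist[-1]["pl"] < hist[0]["pl"]

    def test_training_deterministic_given_seed(self):
        ds = make_two_class_set(n_per_class=6, seed=6)
        mc = pf.ModelConfig(input_length=128, conv_kernels=((5, 4),), pool_width=4,
                            feature_dim=4, seed=6)
        tc = TrainConfig(epochs=5, seed=6)
        a = train(ds, model_config=mc, train_config=tc)
        b = train(ds, model_config=mc, train_config=tc)
        assert a.model_state.digest() == b.model_state.digest()
        np.testing.assert_array_equal(a.prototypes.prototypes, b.prototypes.prototypes)

    def test_lambda_pulls_features_toward_prototypes(self):
        # stronger prototype-loss weight => smaller final mean squared
        # feature-to-prototype distance (averaged over 5 seeds)
        mc = pf.ModelConfig(input_length=128, conv_kernels=((5, 8),), pool_width=4,
                            feature_dim=8)
        final_pl = {}
        for lam in (0.0, 0.1, 1.0):
            vals = []
            for seed in range(5):
                ds = make_two_class_set(n_per_class=8, seed=seed)
                from dataclasses import replace
                clf = train(ds, model_config=replace(mc, seed=seed),
                            train_config=TrainConfig(epochs=25, lam=lam, seed=seed))
                vals.append(clf.history[-1]["pl"])
            final_pl[lam] = float(np.mean(vals))
        assert final_pl[0.0] >= final_pl[0.1] >= final_pl[1.0]

    def test_separate_models_do_not_share_state(self):
        rbc = make_two_class_set(n_per_class=6, seed=7)
        mc = pf.ModelConfig(input_length=128, conv_kernels=((5, 4),), pool_width=4,
                            feature_dim=4, seed=7)
        tc = TrainConfig(epochs=3, seed=7)
        clf_a = train(rbc, model_config=mc, train_config=tc)
        digest_before = clf_a.model_state.digest()
        protos_before = clf_a.prototypes.prototypes.copy()
        # training a second model of the same architecture on other data
        other = make_two_class_set(n_per_class=6, seed=8)
        train(other, model_config=mc, train_config=tc)
        assert clf_a.model_state.digest() == digest_before
        np.testing.assert_array_equal(clf_a.prototypes.prototypes, protos_before)


class TestPredict:
    def test_predict_matches_nearest_prototype_oracle(self, rbc_classifier, rbc_split):
        _, test_set, _ = rbc_split
        sheep = [s for s in test_set.signals if s.label == "sheep"]
        est = rbc_classifier.estimator
        for sig in sheep:
            label, probs = pf.predict(rbc_classifier, sig)
            x = rbc_classifier.signal_to_input(sig)[None, :]
            feat = est.transform(x)[0]
            oracle, _ = pf.classify(feat, est.prototypes_)
            assert label == oracle
            assert probs.top == label
            assert float(probs.probabilities.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_incompatible_length_rejected(self, rbc_classifier):
        with pytest.raises(ValueError):
            rbc_classifier.estimator.predict(np.ones((1, 77)))


class TestSklearnCompat:
    def test_get_set_params_roundtrip(self):
        est = PrototypeNetClassifier(lam=0.3, epochs=5)
        params = est.get_params()
        assert params["lam"] == 0.3
        est2 = PrototypeNetClassifier(**params)
        assert est2.get_params() == params

    def test_fit_predict_on_vectors(self):
        rng = np.random.default_rng(0)
        X = np.zeros((40, 64))
        y = np.array(["a", "b"] * 20)
        X[::2, 10] = 1.0
        X[1::2, 50] = 1.0
        X += 0.01 * rng.standard_normal(X.shape)
        est = PrototypeNetClassifier(
            conv_kernels=((3, 4),), pool_width=2, feature_dim=4,
            epochs=30, random_state=0,
        )
        est.fit(X, y)
        assert est.score(X, y) == 1.0
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
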