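"""Training loop, splitting, augmentation, early stopping, prediction."""

import numpy as np
import pytest

from spiroqc.errors import InvalidParameterError
from spiroqc.model import (
    AugmentConfig,
    EarlyStopper,
    SplitSpec,
    TrainConfig,
    augment_image,
    build_classifier,
    load_checkpoint,
    save_checkpoint,
    split_dataset,
    train,
)


def _toy_dataset(rng, n=24, side=32):
    """Small images whose class is a bright square present/absent."""
    imgs = np.zeros((n, side, side, 3), np.uint8)
    labels = np.zeros(n, int)
    for i in range(n):
        if i % 2:
            r, c = rng.integers(4, side - 10, 2)
            imgs[i, r : r + 6, c : c + 6] = 255
            labels[i] = 1
    return imgs, labels


class TestEarlyStopping:
    def test_stops_after_patience_and_keeps_best(self):
        """Error improving through evaluation 3 then rising monotonically:
        with patience 2 training stops at evaluation 5, parameters from 3."""
        stopper = EarlyStopper(patience=2)
        decisions = [stopper.update(v) for v in [3.0, 2.0, 1.0, 2.0, 3.0]]
        assert decisions == [False, False, False, False, True]
        assert stopper.best_eval == 3
        assert stopper.best_loss == 1.0

    def test_never_returns_worse_than_seen(self, rng):
        stopper = EarlyStopper(patience=3)
        losses = rng.random(30)
        for v in losses:
            if stopper.update(float(v)):
                break
        seen = losses[: stopper.n_evals]
        assert stopper.best_loss == seen.min()
        assert stopper.best_eval == int(seen.argmin()) + 1


class TestSplitting:
    def test_partition_is_disjoint_and_complete(self):
        labels = np.array([0] * 60 + [1] * 30)
        tr, val, te = split_dataset(labels, SplitSpec(seed=5))
        all_idx = np.concatenate([tr, val, te])
        assert np.array_equal(np.sort(all_idx), np.arange(90))
        assert len(set(tr) & set(val)) == len(set(val) & set(te)) == 0
        assert te.size == 9 and val.size == 23

    def test_stratified_split_keeps_both_classes_everywhere(self):
        labels = np.array([0] * 80 + [1] * 20)
        tr, val, te = split_dataset(labels, SplitSpec(validation=0.1, seed=0))
        for part in (tr, val, te):
            assert set(labels[part]) == {0, 1}


class TestAugmentation:
    def test_zero_ranges_are_exact_identity(self, rng):
        ac = AugmentConfig(rotation_deg=(0, 0), translate_x_px=(0, 0),
                           translate_y_px=(0, 0), scale_x=(1, 1), scale_y=(1, 1))
        img = rng.random((50, 50)) * 255
        out = augment_image(img, ac, rng)
        assert out is img

    def test_translation_shifts_content(self, rng):
        ac = AugmentConfig(rotation_deg=(0, 0), translate_x_px=(5, 5),
                           translate_y_px=(0, 0), scale_x=(1, 1), scale_y=(1, 1))
        img = np.zeros((40, 40))
        img[10, 10] = 255.0
        out = augment_image(img, ac, np.random.default_rng(0))
        assert out[10, 15] == pytest.approx(255.0, abs=1e-6)

    def test_zero_width_ranges_match_disabled_trajectories(self, rng):
        """Augmentation draws come from their own RNG stream, so identity
        transforms reproduce the no-augmentation run exactly."""
        imgs, labels = _toy_dataset(rng)
        zero = AugmentConfig(rotation_deg=(0, 0), translate_x_px=(0, 0),
                             translate_y_px=(0, 0), scale_x=(1, 1), scale_y=(1, 1))
        kw = dict(tc=TrainConfig(max_epochs=3, mini_batch=8, learning_rate=1e-3),
                  split=SplitSpec(validation=4, seed=0), seed=7)
        r1 = train(imgs, labels, ac=zero, **kw)
        r2 = train(imgs, labels, ac=AugmentConfig(enabled=False), **kw)
        assert r1.history.equals(r2.history)
        p1, p2 = r1.classifier.net.get_params(), r2.classifier.net.get_params()
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)


class TestTraining:
    def test_learns_toy_separation(self, rng):
        imgs, labels = _toy_dataset(rng, n=40)
        res = train(imgs, labels,
                    tc=TrainConfig(max_epochs=20, mini_batch=8, learning_rate=3e-3),
                    ac=AugmentConfig(enabled=False),
                    split=SplitSpec(validation=6, seed=1), seed=1)
        assert res.history.val_loss.min() < res.history.val_loss.iloc[0]
        assert res.best_eval == int(res.history.val_loss.idxmin()) + 1

    def test_single_class_rejected(self, rng):
        imgs, _ = _toy_dataset(rng)
        with pytest.raises(InvalidParameterError):
            train(imgs, np.zeros(len(imgs), int))

    def test_reproducible_given_seed(self, rng):
        imgs, labels = _toy_dataset(rng)
        kw = dict(tc=TrainConfig(max_epochs=2, mini_batch=8, learning_rate=1e-3),
                  split=SplitSpec(validation=4, seed=0), seed=3)
        p1 = train(imgs, labels, **kw).classifier.net.get_params()
        p2 = train(imgs, labels, **kw).classifier.net.get_params()
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)


class TestPrediction:
    def test_risk_contracts_untrained(self, rng):
        clf = build_classifier(seed=0)
        x = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="not been trained"):
            risk = clf.predict_risk(x)
        assert 0.0 <= risk <= 1.0
        with pytest.warns(UserWarning):
            proba = clf.predict_proba(x)
        assert proba.shape == (1, 2)
        assert proba.sum() == pytest.approx(1.0, abs=1e-5)
        assert proba[0, 1] == pytest.approx(risk, abs=1e-6)

    def test_batch_equals_one_by_one(self, rng):
        clf = build_classifier(seed=1)
        clf.trained = True
        batch = rng.integers(0, 256, (4, 64, 64, 3), dtype=np.uint8)
        joint = clf.predict_risk(batch)
        single = [clf.predict_risk(batch[i]) for i in range(4)]
        assert np.allclose(joint, single, atol=1e-6)

    def test_deterministic_forward(self, rng):
        clf = build_classifier(seed=2)
        clf.trained = True
        x = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        assert clf.predict_risk(x) == clf.predict_risk(x)

    def test_bad_shape_rejected(self, rng):
        clf = build_classifier(seed=0)
        with pytest.raises(InvalidParameterError):
            clf.predict_risk(rng.random((10, 10, 4)))

    def test_pretrained_weights_unavailable(self):
        with pytest.raises(InvalidParameterError, match="pretrained"):
            build_classifier(pretrained=True)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        clf = build_classifier(seed=9)
        clf.trained = True
        path = tmp_path / "model.npz"
        save_checkpoint(clf, path)
        loaded = load_checkpoint(path)
        x = rng.integers(0, 256, (3, 48, 48, 3), dtype=np.uint8)
        assert np.allclose(clf.predict_risk(x), loaded.predict_risk(x), atol=1e-7)
        assert loaded.trained


class TestSanity:
    def test_shuffled_labels_give_chance_auc(self, cough_experiment, rng):
        """Label-shuffled training cannot beat chance beyond noise."""
        from sklearn.metrics import roc_auc_score

        imgs = np.stack([c.network_input for c in cough_experiment.constructs])
        labels = cough_experiment.labels.copy()
        rng.shuffle(labels)
        shuffled = train(
            imgs[:120], labels[:120],
            tc=TrainConfig(max_epochs=8, learning_rate=3e-3),
            split=SplitSpec(validation=15, seed=0), seed=0,
        )
        risks = shuffled.classifier.predict_risk(imgs[:120][shuffled.test_idx])
        auc = roc_auc_score(labels[:120][shuffled.test_idx], risks)
        assert 0.1 <= auc <= 0.9
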