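"""Fold construction, early stopping, prediction contracts and
leakage-free augmentation."""

import numpy as np
import pytest

import hbscreen as hb
from hbscreen.classify import EarlyStopper, _encode, build_model
from hbscreen.errors import ParameterError
from conftest import make_uniform_lane


def balanced_labels(n_per_class):
    labels = {}
    for i in range(n_per_class):
        labels[f"n{i}"] = "normal"
        labels[f"t{i}"] = "thalassaemia"
    return labels


class TestMakeFolds:
    def test_protocol_sizes_262_per_class(self):
        folds = hb.make_folds(balanced_labels(262), k=5, val_per_class=21,
                              seed=1)
        assert len(folds) == 5
        for fold in folds:
            assert len(fold.test_ids) == 2 * 52
            assert len(fold.val_ids) == 2 * 21
            assert len(fold.train_ids) == 2 * 189
            assert not set(fold.test_ids) & (
                set(fold.train_ids) | set(fold.val_ids)
            )
            assert not set(fold.train_ids) & set(fold.val_ids)

    def test_small_case_arithmetic(self):
        folds = hb.make_folds(balanced_labels(10), k=5, val_per_class=1,
                              seed=0)
        for fold in folds:
            assert len(fold.test_ids) == 2 * 2
            assert len(fold.val_ids) == 2 * 1
            assert len(fold.train_ids) == 2 * 7

    def test_test_sets_cover_260_of_262_without_repeats(self):
        folds = hb.make_folds(balanced_labels(262), k=5, val_per_class=21,
                              seed=3)
        seen = [id_ for fold in folds for id_ in fold.test_ids]
        assert len(seen) == len(set(seen)) == 2 * 260

    def test_stratification(self):
        labels = balanced_labels(25)
        folds = hb.make_folds(labels, k=5, val_per_class=2, seed=9)
        for fold in folds:
            for ids, expect in [(fold.test_ids, 5), (fold.val_ids, 2)]:
                classes = [labels[i] for i in ids]
                assert classes.count("normal") == expect
                assert classes.count("thalassaemia") == expect

    def test_determinism_and_seed_sensitivity(self):
        a = hb.make_folds(balanced_labels(20), k=5, seed=4)
        b = hb.make_folds(balanced_labels(20), k=5, seed=4)
        c = hb.make_folds(balanced_labels(20), k=5, seed=5)
        assert [f.test_ids for f in a] == [f.test_ids for f in b]
        assert [f.test_ids for f in a] != [f.test_ids for f in c]

    def test_k_below_two_rejected(self):
        with pytest.raises(ParameterError):
            hb.make_folds(balanced_labels(10), k=1)


class TestEarlyStopper:
    def test_flat_loss_stops_after_five_bad_epochs(self):
        """A validation loss that never improves after epoch 1 halts
        training at epoch 6 (5 consecutive non-improving epochs)."""
        stopper = EarlyStopper(lr_patience=4, stop_patience=5,
                               lr_factor=0.1)
        decisions = [stopper.update(1.0)]  # epoch 1: improvement
        for _ in range(5):
            decisions.append(stopper.update(1.0))
        assert decisions[0] == (True, False)
        assert [d[1] for d in decisions] == [False] * 5 + [True]

    def test_lr_reduced_after_patience(self):
        stopper = EarlyStopper(lr_patience=4, stop_patience=5,
                               lr_factor=0.1)
        stopper.update(1.0)
        for i in range(4):
            assert stopper.lr_scale == 1.0
            stopper.update(1.0)
        assert stopper.lr_scale == pytest.approx(0.1)

    def test_decreasing_loss_never_stops(self):
        stopper = EarlyStopper(lr_patience=4, stop_patience=5,
                               lr_factor=0.1)
        for e in range(15):
            improved, stop = stopper.update(1.0 / (e + 1))
            assert improved and not stop
        assert stopper.lr_scale == 1.0


@pytest.fixture(scope="module")
def tiny_fit(clean_lanes):
    lanes = clean_lanes[:60]
    X = hb.classify.lanes_to_batch([ln.pixels for ln in lanes])
    y = _encode([ln.label for ln in lanes])
    model = build_model(hb.ModelSpec("tinycnn"), seed=2)
    cfg = hb.TrainConfig(seed=2, max_epochs=6)
    trained = hb.fit(model, X[:48], y[:48], X[48:], y[48:], cfg)
    return trained, lanes


class TestFitAndPredict:
    def test_history_schema_and_length(self, tiny_fit):
        trained, _ = tiny_fit
        assert 1 <= len(trained.history) <= 6
        assert set(trained.history[0]) == {
            "epoch", "train_loss", "train_acc", "val_loss", "val_acc", "lr"
        }

    def test_scores_sum_to_one_and_argmax_rule(self, tiny_fit):
        trained, lanes = tiny_fit
        records = hb.predict(trained, lanes[:10])
        for r in records:
            assert 0.0 <= r.score <= 1.0
            expected = ("thalassaemia" if r.score > 0.5 else "normal"
                        ) if r.score != 0.5 else r.predicted_label
            assert r.predicted_label == expected

    def test_duplicate_input_identical_scores(self, tiny_fit):
        trained, lanes = tiny_fit
        r = hb.predict(trained, [lanes[0], lanes[0]])
        assert r[0].score == r[1].score

    def test_batch_and_single_inference_agree(self, tiny_fit):
        trained, lanes = tiny_fit
        batch = hb.predict(trained, lanes[:10])
        singles = [hb.predict(trained, [ln])[0] for ln in lanes[:10]]
        for rb, rs in zip(batch, singles):
            assert rb.score == pytest.approx(rs.score, abs=1e-6)

    def test_model_roundtrip_through_disk(self, tiny_fit, tmp_path):
        trained, lanes = tiny_fit
        hb.save_model(trained, tmp_path / "m.npz")
        loaded = hb.load_model(tmp_path / "m.npz")
        a = hb.predict(trained, lanes[:5])
        b = hb.predict(loaded, lanes[:5])
        assert [r.score for r in a] == pytest.approx(
            [r.score for r in b], abs=1e-7
        )


class TestCrossValidate:
    def test_pooled_predictions_cover_each_retained_lane_once(
        self, clean_lanes
    ):
        lanes = clean_lanes[:40]
        res = hb.cross_validate(
            lanes, cfg=hb.TrainConfig(seed=3, max_epochs=2), k=5,
            val_per_class=2,
        )
        ids = [r.lane_id for r in res.records]
        assert len(ids) == len(set(ids))
        test_sets = [set(f.test_ids) for f in res.folds]
        for a in range(5):
            for b in range(a + 1, 5):
                assert not test_sets[a] & test_sets[b]
        n_norm = sum(ln.label == "normal" for ln in lanes)
        n_thal = len(lanes) - n_norm
        assert len(ids) == 5 * (n_norm // 5) + 5 * (n_thal // 5)

    def test_augmentation_applies_to_training_only(self, clean_lanes,
                                                   monkeypatch):
        """The 15x expansion happens after splitting and touches only
        training ids — no augmented image can reach val or test."""
        import hbscreen.classify as cls

        lanes = clean_lanes[:20]
        seen = {}

        real_fit = cls.fit

        def spy_fit(model, X_train, y_train, X_val, y_val, cfg):
            seen.setdefault("sizes", []).append(
                (X_train.shape[0], X_val.shape[0])
            )
            return real_fit(model, X_train, y_train, X_val, y_val, cfg)

        monkeypatch.setattr(cls, "fit", spy_fit)
        res = cls.cross_validate(
            lanes, cfg=hb.TrainConfig(seed=1, max_epochs=1), k=5,
            val_per_class=1, augment=hb.AugmentSpec(seed=0, n_variants=14),
        )
        n_norm = sum(ln.label == "normal" for ln in lanes)
        n_thal = len(lanes) - n_norm
        expected_train = sum(
            (n - n // 5 - 1) * 15 for n in (n_norm, n_thal)
        )
        for n_train, n_val in seen["sizes"]:
            assert n_train == expected_train
            assert n_val == 2 * 1
        assert len(res.records) == 5 * (n_norm // 5) + 5 * (n_thal // 5)

    def test_unknown_architecture_and_pretrained_guard(self):
        with pytest.raises(ParameterError):
            hb.ModelSpec(name="alexnet")
        with pytest.raises(ParameterError):
            hb.ModelSpec(name="tinycnn", pretrained=True)
        with pytest.raises(ParameterError):
            build_model(hb.ModelSpec(name="resnet18"))
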