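"""Classifier construction, staged fine-tuning, and checkpointing."""

import numpy as np
import pandas as pd
import pytest

from cxrgrade import _nn, splits, train


def test_build_classifier_validation():
    with pytest.raises(ValueError):
        train.build_classifier("alexnet")
    with pytest.raises(ValueError):
        train.OpacityClassifier("tiny", side="up")


@pytest.mark.parametrize("name,n_convs", [("tiny", 6), ("vgg16", 13),
                                          ("resnet50", 49), ("chexnet121", 120)])
def test_backbone_conv_counts(name, n_convs):
    model = train.build_classifier(name, input_size=64)
    assert model.backbone.total_conv_layers == n_convs
    assert len(model.conv_layers()) == n_convs


def test_forward_shapes_all_backbones():
    x = np.random.default_rng(0).random((2, 1, 64, 64)).astype(np.float32)
    for name in ("tiny", "vgg16"):
        model = train.build_classifier(name, input_size=64)
        logits = model.forward(x)
        assert logits.shape == (2, 4)
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_same_seed_same_initialization():
    a = train.build_classifier("tiny", seed=3, input_size=64)
    b = train.build_classifier("tiny", seed=3, input_size=64)
    for pa, pb in zip(a.params(), b.params()):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_freeze_then_unfreeze_last():
    model = train.build_classifier("tiny", input_size=64)
    assert all(not p.trainable for p in model.features.params())
    assert all(p.trainable for p in model.head.params())
    model.unfreeze_last(2)
    convs = model.conv_layers()
    for c in convs[:-2]:
        assert not c.compute_param_grads
        assert all(not p.trainable for p in c.params())
    for c in convs[-2:]:
        assert c.compute_param_grads
        assert all(p.trainable for p in c.params())


def test_schedule_validation():
    with pytest.raises(ValueError):
        train.TrainingSchedule(lr_stage1=-1.0)
    with pytest.raises(ValueError):
        train.TrainingSchedule(stage1_epochs_max=3, stage2_epochs_max=3,
                               lr_reduce_patience=3)


def test_fit_two_stage_requires_rows():
    model = train.build_classifier("tiny", input_size=64)
    empty = pd.DataFrame({"i": []})
    plan = splits.BalancedTrainingPlan(empty, empty,
                                       splits.BalancingScheme.UNDER,
                                       "left_grade")
    sched = train.TrainingSchedule(stage1_epochs_max=2, stage2_epochs_max=2,
                                   lr_reduce_patience=1)
    with pytest.raises(ValueError):
        train.fit_two_stage(model, plan, empty, sched, loader=lambda r: (None, None))


def test_history_records_both_stages(tiny_trained):
    _, history = tiny_trained
    assert len(history["stage1_train_loss"]) >= 1
    assert len(history["stage2_train_loss"]) >= 1
    assert history["stage1_best_val_loss"] < np.inf
    assert history["unfreeze_last_n"] == 6       # tiny fine-tunes fully
    for lr in history["stage1_lr"]:
        assert lr <= 1e-3 + 1e-12


def test_stage1_leaves_conv_weights_untouched(phantom_arrays):
    Xtr, ytr, _ = phantom_arrays["train"]
    Xv, yv, _ = phantom_arrays["val"]
    model = train.build_classifier("tiny", seed=1, input_size=64)
    before = [c.W.value.copy() for c in model.conv_layers()]
    plan = splits.BalancedTrainingPlan(
        pd.DataFrame({"i": range(len(ytr))}), pd.DataFrame({"i": []}),
        splits.BalancingScheme.UNDER, "left_grade")

    def loader(rows):
        return (Xtr, ytr) if len(rows) == len(ytr) else (Xv, yv)

    sched = train.TrainingSchedule(stage1_epochs_max=2, stage2_epochs_max=1,
                                   lr_reduce_patience=1, early_stop_patience=2,
                                   unfreeze_last_n=0, seed=1)
    train.fit_two_stage(model, plan, pd.DataFrame({"i": range(len(yv))}),
                        sched, loader=loader)
    after = [c.W.value for c in model.conv_layers()]
    for b, a in zip(before, after):
        np.testing.assert_array_equal(b, a)


def test_training_beats_chance_on_phantoms(tiny_trained, phantom_arrays):
    model, _ = tiny_trained
    Xte, yte, _ = phantom_arrays["test"]
    _, grades = train.predict(model, Xte)
    acc = (grades == yte).mean()
    assert acc > 0.4        # far above the 0.25 chance level


def test_predict_shapes_and_validation(tiny_trained):
    model, _ = tiny_trained
    X = np.random.default_rng(0).random((5, 1, 64, 64)).astype(np.float32)
    probs, grades = train.predict(model, X)
    assert probs.shape == (5, 4)
    assert grades.shape == (5,)
    assert set(grades) <= {0, 1, 2, 3}
    probs2, _ = train.predict(model, X[:, 0])     # (n, H, W) accepted
    np.testing.assert_array_equal(probs, probs2)
    with pytest.raises(ValueError):
        train.predict(model, np.zeros((5, 3, 64, 64), np.float32))


def test_save_load_round_trip(tiny_trained, tmp_path):
    model, _ = tiny_trained
    path = tmp_path / "clf"
    train.save_classifier(model, path, extra={"note": "unit"})
    back = train.load_classifier(path)
    X = np.random.default_rng(1).random((3, 1, 64, 64)).astype(np.float32)
    np.testing.assert_array_equal(back.predict_proba(X),
                                  model.predict_proba(X))
    assert back.backbone.name == "tiny"
    assert back.side == model.side


def test_default_loader_applies_stored_augmentation(clean_cohort):
    rows = clean_cohort.head(2).copy()
    rows["synthetic"] = [False, True]
    rows["aug"] = [None,
                   '{"rotation_deg": 0.0, "scale": 1.0, '
                   '"tx_frac": 0.05, "ty_frac": 0.0}']
    X, y = train.default_loader(rows, "left_grade", input_size=64)
    assert X.shape == (2, 1, 64, 64)
    assert y.shape == (2,)
    plain, _ = train.default_loader(rows.assign(synthetic=False), "left_grade",
                                    input_size=64)
    np.testing.assert_array_equal(X[0], plain[0])
    assert np.abs(X[1] - plain[1]).max() > 0


def test_adam_weight_decay_shrinks_matrices_not_biases():
    rng = np.random.default_rng(0)
    d = _nn.Dense(4, 4, rng=rng, name="d")
    w0 = np.abs(d.W.value).sum()
    opt = _nn.Adam(d.params(), lr=0.0, weight_decay=1.0)
    b0 = d.b.value.copy()
    opt.zero_grad()
    opt.step()
    # lr = 0 makes the gradient step vanish; any change is pure decay
    assert np.abs(d.W.value).sum() == w0     # decay scales with lr
    opt.lr = 0.01
    opt.zero_grad()
    opt.step()
    assert np.abs(d.W.value).sum() < w0
    np.testing.assert_array_equal(d.b.value, b0)
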