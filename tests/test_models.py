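"""Model family: declared architectures, parameter counting, training laws."""

import numpy as np
import pytest

from actigate import _nn
from actigate import models as mdl


def _kinds(spec, exclude=("dropout",)):
    return [l.kind for l in spec.layers if l.kind not in exclude]


def test_fcn3_layer_sequence():
    spec = mdl.build_spec("FCN-III")
    assert _kinds(spec) == [
        "conv", "conv", "pool", "conv", "conv", "pool", "conv", "gap", "softmax",
    ]
    filters = [l.filters for l in spec.layers if l.kind == "conv"]
    assert filters == [32, 32, 64, 64, 6]


def test_fcn1_and_fcn4_conv_stacks():
    f1 = [l.filters for l in mdl.build_spec("FCN-I").layers if l.kind == "conv"]
    assert f1 == [16, 16, 32, 6]
    f4 = [l.filters for l in mdl.build_spec("FCN-IV").layers if l.kind == "conv"]
    assert f4 == [32, 32, 32, 64, 64, 6]


def test_cnn_is_fcn3_front_plus_two_dense_256():
    spec = mdl.build_spec("CNN")
    assert _kinds(spec) == [
        "conv", "conv", "pool", "conv", "conv", "pool",
        "flatten", "dense", "dense", "dense", "softmax",
    ]
    dense = [l.units for l in spec.layers if l.kind == "dense"]
    assert dense == [256, 256, 6]
    # shared convolutional front is identical to FCN-III's
    front = [l for l in spec.layers if l.kind in ("conv", "pool")][:6]
    fcn_front = [l for l in mdl.build_spec("FCN-III").layers if l.kind in ("conv", "pool")][:6]
    assert front == fcn_front


def test_unknown_variant_error_lists_valid_names():
    with pytest.raises(ValueError, match="FCN-I.*CNN"):
        mdl.build_spec("FCN-V")


def test_cnn_parameter_count():
    assert mdl.count_parameters(mdl.build_spec("CNN")) == 820_710


def test_single_conv_16_parameter_count():
    spec = mdl.ModelSpec(variant="x", layers=(mdl.LayerDef("conv", filters=16),))
    assert mdl.count_parameters(spec) == 160  # 16 * (9 * 1 + 1)


def test_fcn3_parameter_count_closed_form():
    # 320 + 9,248 + 18,496 + 36,928 + 3,462
    assert mdl.count_parameters(mdl.build_spec("FCN-III")) == 68_454


def test_shared_front_parameter_count():
    fcn = mdl.build_spec("FCN-III")
    front = mdl.ModelSpec(variant="front", layers=tuple(fcn.layers[:6]))
    assert mdl.count_parameters(front) == 64_992


@pytest.mark.parametrize("variant", mdl.VARIANTS)
def test_built_network_matches_closed_form_count(variant):
    spec = mdl.build_spec(variant)
    net = mdl.build_network(spec, seed=0)
    assert net.n_params == mdl.count_parameters(spec)


def test_gap_logits_length_and_softmax_normalisation():
    spec = mdl.build_spec("FCN-II")
    net = mdl.build_network(spec, seed=1)
    x = np.random.default_rng(0).normal(size=(3, 30, 24, 1)).astype(np.float32)
    logits = net.forward(x)
    assert logits.shape == (3, 6)
    probs = _nn.softmax(logits)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_train_rejects_empty_and_single_class_data():
    spec = mdl.build_spec("FCN-I")
    with pytest.raises(ValueError):
        mdl.train(spec, np.empty((0, 30, 24, 1)), [])
    imgs = np.zeros((10, 30, 24, 1), dtype=np.float32)
    with pytest.raises(ValueError, match="two classes"):
        mdl.train(spec, imgs, ["sitting"] * 10)


def test_training_separates_noiseless_activities():
    """Noiseless default profiles are separable: a small FCN reaches >=95%
    training accuracy on a 6-class, 100-windows-per-class set within 100
    epochs."""
    from dataclasses import replace

    import actigate as ag
    from actigate.encoding import ChannelStats, encode_windows, stack_channels

    quiet = {
        k: replace(v, noise_sd=0.0, amplitude_cv=0.0, fidget_rate=0.0)
        for k, v in ag.default_profiles().items()
    }
    windows = []
    for i, label in enumerate(sorted(quiet)):
        sched = ag.ActivitySchedule(
            entries=((label, 230.0),), subject_id=f"s{i}", seed=50 + i
        )
        windows.extend(ag.segment_run(ag.generate_stream(sched, quiet).runs[0])[:100])
    stats = ChannelStats.fit([stack_channels(w) for w in windows])
    images = encode_windows(windows, stats)
    labels = np.array([w.true_label for w in windows])
    cfg = mdl.TrainingConfig(max_epochs=100, patience=20, seed=0)
    model = mdl.train(mdl.build_spec("FCN-I"), images, labels, cfg, stats=stats)
    train_acc = (model.predict_labels(images) == labels).mean()
    assert train_acc >= 0.95
    assert len(model.history) <= 100


def test_early_stopping_halts_when_validation_stops_improving():
    """Unlearnable labels make validation loss rise; training halts early and
    the restored weights correspond to the best validation epoch."""
    rng = np.random.default_rng(6)
    images = rng.normal(size=(80, 30, 24, 1)).astype(np.float32)
    labels = rng.choice(["a", "b"], size=80)  # no signal: the net can only overfit
    cfg = mdl.TrainingConfig(learning_rate=1e-3, max_epochs=80, patience=3, seed=0)
    model = mdl.train(mdl.build_spec("FCN-I"), images, labels, cfg)
    assert len(model.history) < 80
    best = model.history["val_loss"].idxmin()
    assert len(model.history) - 1 - best >= cfg.patience


def test_cross_validation_partition_laws():
    rng = np.random.default_rng(7)
    images = rng.normal(size=(100, 30, 24, 1)).astype(np.float32)
    labels = np.array((["a"] * 50) + (["b"] * 50))
    from sklearn.model_selection import KFold

    cfg = mdl.TrainingConfig(seed=5)
    kf = KFold(n_splits=10, shuffle=True, random_state=cfg.seed)
    test_folds = [te for _, te in kf.split(images)]
    sizes = [len(te) for te in test_folds]
    assert max(sizes) - min(sizes) <= 1
    all_tested = np.concatenate(test_folds)
    assert sorted(all_tested) == list(range(100))  # each sample tested exactly once
    # fold assignment depends only on the seed
    again = [te for _, te in KFold(10, shuffle=True, random_state=cfg.seed).split(images)]
    for a, b in zip(test_folds, again):
        np.testing.assert_array_equal(a, b)


def test_cross_validate_returns_k_fold_accuracies():
    rng = np.random.default_rng(8)
    images = rng.normal(size=(40, 30, 24, 1)).astype(np.float32)
    labels = np.array(["a", "b"] * 20)
    images[labels == "b", :, :, 0] += 2.0
    cfg = mdl.TrainingConfig(max_epochs=2, patience=1, seed=0)
    result = mdl.cross_validate(mdl.build_spec("FCN-I"), images, labels, k=4, config=cfg)
    assert len(result.fold_accuracies) == 4
    assert 0.0 <= result.mean <= 1.0
    with pytest.raises(ValueError):
        mdl.cross_validate(mdl.build_spec("FCN-I"), images, labels, k=1, config=cfg)


def test_save_and_load_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    images = rng.normal(size=(30, 30, 24, 1)).astype(np.float32)
    labels = np.array(["a", "b", "c"] * 10)
    cfg = mdl.TrainingConfig(max_epochs=2, patience=1, seed=0)
    model = mdl.train(mdl.build_spec("FCN-I"), images, labels, cfg)
    path = tmp_path / "model.npz"
    mdl.save_model(model, path)
    loaded = mdl.load_model(path)
    np.testing.assert_array_equal(
        model.predict_labels(images), loaded.predict_labels(images)
    )


def test_describe_prints_layers_and_count():
    text = mdl.describe(mdl.build_spec("CNN"))
    assert "820,710" in text
    assert "Dense 256" in text
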