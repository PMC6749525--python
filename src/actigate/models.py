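"""The FCN-I..IV family and the baseline CNN: declaration, parameter
counting, building, training and cross-validation.

All variants consume a 30×24 single-channel image and emit 6 class scores.
The FCN variants are fully convolutional: stacks of 3×3 ReLU convolutions and
2×2 max-pooling layers ending in a 6-filter convolution whose feature maps
are reduced by global average pooling (GAP) directly to the class logits —
no dense layers, so the parameter count stays small. The baseline CNN shares
the FCN-III convolutional front but replaces the final convolution and GAP
with two 256-unit fully connected layers, which is where almost all of its
~821k parameters live.

Architectural conventions (frozen here so that the closed-form parameter
counter, the built networks, and any saved checkpoints agree): convolutions
use 'same' padding with biases; 2×2 pooling floors odd spatial dimensions
(30×24 → 15×12 → 7×6); dropout 0.25 sits immediately before the final
convolution in the FCNs and dropout 0.5 follows each dense layer in the CNN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from actigate import _nn
from actigate.encoding import IMAGE_HEIGHT, IMAGE_WIDTH, ChannelStats

N_CLASSES = 6

VARIANTS = ("FCN-I", "FCN-II", "FCN-III", "FCN-IV", "CNN")


@dataclass(frozen=True)
class LayerDef:
    """One declarative layer: conv/pool/gap/flatten/dense/dropout/softmax."""

    kind: str
    filters: int | None = None
    kernel: int = 3
    units: int | None = None
    rate: float | None = None
    size: int = 2
    relu: bool = True


def _conv(f: int) -> LayerDef:
    return LayerDef("conv", filters=f)


def _pool() -> LayerDef:
    return LayerDef("pool")


def _dense(u: int, relu: bool = True) -> LayerDef:
    return LayerDef("dense", units=u, relu=relu)


def _dropout(r: float) -> LayerDef:
    return LayerDef("dropout", rate=r)


@dataclass(frozen=True)
class ModelSpec:
    variant: str
    layers: tuple[LayerDef, ...]
    input_shape: tuple[int, int, int] = (IMAGE_HEIGHT, IMAGE_WIDTH, 1)
    n_classes: int = N_CLASSES


_FCN_BODIES: dict[str, list[LayerDef]] = {
    "FCN-I": [_conv(16), _conv(16), _pool(), _conv(32), _pool()],
    "FCN-II": [_conv(32), _conv(32), _pool(), _conv(64), _pool()],
    "FCN-III": [_conv(32), _conv(32), _pool(), _conv(64), _conv(64), _pool()],
    "FCN-IV": [_conv(32), _conv(32), _conv(32), _pool(), _conv(64), _conv(64), _pool()],
}


def build_spec(variant: str) -> ModelSpec:
    """Declarative layer list for one model variant."""
    if variant in _FCN_BODIES:
        layers = (
            *_FCN_BODIES[variant],
            _dropout(0.25),
            _conv(N_CLASSES),
            LayerDef("gap"),
            LayerDef("softmax"),
        )
    elif variant == "CNN":
        layers = (
            *_FCN_BODIES["FCN-III"],
            LayerDef("flatten"),
            _dense(256),
            _dropout(0.5),
            _dense(256),
            _dropout(0.5),
            _dense(N_CLASSES, relu=False),
            LayerDef("softmax"),
        )
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return ModelSpec(variant=variant, layers=layers)


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter count.

    conv: filters × (kernel² × in_channels + 1); dense: in × out + out;
    pooling, GAP, dropout and the softmax activation contribute nothing.
    Spatial dimensions are tracked through 'same' convolutions and
    floor-division pooling so the CNN's flatten size is exact.
    """
    h, w, c = spec.input_shape
    units = None  # set once the net goes 1-D
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv":
            total += layer.filters * (layer.kernel**2 * c + 1)
            c = layer.filters
        elif layer.kind == "pool":
            h, w = h // layer.size, w // layer.size
        elif layer.kind == "gap":
            units = c
        elif layer.kind == "flatten":
            units = h * w * c
        elif layer.kind == "dense":
            total += units * layer.units + layer.units
            units = layer.units
        elif layer.kind in ("dropout", "softmax"):
            pass
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return total


def build_network(spec: ModelSpec, seed: int = 0) -> _nn.Network:
    """Instantiate a trainable network from a spec (seeded initialisation)."""
    rng = np.random.default_rng(seed)
    h, w, c = spec.input_shape
    units = None
    layers: list[_nn.Layer] = []
    for layer in spec.layers:
        if layer.kind == "conv":
            layers.append(_nn.Conv2D(c, layer.filters, kernel=layer.kernel, relu=True, rng=rng))
            c = layer.filters
        elif layer.kind == "pool":
            layers.append(_nn.MaxPool2D(layer.size))
            h, w = h // layer.size, w // layer.size
        elif layer.kind == "gap":
            layers.append(_nn.GlobalAvgPool())
            units = c
        elif layer.kind == "flatten":
            layers.append(_nn.Flatten())
            units = h * w * c
        elif layer.kind == "dense":
            layers.append(_nn.Dense(units, layer.units, relu=layer.relu, rng=rng))
            units = layer.units
        elif layer.kind == "dropout":
            layers.append(_nn.Dropout(layer.rate, rng=rng))
        elif layer.kind == "softmax":
            pass  # handled by the softmax cross-entropy loss / predict_proba
    return _nn.Network(layers)


def _resize_output(spec: ModelSpec, k: int) -> ModelSpec:
    """Shrink the class-score layer when fewer than 6 classes are present."""
    if k == spec.n_classes:
        return spec
    layers = list(spec.layers)
    for i in range(len(layers) - 1, -1, -1):
        if layers[i].kind == "conv":
            layers[i] = replace(layers[i], filters=k)
            break
        if layers[i].kind == "dense":
            layers[i] = replace(layers[i], units=k)
            break
    return replace(spec, layers=tuple(layers), n_classes=k)


@dataclass
class TrainingConfig:
    """Training protocol: Adam with a constant learning rate, mini-batches of
    32, at most 400 epochs with early stopping on validation loss."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 400
    patience: int = 20
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("max_epochs, batch_size and patience must be >= 1")


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reuse it consistently."""

    spec: ModelSpec
    network: _nn.Network
    classes: np.ndarray  # index -> label
    stats: ChannelStats | None = None
    history: pd.DataFrame | None = None

    def predict_indices(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict(images)

    def predict_labels(self, images: np.ndarray) -> np.ndarray:
        return self.classes[self.network.predict(images)]


def _encode_labels(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    return classes, y  # classes sorted => alphabetical index mapping


def train(
    spec: ModelSpec,
    images: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    config: TrainingConfig | None = None,
    stats: ChannelStats | None = None,
) -> TrainedModel:
    """Train one model on encoded images.

    ``images`` is (n, 30, 24, 1); ``labels`` are activity names (encoded
    alphabetically) or already-encoded integer indices. A seeded 10% split
    serves as validation data; training halts when validation loss has not
    improved for ``patience`` epochs and the best weights are restored.
    """
    config = config or TrainingConfig()
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    if len(images) == 0:
        raise ValueError("cannot train on an empty dataset")
    if images.shape[1:3] != spec.input_shape[:2]:
        raise ValueError(
            f"images are {images.shape[1:3]}, model expects {spec.input_shape[:2]}"
        )
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        y = labels.astype(np.int64)
        classes = np.arange(spec.n_classes)
    else:
        classes, y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least two classes present")
    spec = _resize_output(spec, len(classes))

    rng = np.random.default_rng(config.seed)
    net = build_network(spec, seed=config.seed)
    order = rng.permutation(len(images))
    n_val = max(1, int(round(config.validation_fraction * len(images))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("dataset too small for the validation split")
    x_tr, y_tr = images[tr_idx], y[tr_idx]
    x_val, y_val = images[val_idx], y[val_idx]

    opt = _nn.Adam(net.parameters, lr=config.learning_rate)
    best_loss, best_weights, best_epoch = np.inf, net.get_weights(), -1
    records = []
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(perm), config.batch_size):
            batch = perm[i : i + config.batch_size]
            losses.append(net.loss_and_grad(x_tr[batch], y_tr[batch]))
            opt.step(net.gradients)
        val_loss = net.evaluate_loss(x_val, y_val)
        val_acc = float((net.predict(x_val) == y_val).mean())
        records.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, best_epoch = val_loss, net.get_weights(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    net.set_weights(best_weights)
    return TrainedModel(
        spec=spec,
        network=net,
        classes=classes,
        stats=stats,
        history=pd.DataFrame.from_records(records),
    )


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean: float
    sd: float


def cross_validate(
    spec: ModelSpec,
    images: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    k: int = 10,
    config: TrainingConfig | None = None,
) -> CVResult:
    """k-fold cross-validation with a random (window-level) partition.

    Folds are shuffled with the config seed, sized within one sample of each
    other, and each sample is tested exactly once. The partition is at window
    level, not subject level, so windows of one subject can appear in both
    train and test folds — a deliberate convention whose leakage caveat is
    documented rather than corrected.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    config = config or TrainingConfig()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if len(images) < k:
        raise ValueError(f"need at least k={k} samples, got {len(images)}")
    accs = []
    kf = KFold(n_splits=k, shuffle=True, random_state=config.seed)
    for fold, (tr, te) in enumerate(kf.split(images)):
        model = train(spec, images[tr], labels[tr], replace(config, seed=config.seed + fold))
        pred = model.predict_labels(images[te])
        truth = model.classes[labels[te]] if labels.dtype.kind in "iu" else labels[te]
        accs.append(float((pred == truth).mean()))
    accs = np.asarray(accs)
    return CVResult(fold_accuracies=accs, mean=float(accs.mean()), sd=float(accs.std(ddof=1)))


def describe(spec: ModelSpec) -> str:
    """Human-readable layer table with the closed-form parameter count."""
    lines = [f"{spec.variant}  (input {spec.input_shape[0]}x{spec.input_shape[1]}x{spec.input_shape[2]})"]
    for i, layer in enumerate(spec.layers, start=1):
        if layer.kind == "conv":
            desc = f"Conv {layer.filters}@({layer.kernel}x{layer.kernel}), ReLU, same"
        elif layer.kind == "pool":
            desc = f"MaxPool ({layer.size}x{layer.size})"
        elif layer.kind == "gap":
            desc = "GlobalAvgPool"
        elif layer.kind == "flatten":
            desc = "Flatten"
        elif layer.kind == "dense":
            desc = f"Dense {layer.units}" + (", ReLU" if layer.relu else "")
        elif layer.kind == "dropout":
            desc = f"Dropout {layer.rate}"
        else:
            desc = "Softmax"
        lines.append(f"  {i:2d}. {desc}")
    lines.append(f"  trainable parameters: {count_parameters(spec):,}")
    return "\n".join(lines)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise a trained model (weights + spec + classes) to ``.npz``."""
    path = Path(path)
    meta = {
        "variant": model.spec.variant,
        "n_classes": model.spec.n_classes,
        "classes": [str(c) for c in model.classes],
        "has_stats": model.stats is not None,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.network.get_weights())}
    if model.stats is not None:
        arrays["stats_mean"] = model.stats.mean
        arrays["stats_sd"] = model.stats.sd
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    spec = _resize_output(build_spec(meta["variant"]), meta.get("n_classes", N_CLASSES))
    net = build_network(spec)
    weights = [data[f"w{i}"] for i in range(len(net.parameters))]
    net.set_weights(weights)
    stats = None
    if meta["has_stats"]:
        stats = ChannelStats(mean=data["stats_mean"], sd=data["stats_sd"])
    return TrainedModel(
        spec=spec, network=net, classes=np.asarray(meta["classes"]), stats=stats
    )
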