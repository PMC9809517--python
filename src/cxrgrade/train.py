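"""Per-lung ordinal classifiers and the two-stage transfer-learning protocol.

Each classifier is a convolutional backbone with a fresh fully connected
head producing softmax probabilities over the four opacity grades.  Training
is staged:

1. all convolutional layers frozen, the head fine-tuned at a learning rate
   of 1e-3 on the (balanced) stage-1 rows;
2. the last N convolutional layers unfrozen (N = T - 5 by default, with T
   the backbone's total convolutional layer count; per-backbone overrides
   supported) and fine-tuned at 1e-4, on the full unbalanced set under
   double-stage sampling or the stage-1 rows otherwise.

Both stages run Adam with batch size 32, automated learning-rate reduction
on a stalled validation loss (patience 7, factor 0.1), early stopping
(patience 10), and restoration of the best-validation-loss weights.

Named backbones (``resnet50``, ``vgg16``, ``chexnet121``) are compact-width
random-initialised variants with the canonical convolutional layer counts,
so the freeze/unfreeze arithmetic is faithful; pretrained weights are never
downloaded.  The six-conv ``tiny`` backbone is the fast test vehicle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import _nn
from .segment import normalize_for_net
from .splits import BalancedTrainingPlan, BalancingScheme, augment_image

__all__ = [
    "BackboneSpec",
    "BACKBONES",
    "DISCUSSION_UNFREEZE_OVERRIDES",
    "TrainingSchedule",
    "OpacityClassifier",
    "TrainingFailure",
    "build_classifier",
    "fit_two_stage",
    "predict",
    "default_loader",
    "save_classifier",
    "load_classifier",
]


class TrainingFailure(RuntimeError):
    """Non-finite loss during training; carries the epoch index."""

    def __init__(self, epoch: int, stage: int) -> None:
        super().__init__(f"non-finite loss at stage {stage}, epoch {epoch}")
        self.epoch = epoch
        self.stage = stage


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    name: str
    total_conv_layers: int
    pretrained: bool = False


#: alternative unfreeze depths reported for the full-scale study
DISCUSSION_UNFREEZE_OVERRIDES = {"resnet50": 5, "vgg16": 5, "chexnet121": 15}

#: stage-2 unfreeze depth used when the schedule leaves it unset; backbones
#: absent from this map follow the generic T - 5 rule
DEFAULT_UNFREEZE = {"tiny": 6}


def _build_tiny(rng, cin):
    # A coordinate ramp channel makes side-selective channels learnable
    # under the global-average-pooled head this backbone uses.
    cfg = [(8, 2), (8, 2), (16, 2), (16, 2), (32, 2), (32, 1)]
    layers = [_nn.CoordChannel()]
    c = cin + 1
    for i, (w, s) in enumerate(cfg):
        layers += [_nn.Conv2d(c, w, stride=s, rng=rng, name=f"conv{i}"), _nn.ReLU()]
        c = w
    return _nn.Sequential(layers), c


def _build_vgg16(rng, cin):
    blocks = [(2, 8), (2, 16), (3, 16), (3, 32), (3, 32)]
    layers = []
    c = cin
    i = 0
    for n, w in blocks:
        for _ in range(n):
            layers += [_nn.Conv2d(c, w, rng=rng, name=f"conv{i}"), _nn.ReLU()]
            c = w
            i += 1
        layers.append(_nn.MaxPool2())
    return _nn.Sequential(layers), c


def _build_resnet50(rng, cin):
    def bottleneck(c_in, mid, c_out, stride, tag):
        body = _nn.Sequential([
            _nn.Conv2d(c_in, mid, k=1, rng=rng, name=f"{tag}.a"), _nn.ReLU(),
            _nn.Conv2d(mid, mid, k=3, stride=stride, rng=rng, name=f"{tag}.b"), _nn.ReLU(),
            _nn.Conv2d(mid, c_out, k=1, rng=rng, name=f"{tag}.c"),
        ])
        short = None
        if stride != 1 or c_in != c_out:
            short = _nn.Conv2d(c_in, c_out, k=1, stride=stride, rng=rng,
                               counted=False, name=f"{tag}.proj")
        return _nn.Sequential([_nn.Residual(body, short), _nn.ReLU()])

    layers = [_nn.Conv2d(cin, 8, k=7, stride=2, pad=3, rng=rng, name="stem"),
              _nn.ReLU(), _nn.MaxPool2()]
    c = 8
    stage_cfg = [(3, 8, 32, 1), (4, 16, 64, 2), (6, 32, 128, 2), (3, 32, 128, 2)]
    for s_idx, (n, mid, out, stride) in enumerate(stage_cfg):
        for b in range(n):
            layers.append(bottleneck(c, mid, out, stride if b == 0 else 1,
                                     f"s{s_idx}b{b}"))
            c = out
    return _nn.Sequential(layers), c


def _build_chexnet121(rng, cin):
    growth = 4
    layers = [_nn.Conv2d(cin, 2 * growth, k=7, stride=2, pad=3, rng=rng,
                         name="stem"), _nn.ReLU(), _nn.MaxPool2()]
    c = 2 * growth
    for s_idx, n in enumerate((6, 12, 24, 16)):
        block = _nn.DenseBlock(c, n, growth, rng=rng, name=f"db{s_idx}")
        layers.append(block)
        c = block.cout
        if s_idx < 3:
            layers += [_nn.ReLU(),
                       _nn.Conv2d(c, c // 2, k=1, rng=rng, name=f"trans{s_idx}"),
                       _nn.MaxPool2()]
            c = c // 2
    layers.append(_nn.ReLU())
    return _nn.Sequential(layers), c


BACKBONES = {
    "tiny": _build_tiny,
    "vgg16": _build_vgg16,
    "resnet50": _build_resnet50,
    "chexnet121": _build_chexnet121,
}


class OpacityClassifier:
    """Backbone + fully connected head -> 4-class softmax, one lung side."""

    def __init__(self, backbone_name: str, side: str = "left", seed: int = 0,
                 in_channels: int = 1, input_size: int = 224,
                 config: dict | None = None) -> None:
        if backbone_name not in BACKBONES:
            raise ValueError(f"unknown backbone: {backbone_name!r}")
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        rng = np.random.default_rng(seed)
        self.features, feat_c = BACKBONES[backbone_name](rng, in_channels)
        # The VGG backbone flattens its final feature map, as the original
        # does; the others pool globally.  The globally pooled backbones get
        # laterality from channel semantics (tiny injects a coordinate ramp
        # so such channels exist), which also keeps Grad-CAM's pooled-gradient
        # weighting faithful to the decision.
        if backbone_name == "vgg16":
            self.gap = _nn.Flatten()
            probe = np.zeros((1, in_channels, input_size, input_size),
                             dtype=np.float32)
            head_in = self.gap.forward(self.features.forward(probe)).shape[1]
        else:
            self.gap = _nn.GlobalAvgPool()
            head_in = feat_c
        self.head = _nn.Sequential([
            _nn.BatchScale(),
            _nn.Dense(head_in, 32, rng=rng, name="fc1"), _nn.ReLU(),
            _nn.Dense(32, 4, rng=rng, name="fc2"),
        ])
        self.side = side
        self.in_channels = in_channels
        self.input_size = input_size
        self.seed = seed
        self.config = dict(config or {})
        self.backbone = BackboneSpec(backbone_name,
                                     len(list(_nn.iter_convs(self.features))))
        self.freeze_all_convs()

    # -- structure -----------------------------------------------------
    def conv_layers(self) -> list[_nn.Conv2d]:
        return list(_nn.iter_convs(self.features))

    @property
    def last_conv(self) -> _nn.Conv2d:
        return self.conv_layers()[-1]

    def params(self) -> list[_nn.Param]:
        return self.features.params() + self.head.params()

    def trainable_params(self) -> list[_nn.Param]:
        return [p for p in self.params() if p.trainable]

    def freeze_all_convs(self) -> None:
        for p in self.features.params():
            p.trainable = False
        for conv in _nn.iter_convs(self.features, include_shortcut=True):
            conv.compute_param_grads = False
        for p in self.head.params():
            p.trainable = True

    def unfreeze_last(self, n: int) -> None:
        """Unfreeze the last ``n`` counted convolutional layers; a shortcut
        projection is unfrozen along with its residual block's body."""
        convs = self.conv_layers()
        chosen = set(id(c) for c in convs[max(len(convs) - n, 0):])

        def visit(layer):
            if isinstance(layer, _nn.Conv2d):
                if layer.counted:
                    on = id(layer) in chosen
                    layer.compute_param_grads = on
                    for p in layer.params():
                        p.trainable = on
            elif isinstance(layer, _nn.Sequential):
                for l in layer.layers:
                    visit(l)
            elif isinstance(layer, _nn.Residual):
                visit(layer.body)
                if layer.shortcut is not None:
                    on = any(id(c) in chosen
                             for c in _nn.iter_convs(layer.body))
                    layer.shortcut.compute_param_grads = on
                    for p in layer.shortcut.params():
                        p.trainable = on
            elif isinstance(layer, _nn.DenseBlock):
                for s in layer.sub:
                    visit(s)

        visit(self.features)

    # -- forward / predict ---------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.gap.forward(self.features.forward(x)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.forward(x))

    def backward_from_logits(self, dlogits: np.ndarray,
                             through_features: bool = True) -> None:
        d = self.head.backward(dlogits)
        if through_features:
            self.features.backward(self.gap.backward(d))

    def state_dict(self) -> dict:
        return {p.name + f"#{i}": p.value.copy()
                for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[p.name + f"#{i}"]


def build_classifier(backbone: str | BackboneSpec, side: str = "left",
                     seed: int = 0, input_size: int = 224,
                     config: dict | None = None) -> OpacityClassifier:
    name = backbone.name if isinstance(backbone, BackboneSpec) else backbone
    return OpacityClassifier(name, side=side, seed=seed,
                             input_size=input_size, config=config)


@dataclasses.dataclass
class TrainingSchedule:
    stage1_epochs_max: int = 20
    stage2_epochs_max: int = 20
    batch_size: int = 32
    lr_stage1: float = 1e-3
    lr_stage2: float = 1e-4
    lr_reduce_patience: int = 7
    lr_reduce_factor: float = 0.1
    min_lr: float = 1e-6
    early_stop_patience: int = 10
    unfreeze_last_n: int | None = None  # None -> per-backbone default
    weight_decay: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.lr_stage1 <= 0 or self.lr_stage2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.lr_reduce_patience >= max(self.stage1_epochs_max,
                                          self.stage2_epochs_max):
            raise ValueError("lr_reduce_patience must be below the epoch maxima")


def default_loader(rows: pd.DataFrame, label_column: str, input_size: int = 224,
                   channels: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Read images from ``image_path``, apply stored augmentations to
    synthetic rows, and normalize for the network."""
    xs, ys = [], []
    for _, row in rows.iterrows():
        img = np.asarray(Image.open(row["image_path"]).convert("L"))
        img = img.astype(np.float32) / 255.0
        if bool(row.get("synthetic", False)) and row.get("aug"):
            img = augment_image(img, json.loads(row["aug"]))
        xs.append(normalize_for_net(img, size=input_size, channels=channels))
        ys.append(int(row[label_column]))
    return np.stack(xs), np.asarray(ys, dtype=int)


def _val_loss(model, head_input, y) -> float:
    probs = _nn.softmax(model.head.forward(head_input))
    return _nn.cross_entropy(probs, y)


def _split_frozen_prefix(model: OpacityClassifier):
    """Longest leading run of feature layers with no trainable params."""
    cut = 0
    for i, layer in enumerate(model.features.layers):
        if any(p.trainable for p in layer.params()):
            break
        cut = i + 1
    prefix = _nn.Sequential(model.features.layers[:cut])
    suffix = _nn.Sequential(model.features.layers[cut:])
    return prefix, suffix


def _run_stage(model: OpacityClassifier, X, y, Xv, yv, epochs: int, lr: float,
               schedule: TrainingSchedule, stage: int, rng, history: dict) -> None:
    prefix, suffix = _split_frozen_prefix(model)

    def feats_of(data, chunk=64):
        outs = [prefix.forward(data[i:i + chunk]) for i in range(0, len(data), chunk)]
        return np.concatenate(outs) if outs else data

    Xf = feats_of(X)
    Xvf = feats_of(Xv)

    def head_pass(xf):
        return model.head.forward(model.gap.forward(suffix.forward(xf)))

    opt = _nn.Adam(model.trainable_params(), lr=lr,
                   weight_decay=schedule.weight_decay)
    best_loss = np.inf
    best_state = model.state_dict()
    stall = 0
    n = len(Xf)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, schedule.batch_size):
            idx = order[s:s + schedule.batch_size]
            probs = _nn.softmax(head_pass(Xf[idx]))
            loss = _nn.cross_entropy(probs, y[idx])
            if not np.isfinite(loss):
                raise TrainingFailure(epoch, stage)
            losses.append(loss)
            d = _nn.cross_entropy_grad(probs, y[idx]).astype(np.float32)
            opt.zero_grad()
            d = model.head.backward(d)
            if suffix.layers and any(p.trainable for p in suffix.params()):
                suffix.backward(model.gap.backward(d))
            opt.step()
        # validation in chunks
        vlosses = []
        for s in range(0, len(Xvf), 256):
            probs = _nn.softmax(head_pass(Xvf[s:s + 256]))
            vlosses.append(_nn.cross_entropy(probs, yv[s:s + 256])
                           * len(yv[s:s + 256]))
        vloss = float(np.sum(vlosses) / len(yv))
        history[f"stage{stage}_train_loss"].append(float(np.mean(losses)))
        history[f"stage{stage}_val_loss"].append(vloss)
        history[f"stage{stage}_lr"].append(opt.lr)
        if vloss < best_loss - 1e-6:
            best_loss = vloss
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= schedule.early_stop_patience:
                break
            if stall and stall % schedule.lr_reduce_patience == 0:
                opt.lr = max(opt.lr * schedule.lr_reduce_factor, schedule.min_lr)
    model.load_state_dict(best_state)
    history[f"stage{stage}_best_val_loss"] = best_loss


def fit_two_stage(model: OpacityClassifier, plan: BalancedTrainingPlan,
                  val_rows: pd.DataFrame, schedule: TrainingSchedule,
                  loader=None) -> tuple[OpacityClassifier, dict]:
    """Run the staged fine-tuning protocol.

    ``loader`` converts manifest rows to (images, labels); it defaults to
    reading PNGs from ``image_path`` (with stored augmentations applied to
    synthetic rows).  Stage 2 uses the plan's stage-2 rows under
    double-stage sampling and the stage-1 rows otherwise, with a fresh
    optimizer at the stage-2 learning rate.
    """
    if loader is None:
        loader = lambda rows: default_loader(rows, plan.label_column,
                                             model.input_size, model.in_channels)
    if len(plan.stage1_rows) == 0:
        raise ValueError("empty stage-1 rows")
    if len(val_rows) == 0:
        raise ValueError("empty validation rows")
    X1, y1 = loader(plan.stage1_rows)
    Xv, yv = loader(val_rows)
    rng = np.random.default_rng(schedule.seed)
    history = {f"stage{s}_{k}": [] for s in (1, 2)
               for k in ("train_loss", "val_loss", "lr")}

    model.freeze_all_convs()
    _run_stage(model, X1, y1, Xv, yv, schedule.stage1_epochs_max,
               schedule.lr_stage1, schedule, 1, rng, history)

    n_unfreeze = schedule.unfreeze_last_n
    if n_unfreeze is None:
        # T - 5 protects pretrained features; the from-scratch tiny backbone
        # has none to protect, so its whole stack is fine-tuned in stage 2.
        n_unfreeze = DEFAULT_UNFREEZE.get(
            model.backbone.name, max(model.backbone.total_conv_layers - 5, 1))
    model.unfreeze_last(n_unfreeze)
    if plan.scheme is BalancingScheme.DOUBLE:
        X2, y2 = loader(plan.stage2_rows)
    else:
        X2, y2 = X1, y1
    _run_stage(model, X2, y2, Xv, yv, schedule.stage2_epochs_max,
               schedule.lr_stage2, schedule, 2, rng, history)
    history["unfreeze_last_n"] = n_unfreeze
    return model, history


def predict(model: OpacityClassifier, images: np.ndarray,
            chunk: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities (n x 4) and argmax grades (ties -> lower grade)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[:, None]
    if images.ndim != 4 or images.shape[1] != model.in_channels:
        raise ValueError("expected (n, channels, H, W) images")
    probs = np.concatenate([model.predict_proba(images[i:i + chunk])
                            for i in range(0, len(images), chunk)])
    return probs, probs.argmax(axis=1)


def save_classifier(model: OpacityClassifier, path, extra: dict | None = None) -> None:
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    scaler = model.head.layers[0]
    if isinstance(scaler, _nn.BatchScale) and scaler.mean is not None:
        arrays["scaler_mean"] = scaler.mean
        arrays["scaler_scale"] = scaler.scale
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"backbone": model.backbone.name, "side": model.side,
               "seed": model.seed, "input_size": model.input_size,
               "in_channels": model.in_channels, "config": model.config}
    sidecar.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_classifier(path) -> OpacityClassifier:
    path = Path(path)
    sc = json.loads(path.with_suffix(".json").read_text())
    model = OpacityClassifier(sc["backbone"], side=sc["side"], seed=sc["seed"],
                              in_channels=sc["in_channels"],
                              input_size=sc["input_size"], config=sc["config"])
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    if "scaler_mean" in data:
        scaler = model.head.layers[0]
        scaler.mean = data["scaler_mean"]
        scaler.scale = data["scaler_scale"]
    return model
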