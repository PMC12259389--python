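"""Spectrogram-image classifiers: backbone roster, training recipe, inference.

The roster names six CNN families — alexnet, vgg16, vgg19, resnet18,
resnet50, resnet152 — realized here as compact configurations that carry each
family's architectural motif (a large-stride stem for alexnet, stacked 3x3
convolutions for the VGGs, residual blocks of increasing depth for the
ResNets) at a size trainable in minutes on one CPU. ``pretrained=True``
selects a fixed, architecture-specific reference initialization so every run
starts from identical "stock" weights; ``fine_tune=False`` freezes everything
but the classification head.

Training follows the standard transfer-learning recipe for this problem:
Adam at a maximum learning rate of 0.001 under a one-cycle schedule, batch
size 32, class-weighted losses (binary: gibbon 0.9 / noise 0.1 on a single
logit; multiclass: noise 0.02 and 0.49 per gibbon class over three logits),
and early stopping on validation loss with patience 2, restoring the best
epoch's weights.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnet
from .audio import RenderSpec, normalize_image, spectrogram_image
from .dataset import NOISE_LABEL, LabeledClip

__all__ = [
    "ARCHITECTURES",
    "BackboneSpec",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict_confidence",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("alexnet", "vgg16", "vgg19", "resnet18", "resnet50", "resnet152")

#: deterministic seeds for the fixed reference ("stock") initializations
_REFERENCE_SEEDS = {name: 77000 + i for i, name in enumerate(ARCHITECTURES)}


@dataclass(frozen=True)
class BackboneSpec:
    architecture: str = "alexnet"
    pretrained: bool = True
    fine_tune: bool = True

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )


@dataclass
class TrainConfig:
    max_learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 5
    patience: int = 2
    class_weights: dict = field(default_factory=lambda: {"gibbon": 0.9, NOISE_LABEL: 0.1})
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")
        if len(self.class_weights) < 2:
            raise ValueError("need at least two classes")

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)


class _Net:
    """Backbone + head pair with freeze and state snapshot support."""

    def __init__(self, backbone: nnet.Sequential, head: nnet.Linear, feat_dim: int, out_dim: int):
        self.backbone = backbone
        self.head = head
        self.feat_dim = feat_dim
        self.out_dim = out_dim

    def params(self):
        return self.backbone.params() + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x, train), train)

    def backward(self, dout: np.ndarray) -> None:
        self.backbone.backward(self.head.backward(dout))

    def get_state(self) -> list:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    def backbone_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.backbone.params()))


def _make_backbone(architecture: str, rng) -> tuple:
    """Compact backbone per roster family; returns (Sequential, feature_dim).

    All variants end in a wide flattened feature map (plus a fully-connected
    stage for the alexnet/vgg families, whose originals classify from wide fc
    layers): a head on thousands of features moves much further per optimizer
    step than one on a narrow pooled vector, which is what makes the short
    transfer-learning schedules effective.
    """
    C, R, M, B = nnet.Conv2d, nnet.ReLU, nnet.MaxPool2d, nnet.ResidualBlock
    F, L = nnet.Flatten, nnet.Linear
    if architecture == "alexnet":
        layers = [
            C(3, 16, 8, stride=8, rng=rng), R(),          # 224 -> 28
            C(16, 32, 3, 1, 1, rng=rng), R(), M(),        # 28 -> 14
            C(32, 32, 3, 1, 1, rng=rng), R(), M(),        # 14 -> 7
            F(), L(32 * 7 * 7, 256, rng=rng), R(),
        ]
        return nnet.Sequential(layers), 256
    if architecture in ("vgg16", "vgg19"):
        per_stage = 2 if architecture == "vgg16" else 3
        layers = [C(3, 16, 4, stride=4, rng=rng), R()]    # 224 -> 56
        c_in = 16
        for c_out in (16, 32):
            for _ in range(per_stage):
                layers += [C(c_in, c_out, 3, 1, 1, rng=rng), R()]
                c_in = c_out
            layers.append(M())                            # 56 -> 28 -> 14
        layers += [M(), F(), L(32 * 7 * 7, 256, rng=rng), R()]  # 14 -> 7
        return nnet.Sequential(layers), 256
    # resnet family: residual blocks, deeper with the bigger names
    blocks_per_stage = {"resnet18": 1, "resnet50": 2, "resnet152": 3}[architecture]
    layers = [C(3, 16, 8, stride=8, rng=rng), R()]        # 224 -> 28
    c_in = 16
    for c_out in (16, 32):
        for _ in range(blocks_per_stage):
            layers.append(B(c_in, c_out, rng=rng))
            c_in = c_out
        layers.append(M())                                # 28 -> 14 -> 7
    layers.append(F())
    return nnet.Sequential(layers), 32 * 7 * 7


def build_model(spec: BackboneSpec, n_classes: int, seed: int = 0) -> _Net:
    """Instantiate a backbone and fresh classification head.

    Binary problems (n_classes == 2) get a single-logit head whose sigmoid is
    the positive-class confidence; multiclass heads have one logit per class.
    With ``pretrained`` the backbone starts from the fixed reference weights
    for that architecture; otherwise from a seed-dependent initialization.
    With ``fine_tune=False`` every backbone parameter is frozen.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    backbone_seed = _REFERENCE_SEEDS[spec.architecture] if spec.pretrained else seed
    backbone, feat_dim = _make_backbone(spec.architecture, np.random.default_rng(backbone_seed))
    out_dim = 1 if n_classes == 2 else n_classes
    head = nnet.Linear(feat_dim, out_dim, rng=np.random.default_rng(seed + 1))
    if not spec.fine_tune:
        for p in backbone.params():
            p.trainable = False
    net = _Net(backbone, head, feat_dim, out_dim)
    net.spec = spec
    return net


@dataclass
class TrainedModel:
    net: _Net
    backbone: BackboneSpec
    config: TrainConfig
    render: RenderSpec
    class_order: list
    history: dict
    best_epoch: int
    sample_rate_hz: int | None = None

    def score_window(self, seg, begin_s: float = 0.0) -> dict:
        """Class confidences for one audio window (render -> normalize -> net)."""
        img = spectrogram_image(seg, self.render)
        x = normalize_image(img, self.render)
        conf = predict_confidence(self, x[None])
        if self.net.out_dim == 1:
            p = float(conf[0])
            return {self.class_order[1]: p, self.class_order[0]: 1.0 - p}
        return dict(zip(self.class_order, conf[0]))


def _class_order(cfg: TrainConfig) -> list:
    """Binary: [negative, positive] with noise negative; multiclass: weight-dict order."""
    labels = list(cfg.class_weights)
    if cfg.n_classes == 2:
        if NOISE_LABEL in labels:
            neg = NOISE_LABEL
            pos = next(l for l in labels if l != NOISE_LABEL)
        else:
            neg, pos = labels[1], labels[0]
        return [neg, pos]
    return labels


def _materialize(items, render: RenderSpec, class_order: list):
    """Render and normalize clips (or accept pre-rendered [0,1] images)."""
    xs, ys, rate = [], [], None
    index = {lab: i for i, lab in enumerate(class_order)}
    for item in items:
        if isinstance(item, LabeledClip):
            img = spectrogram_image(item.audio, render)
            x = normalize_image(img, render)
            label = item.label
            rate = item.audio.sample_rate_hz
        else:
            pixels, label = item
            x = normalize_image(np.asarray(pixels), render)
        if label not in index:
            raise ValueError(f"label {label!r} not in class set {class_order}")
        xs.append(np.transpose(x, (2, 0, 1)).astype(np.float32))
        ys.append(index[label])
    return np.stack(xs), np.asarray(ys, dtype=np.int64), rate


def _eval_pass(net: _Net, x: np.ndarray, y: np.ndarray, cfg: TrainConfig, class_order: list, batch: int = 64):
    losses, hits, n = 0.0, 0, len(y)
    weights = np.array([cfg.class_weights[lab] for lab in class_order])
    for i in range(0, n, batch):
        xb, yb = x[i : i + batch], y[i : i + batch]
        logits = net.forward(xb, train=False)
        if net.out_dim == 1:
            loss, _ = nnet.bce_with_logits_loss(logits[:, 0], yb.astype(float), weights[yb])
            pred = (nnet.sigmoid(logits[:, 0]) >= 0.5).astype(int)
        else:
            loss, _ = nnet.softmax_cross_entropy_loss(logits, yb, weights)
            pred = logits.argmax(axis=1)
        losses += loss * len(yb)
        hits += int((pred == yb).sum())
    return losses / n, hits / n


def train(model: _Net, train_clips, val_clips, cfg: TrainConfig, render: RenderSpec | None = None) -> TrainedModel:
    """Train under the one-cycle/Adam recipe with early stopping.

    ``train_clips``/``val_clips`` are sequences of :class:`LabeledClip`
    (rendered on the fly through ``render``) or ``(pixels, label)`` pairs of
    un-normalized [0, 1] images. Validation loss is monitored each epoch;
    after ``patience`` epochs without improvement training stops and the best
    epoch's weights are restored. ``max_epochs=0`` returns the model untouched
    with an empty history.
    """
    render = render or RenderSpec()
    if cfg.max_epochs > 0 and (not len(train_clips) or not len(val_clips)):
        raise ValueError("train and validation partitions must both be non-empty")
    class_order = _class_order(cfg)
    history: dict = {"train_loss": [], "val_loss": [], "val_accuracy": [], "lr": []}
    spec = getattr(model, "spec", BackboneSpec())
    if cfg.max_epochs == 0:
        return TrainedModel(model, spec, cfg, render, class_order, history, best_epoch=0)

    x_tr, y_tr, rate = _materialize(train_clips, render, class_order)
    x_va, y_va, _ = _materialize(val_clips, render, class_order)
    weights = np.array([cfg.class_weights[lab] for lab in class_order])

    rng = np.random.default_rng(cfg.seed)
    opt = nnet.Adam(model.params(), lr=cfg.max_learning_rate)
    steps_per_epoch = int(np.ceil(len(y_tr) / cfg.batch_size))
    sched = nnet.OneCycleLR(cfg.max_learning_rate, total_steps=steps_per_epoch * cfg.max_epochs)

    best_loss, best_epoch, best_state, bad_epochs = np.inf, 0, model.get_state(), 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(y_tr))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.lr = sched.step()
            opt.zero_grad()
            logits = model.forward(xb, train=True)
            if model.out_dim == 1:
                loss, dz = nnet.bce_with_logits_loss(logits[:, 0], yb.astype(float), weights[yb])
                model.backward(dz[:, None])
            else:
                loss, dz = nnet.softmax_cross_entropy_loss(logits, yb, weights)
                model.backward(dz)
            opt.step()
            epoch_loss += loss * len(yb)
        val_loss, val_acc = _eval_pass(model, x_va, y_va, cfg, class_order)
        history["train_loss"].append(epoch_loss / len(y_tr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].extend(sched.history[-steps_per_epoch:])
        if val_loss < best_loss - 1e-12:
            best_loss, best_epoch, best_state, bad_epochs = val_loss, epoch, model.get_state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.set_state(best_state)
    return TrainedModel(
        model, spec, cfg, render, class_order, history, best_epoch, sample_rate_hz=rate
    )


def predict_confidence(tm: TrainedModel, images: np.ndarray):
    """Confidences for normalized image(s): a scalar per image in [0, 1] for
    binary heads (sigmoid of the single logit); a probability vector summing
    to 1 for multiclass heads (softmax over the logits).
    """
    x = np.asarray(images, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    edge = tm.render.image_edge_px
    if x.ndim != 4 or x.shape[1:] != (edge, edge, 3):
        raise ValueError(f"expected images of shape (N, {edge}, {edge}, 3), got {x.shape}")
    x = np.transpose(x, (0, 3, 1, 2))
    logits = tm.net.forward(x, train=False)
    if tm.net.out_dim == 1:
        out = nnet.sigmoid(logits[:, 0])
    else:
        out = nnet.softmax(logits)
    return out[0] if single else out


def save_model(tm: TrainedModel, path) -> None:
    """Checkpoint weights (.npz) with a JSON sidecar carrying the specs and
    class-label ordering (class order is part of the model contract)."""
    path = Path(path)
    state = {f"p{i}": v for i, v in enumerate(tm.net.get_state())}
    np.savez(path.with_suffix(".npz"), **state)
    sidecar = {
        "backbone": tm.backbone.__dict__,
        "config": {**tm.config.__dict__},
        "render": {k: list(v) if isinstance(v, tuple) else v for k, v in tm.render.__dict__.items()},
        "class_order": tm.class_order,
        "best_epoch": tm.best_epoch,
        "sample_rate_hz": tm.sample_rate_hz,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = BackboneSpec(**sidecar["backbone"])
    cfg = TrainConfig(**sidecar["config"])
    render_kwargs = dict(sidecar["render"])
    for key in ("normalization_mean", "normalization_std"):
        render_kwargs[key] = tuple(render_kwargs[key])
    render = RenderSpec(**render_kwargs)
    net = build_model(spec, cfg.n_classes, seed=cfg.seed)
    data = np.load(path.with_suffix(".npz"))
    net.set_state([data[f"p{i}"] for i in range(len(data.files))])
    return TrainedModel(
        net,
        spec,
        cfg,
        render,
        list(sidecar["class_order"]),
        history={},
        best_epoch=int(sidecar["best_epoch"]),
        sample_rate_hz=sidecar.get("sample_rate_hz"),
    )
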