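"""Training and evaluation harness for the onset and aggregate classifiers.

The protocol mirrors the acquisition software it stands in for: per-image
min-max normalization, a 15% test split with 20% of the remainder held out
for validation, Adam updates at learning rate 1e-5 with a binary
cross-entropy loss, early stopping on the validation loss, and a
best-validation checkpoint.

Four compact architecture variants preserve the taxonomy of the original
models (convolutional vs. attention encoders, single vs. multi timepoint)
at desk scale.  z-planes enter as input channels; timepoints as the
temporal axis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _nn
from ._rng import substream
from .synthetic_scope import LabeledExample


class ArchVariant(str, Enum):
    CONV_RECURRENT = "conv_recurrent"
    VIDEO_ATTENTION = "video_attention"
    SINGLE_FRAME_CONV = "single_frame_conv"
    SINGLE_FRAME_ATTENTION = "single_frame_attention"


_SINGLE_FRAME = {ArchVariant.SINGLE_FRAME_CONV, ArchVariant.SINGLE_FRAME_ATTENTION}


@dataclass(frozen=True)
class ArchSpec:
    variant: ArchVariant
    input_shape: tuple[int, int, int, int]  # (T, Z, H, W)
    width: int = 1

    def __post_init__(self) -> None:
        t = self.input_shape[0]
        if self.variant in _SINGLE_FRAME and t != 1:
            raise ValueError(f"{self.variant.value} requires T == 1")
        if self.variant not in _SINGLE_FRAME and t < 2:
            raise ValueError(f"{self.variant.value} requires T > 1")
        if self.width < 1:
            raise ValueError("width must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    loss: str = "bce"
    test_fraction: float = 0.15
    val_fraction: float = 0.20
    patience: int = 10
    max_epochs: int = 400
    batch_size: int = 2  # small batches: enough Adam steps at lr 1e-5 on CPU
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy is supported")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix must be nonempty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Classification metrics; ``None`` marks a flagged-undefined value."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: float


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# normalization


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Rescale a 2D image to [0, 1]; a constant image maps to all zeros."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN or Inf")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def normalize_tensor(tensor: np.ndarray) -> np.ndarray:
    """Apply per-plane min-max normalization to a (T, Z, H, W) tensor."""
    tensor = np.asarray(tensor, dtype=np.float64)
    out = np.empty_like(tensor)
    for t in range(tensor.shape[0]):
        for z in range(tensor.shape[1]):
            out[t, z] = normalize_image(tensor[t, z])
    return out


def stack_examples(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    """Normalize and stack examples -> (X (N,T,Z,H,W), y (N,))."""
    xs = np.stack([normalize_tensor(ex.tensor) for ex in examples])
    ys = np.array([ex.label for ex in examples], dtype=np.int64)
    return xs, ys


# ---------------------------------------------------------------------------
# dataset splitting


def split_dataset(
    examples: Sequence[LabeledExample],
    test_fraction: float = 0.15,
    val_fraction: float = 0.20,
    seed: int = 0,
) -> tuple[list[LabeledExample], list[LabeledExample], list[LabeledExample]]:
    """Stratified, cell-disjoint (train, val, test) split.

    Sizes follow a floor convention with the remainder going to train:
    ``len(test) = floor(N * test_fraction)`` summed over per-class floors,
    then ``len(val) = floor(remaining * val_fraction)``.  Examples that
    share a source cell never straddle splits.
    """
    if not (0.0 < test_fraction < 1.0) or not (0.0 < val_fraction < 1.0):
        raise ValueError("fractions must lie in (0, 1)")
    labels = {ex.label for ex in examples}
    if labels != {0, 1}:
        raise ValueError("both classes must be present")

    rng = substream(seed, "split")
    test: list[LabeledExample] = []
    val: list[LabeledExample] = []
    train: list[LabeledExample] = []
    for label in (1, 0):
        cls = [ex for ex in examples if ex.label == label]
        groups: dict[int, list[LabeledExample]] = {}
        for ex in cls:
            groups.setdefault(ex.cell_id, []).append(ex)
        keys = sorted(groups)
        rng.shuffle(keys)
        n = len(cls)
        n_test = int(math.floor(n * test_fraction))
        n_val = int(math.floor((n - n_test) * val_fraction))
        i = taken = 0
        while i < len(keys) and taken < n_test:
            test.extend(groups[keys[i]])
            taken += len(groups[keys[i]])
            i += 1
        taken = 0
        while i < len(keys) and taken < n_val:
            val.extend(groups[keys[i]])
            taken += len(groups[keys[i]])
            i += 1
        for key in keys[i:]:
            train.extend(groups[key])
    if not test or not val or not train:
        raise ValueError("split produced an empty subset; dataset too small")
    return train, val, test


# ---------------------------------------------------------------------------
# model construction


def _down_factor(h: int, target: int = 32) -> int:
    """Smallest integer pooling factor giving a side <= target that still
    divides h and leaves a side divisible by 4 (two 2x2 pools)."""
    for f in range(max(1, -(-h // target)), h + 1):
        if h % f == 0 and (h // f) % 4 == 0:
            return f
    raise ValueError(f"image side {h} not reducible for the conv trunk")


def _frame_encoder(c_in: int, h: int, width: int, rng) -> tuple[_nn.Sequential, int]:
    f = _down_factor(h)
    enc = _nn.Sequential(
        _nn.AvgPoolDown(f),
        _nn.Conv2d(c_in, 8 * width, rng),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Conv2d(8 * width, 16 * width, rng),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.GlobalAvgMaxPool(),
    )
    return enc, 32 * width


def _attention_encoder(c_in: int, h: int, width: int, rng) -> _nn.Sequential:
    f = _down_factor(h)
    side = h // f
    patch = max(1, side // 4)
    n_tokens = (side // patch) ** 2
    d = 16 * width
    return _nn.Sequential(
        _nn.AvgPoolDown(f),
        _nn.Patchify(patch),
        _nn.Dense(c_in * patch * patch, d, rng),
        _nn.Tanh(),
        _nn.PositionalEmbedding(n_tokens, d, rng),
        _nn.SelfAttention(d, rng),
        _nn.MeanTokens(),
        _nn.FeatureNorm(d),
        _nn.Dense(d, 1, rng, zero_init=True),
    )


def build_network(arch: ArchSpec, seed: int) -> _nn.Sequential:
    t, z, h, w = arch.input_shape
    if h != w:
        raise ValueError("square inputs expected")
    rng = substream(seed, "init", arch.variant.value)
    if arch.variant is ArchVariant.SINGLE_FRAME_CONV:
        enc, feat = _frame_encoder(z, h, arch.width, rng)
        return _nn.Sequential(enc, _nn.FeatureNorm(feat),
                              _nn.Dense(feat, 1, rng, zero_init=True))
    if arch.variant is ArchVariant.SINGLE_FRAME_ATTENTION:
        return _attention_encoder(z, h, arch.width, rng)
    if arch.variant is ArchVariant.CONV_RECURRENT:
        enc, feat = _frame_encoder(z, h, arch.width, rng)
        hid = 16 * arch.width
        return _nn.Sequential(_nn.FrameEncoderSequence(enc),
                              _nn.SimpleRNN(feat, hid, rng),
                              _nn.FeatureNorm(hid),
                              _nn.Dense(hid, 1, rng, zero_init=True))
    if arch.variant is ArchVariant.VIDEO_ATTENTION:
        enc, feat = _frame_encoder(z, h, arch.width, rng)
        d = 16 * arch.width
        return _nn.Sequential(_nn.FrameEncoderSequence(enc),
                              _nn.Dense(feat, d, rng),
                              _nn.Tanh(),
                              _nn.PositionalEmbedding(t, d, rng),
                              _nn.SelfAttention(d, rng),
                              _nn.MeanTokens(),
                              _nn.FeatureNorm(d),
                              _nn.Dense(d, 1, rng, zero_init=True))
    raise ValueError(f"unknown variant {arch.variant}")


@dataclass
class TrainedModel:
    """Opaque predictor with its architecture spec and decision threshold."""

    net: _nn.Sequential
    arch: ArchSpec
    decision_threshold: float = 0.5
    normalization: str = "per-image min-max to [0, 1]"
    train_seed: int = 0
    history: dict = field(default_factory=dict)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        # (N, T, Z, H, W); single-frame nets consume (N, Z, H, W)
        if self.arch.variant in _SINGLE_FRAME:
            return x[:, 0]
        return x

    def predict_scores(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        """Sigmoid scores for a normalized batch (N, T, Z, H, W)."""
        if x.shape[1:] != self.arch.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} != expected {self.arch.input_shape}")
        out = []
        for i in range(0, len(x), batch):
            z = self.net.forward(self._prepare(x[i:i + batch]))
            out.append(_nn.sigmoid(z.reshape(-1)))
        return np.concatenate(out)


def predict(model: TrainedModel, tensor: np.ndarray) -> tuple[float, int]:
    """Score one normalized (T, Z, H, W) tensor; label = score >= threshold."""
    tensor = np.asarray(tensor, dtype=np.float64)
    if tensor.shape != model.arch.input_shape:
        raise ValueError(
            f"tensor shape {tensor.shape} != expected {model.arch.input_shape}")
    score = float(model.predict_scores(tensor[None])[0])
    return score, int(score >= model.decision_threshold)


# ---------------------------------------------------------------------------
# training


def _dataset_loss(net: _nn.Sequential, x: np.ndarray, y: np.ndarray,
                  prepare, batch: int = 32) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        xb, yb = x[i:i + batch], y[i:i + batch]
        z = net.forward(prepare(xb))
        loss, _ = _nn.bce_with_logits(z, yb)
        total += loss * len(xb)
        n += len(xb)
    return total / max(n, 1)


def train_classifier(
    train: Sequence[LabeledExample],
    val: Sequence[LabeledExample],
    arch: ArchSpec,
    cfg: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train with Adam/BCE, early stopping on validation loss, and return the
    best-validation checkpoint."""
    net = build_network(arch, cfg.seed)
    model = TrainedModel(net=net, arch=arch, train_seed=cfg.seed)
    x_tr, y_tr = stack_examples(train)
    x_va, y_va = stack_examples(val)
    if x_tr.shape[1:] != arch.input_shape:
        raise ValueError(
            f"training tensors {x_tr.shape[1:]} != arch {arch.input_shape}")

    net.calibrate(model._prepare(x_tr))
    params = net.params()
    best_loss = math.inf
    best_state: Optional[list[np.ndarray]] = None
    stale = 0
    step = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.max_epochs):
        order = substream(cfg.seed, "epoch", epoch).permutation(len(x_tr))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = model._prepare(x_tr[idx])
            z = net.forward(xb)
            loss, gz = _nn.bce_with_logits(z, y_tr[idx])
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss diverged at epoch {epoch}, step {step}")
            _nn.zero_grads(params)
            net.backward(gz.reshape(z.shape))
            step += 1
            _nn.adam_step(params, cfg.learning_rate, step)
            ep_loss += loss
            nb += 1
        val_loss = _dataset_loss(net, x_va, y_va, model._prepare)
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = [p.value.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        for p, v in zip(params, best_state):
            p.value[...] = v
    model.history = {"epochs": len(history["val_loss"]),
                     "best_val_loss": best_loss, **history}
    return model


# ---------------------------------------------------------------------------
# evaluation


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """precision / recall / F1 / accuracy with flagged-undefined semantics."""
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    accuracy = (cm.tp + cm.tn) / cm.total
    return Metrics(precision=precision, recall=recall, f1=f1, accuracy=accuracy)


def evaluate(model, test: Sequence[LabeledExample]) -> tuple[ConfusionMatrix, Metrics]:
    """Confusion matrix and metrics of ``model`` on a labeled test set.

    ``model`` needs ``predict_scores`` and ``decision_threshold`` — any
    object with that surface (e.g. an oracle or constant baseline) works.
    """
    if not test:
        raise ValueError("test set must be nonempty")
    x, y = stack_examples(test)
    scores = model.predict_scores(x)
    pred = (scores >= model.decision_threshold).astype(np.int64)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return cm, compute_metrics(cm)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON sidecar describing the model."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    for i, buf in enumerate(model.net.buffers()):
        arrays[f"b{i}"] = buf
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "variant": model.arch.variant.value,
        "input_shape": list(model.arch.input_shape),
        "width": model.arch.width,
        "decision_threshold": model.decision_threshold,
        "normalization": model.normalization,
        "train_seed": model.train_seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arch = ArchSpec(variant=ArchVariant(sidecar["variant"]),
                    input_shape=tuple(sidecar["input_shape"]),
                    width=sidecar["width"])
    net = build_network(arch, sidecar["train_seed"])
    params = net.params()
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]
        for i, buf in enumerate(net.buffers()):
            buf[...] = data[f"b{i}"]
    for lyr in net.layers:
        if isinstance(lyr, _nn.FeatureNorm):
            lyr.initialized = True
    return TrainedModel(net=net, arch=arch,
                        decision_threshold=sidecar["decision_threshold"],
                        normalization=sidecar["normalization"],
                        train_seed=sidecar["train_seed"])
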